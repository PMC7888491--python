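# Template for the companion-study samples that complete the 8-sample
# rapeseed-meal regression panel.  The three additional samples were
# characterised with the same chambers and protocol but their composition
# and energy values are tabulated in the companion reports, not here; fill
# in one row per sample (composition in % of DM, energies in MJ/kg DM) and
# pass the file to the pipeline's panel input.
sample_id	cp	ee	starch	ndf	adf	ash	crude_fiber	ge	de	me	ne
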