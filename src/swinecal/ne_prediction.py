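"""Correlation analysis and stepwise NE prediction equations for feed samples.

Across a panel of ingredient samples (chemical composition in % of DM,
energy values in MJ/kg DM) the module computes pairwise Pearson
correlations and fits linear NE prediction equations by ordinary least
squares with forward-with-backward-elimination stepwise selection.

Model metrics follow the conventions common in animal-nutrition work done
with SAS PROC REG: R^2 = 1 - SSE/SST, RMSE = sqrt(SSE/(n - p - 1)) for p
slope terms, and the log-SSE AIC variant

    AIC = n * ln(SSE / n) + 2 * (p + 1),

which is negative for small residual variance (an ``aic_definition``
switch selects the likelihood-based statsmodels AIC instead).  Candidate
predictor families mirror common practice: composition only, or
composition plus one of GE/DE/ME; the family with the greatest R^2 and
least RMSE (AIC as final tiebreak) is the headline equation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "COMPOSITION_COLUMNS",
    "ENERGY_COLUMNS",
    "SamplePanelRow",
    "RegressionModel",
    "RSM_NE_EQUATIONS",
    "panel_frame",
    "pearson_matrix",
    "fit_ols",
    "stepwise_select",
    "best_subset",
    "apply_equation",
    "fit_equation_families",
]

COMPOSITION_COLUMNS = ("cp", "ee", "starch", "ndf", "adf", "ash", "crude_fiber")
ENERGY_COLUMNS = ("ge", "de", "me", "ne")

AicDefinition = Literal["sas", "loglik"]


@dataclass(frozen=True)
class SamplePanelRow:
    """One ingredient sample: composition (% of DM) and energies (MJ/kg DM)."""

    sample_id: str
    cp: float
    ee: float
    starch: float
    ndf: float
    adf: float
    ash: float
    crude_fiber: float
    ge: float
    de: float
    me: float
    ne: float

    def __post_init__(self) -> None:
        for name in COMPOSITION_COLUMNS:
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must lie in [0, 100] % of DM, got {v!r}")
        for name in ENERGY_COLUMNS:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)!r}")
        if not self.ge >= self.de >= self.me >= self.ne:
            raise ValueError(
                f"{self.sample_id}: energies must satisfy GE >= DE >= ME >= NE, got "
                f"{self.ge}, {self.de}, {self.me}, {self.ne}"
            )


def panel_frame(panel: Sequence[SamplePanelRow] | pd.DataFrame) -> pd.DataFrame:
    """Panel as a DataFrame indexed by sample id."""
    if isinstance(panel, pd.DataFrame):
        return panel
    return pd.DataFrame(
        [
            {c: getattr(r, c) for c in COMPOSITION_COLUMNS + ENERGY_COLUMNS}
            for r in panel
        ],
        index=[r.sample_id for r in panel],
    )


def pearson_matrix(
    panel: Sequence[SamplePanelRow] | pd.DataFrame,
    columns: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p-values (t distribution, n-2 df)."""
    df = panel_frame(panel)
    cols = list(columns) if columns is not None else list(df.columns)
    n = len(df)
    if n < 3:
        raise ValueError(f"need at least 3 samples for correlations, got {n}")
    for c in cols:
        if df[c].nunique() <= 1:
            raise ValueError(f"column {c!r} is constant; correlation undefined")
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for a, b in itertools.combinations(cols, 2):
        res = stats.pearsonr(df[a], df[b])
        r.loc[a, b] = r.loc[b, a] = res.statistic
        p.loc[a, b] = p.loc[b, a] = res.pvalue
    return r, p


@dataclass
class RegressionModel:
    """A fitted (or published) linear prediction equation with its metrics."""

    response: str
    predictors: tuple[str, ...]
    coefficients: dict[str, float]
    intercept: float
    r2: float
    rmse: float
    aic: float
    overall_p: float
    n: int

    def predict(self, sample: Mapping[str, float] | SamplePanelRow) -> float:
        return apply_equation(self, sample)

    def equation(self, digits: int = 2) -> str:
        terms = [
            f"{coef:+.{digits}f}*{name}" for name, coef in self.coefficients.items()
        ]
        return f"{self.response} = " + " ".join(terms) + f" {self.intercept:+.{digits}f}"


def _as_xy(y, X) -> tuple[np.ndarray, pd.DataFrame]:
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise ValueError("y and X have different lengths")
    return y, X


def fit_ols(
    y: Sequence[float] | np.ndarray,
    X: pd.DataFrame | Mapping[str, Sequence[float]],
    response: str = "ne",
    aic_definition: AicDefinition = "sas",
) -> RegressionModel:
    """Ordinary least squares with R^2, RMSE, AIC and the overall F-test."""
    y, X = _as_xy(y, X)
    n, p = len(y), X.shape[1]
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    if p > 0:
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), X.to_numpy(dtype=float)]))
        if rank < p + 1:
            corr = X.corr().abs()
            np.fill_diagonal(corr.values, 0.0)
            worst = corr.stack().idxmax() if p > 1 else (X.columns[0],)
            raise ValueError(f"design matrix is rank deficient; check columns {tuple(worst)}")
    res = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    sse = float(res.ssr)
    r2 = float(res.rsquared) if p > 0 else 0.0
    rmse = math.sqrt(sse / (n - p - 1))
    if aic_definition == "sas":
        aic = n * math.log(sse / n) + 2 * (p + 1) if sse > 0 else -math.inf
    elif aic_definition == "loglik":
        aic = float(res.aic)
    else:
        raise ValueError(f"unknown aic_definition {aic_definition!r}")
    return RegressionModel(
        response=response,
        predictors=tuple(X.columns),
        coefficients={c: float(res.params[c]) for c in X.columns},
        intercept=float(res.params["const"]),
        r2=r2,
        rmse=rmse,
        aic=aic,
        overall_p=float(res.f_pvalue) if p > 0 else math.nan,
        n=n,
    )


def _partial_p(y: np.ndarray, X: pd.DataFrame, term: str) -> float:
    # two-sided t-test p of the term's coefficient in the full model,
    # identical to the partial F p-value for one added term
    res = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    return float(res.pvalues[term])


def stepwise_select(
    y: Sequence[float] | np.ndarray,
    X: pd.DataFrame | Mapping[str, Sequence[float]],
    alpha_enter: float = 0.15,
    alpha_stay: float = 0.15,
    candidate_sets: Sequence[str] | None = None,
    response: str = "ne",
    aic_definition: AicDefinition = "sas",
) -> RegressionModel:
    """Forward stepwise selection with backward elimination.

    At each step the candidate with the smallest partial-F p-value below
    ``alpha_enter`` enters; any included term whose p-value rises above
    ``alpha_stay`` is then removed.  Iterates to a fixed point.  If no
    predictor qualifies, an intercept-only model is returned with a
    warning.
    """
    y, X = _as_xy(y, X)
    if not (0 < alpha_enter < 1 and 0 < alpha_stay < 1):
        raise ValueError("alpha_enter and alpha_stay must lie in (0, 1)")
    pool = list(candidate_sets) if candidate_sets is not None else list(X.columns)
    missing = [c for c in pool if c not in X.columns]
    if missing:
        raise ValueError(f"candidate predictors not in X: {missing}")
    selected: list[str] = []
    while True:
        changed = False
        # forward step
        remaining = [c for c in pool if c not in selected]
        if remaining and len(y) > len(selected) + 2:
            pvals = {c: _partial_p(y, X[selected + [c]], c) for c in remaining}
            best = min(pvals, key=pvals.get)
            if pvals[best] < alpha_enter:
                selected.append(best)
                changed = True
        # backward step
        while len(selected) > 0:
            pvals = {c: _partial_p(y, X[selected], c) for c in selected}
            worst = max(pvals, key=pvals.get)
            if pvals[worst] > alpha_stay:
                selected.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break
    if not selected:
        warnings.warn("no predictor met the entry criterion; intercept-only model", stacklevel=2)
        n = len(y)
        sse = float(np.sum((y - y.mean()) ** 2))
        aic = n * math.log(sse / n) + 2 if (aic_definition == "sas" and sse > 0) else math.nan
        return RegressionModel(
            response=response,
            predictors=(),
            coefficients={},
            intercept=float(y.mean()),
            r2=0.0,
            rmse=math.sqrt(sse / (n - 1)),
            aic=aic,
            overall_p=math.nan,
            n=n,
        )
    return fit_ols(y, X[selected], response=response, aic_definition=aic_definition)


def best_subset(
    y: Sequence[float] | np.ndarray,
    X: pd.DataFrame | Mapping[str, Sequence[float]],
    max_terms: int | None = None,
    response: str = "ne",
    aic_definition: AicDefinition = "sas",
) -> RegressionModel:
    """Exhaustive subset search minimising AIC (oracle for stepwise)."""
    y, X = _as_xy(y, X)
    cols = list(X.columns)
    max_terms = max_terms if max_terms is not None else len(cols)
    n_subsets = sum(math.comb(len(cols), k) for k in range(1, max_terms + 1))
    if n_subsets > 100_000:
        raise ValueError(f"{n_subsets} candidate subsets exceed the 1e5 enumeration limit")
    best_model: RegressionModel | None = None
    for k in range(1, max_terms + 1):
        for subset in itertools.combinations(cols, k):
            if len(y) <= k + 1:
                continue
            try:
                model = fit_ols(y, X[list(subset)], response=response, aic_definition=aic_definition)
            except ValueError:  # rank-deficient subset
                continue
            if best_model is None or model.aic < best_model.aic:
                best_model = model
    if best_model is None:
        raise ValueError("no fittable subset (too few observations?)")
    return best_model


def apply_equation(
    model: RegressionModel | Mapping[str, float],
    sample: Mapping[str, float] | SamplePanelRow,
) -> float:
    """Evaluate a prediction equation on one sample.

    ``model`` is a RegressionModel or a mapping of predictor name to
    coefficient with an ``intercept`` entry.  Composition predictors are in
    % of DM and energy predictors in MJ/kg DM, so the result is MJ/kg DM.
    """
    if isinstance(model, RegressionModel):
        coefs, intercept = model.coefficients, model.intercept
    else:
        coefs = {k: v for k, v in model.items() if k != "intercept"}
        intercept = model.get("intercept", 0.0)

    def get(name: str) -> float:
        if isinstance(sample, SamplePanelRow):
            if not hasattr(sample, name):
                raise KeyError(f"sample lacks required field {name!r}")
            return getattr(sample, name)
        if name not in sample:
            raise KeyError(f"sample lacks required field {name!r}")
        return sample[name]

    return intercept + sum(coef * get(name) for name, coef in coefs.items())


#: Published stepwise NE prediction equations for rapeseed meal in growing
#: pigs (n = 8 samples; composition in % of DM, energies in MJ/kg DM),
#: usable with :func:`apply_equation` when only proximate analysis or a
#: single energy value is available for a new sample.
RSM_NE_EQUATIONS: tuple[RegressionModel, ...] = (
    RegressionModel(
        response="ne", predictors=("de", "cp"),
        coefficients={"de": 1.14, "cp": 0.46}, intercept=-25.24,
        r2=0.96, rmse=0.36, aic=-14.14, overall_p=0.005, n=8,
    ),
    RegressionModel(
        response="ne", predictors=("me",),
        coefficients={"me": 0.85}, intercept=-1.48,
        r2=0.88, rmse=0.56, aic=-7.69, overall_p=0.007, n=8,
    ),
    RegressionModel(
        response="ne", predictors=("ge", "ee"),
        coefficients={"ge": 4.62, "ee": -0.67}, intercept=-80.43,
        r2=0.82, rmse=0.75, aic=-2.29, overall_p=0.014, n=8,
    ),
    RegressionModel(
        response="ne", predictors=("ee", "ash"),
        coefficients={"ee": 0.22, "ash": -0.79}, intercept=14.36,
        r2=0.77, rmse=0.84, aic=-0.53, overall_p=0.018, n=8,
    ),
)

#: Candidate predictor families for NE equations: composition only, or
#: composition augmented with a single energy system.
EQUATION_FAMILIES: dict[str, tuple[str, ...]] = {
    "composition": COMPOSITION_COLUMNS,
    "ge": COMPOSITION_COLUMNS + ("ge",),
    "de": COMPOSITION_COLUMNS + ("de",),
    "me": COMPOSITION_COLUMNS + ("me",),
}


def fit_equation_families(
    panel: Sequence[SamplePanelRow] | pd.DataFrame,
    alpha_enter: float = 0.15,
    alpha_stay: float = 0.15,
    aic_definition: AicDefinition = "sas",
) -> dict[str, RegressionModel]:
    """One stepwise NE equation per candidate family.

    The caller ranks families by greatest R^2 and least RMSE (AIC breaking
    ties) to pick the headline equation; all four are returned so the
    trade-off is visible.
    """
    df = panel_frame(panel)
    y = df["ne"].to_numpy()
    out: dict[str, RegressionModel] = {}
    for family, cols in EQUATION_FAMILIES.items():
        usable = [c for c in cols if c in df.columns]
        out[family] = stepwise_select(
            y, df[usable], alpha_enter=alpha_enter, alpha_stay=alpha_stay,
            aic_definition=aic_definition,
        )
    return out
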