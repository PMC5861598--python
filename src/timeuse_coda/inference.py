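"""Group inference on the time-use composition in ilr coordinates.

The question is whether the mean six-part time-use composition differs
between people reporting some active travel and those reporting none.  The
composition is mapped to five ilr coordinates; then:

- :func:`compositional_manova` tests the exposure (or an interaction) term
  jointly across the five coordinates — Wilks' lambda with Rao's F
  approximation (Pillai's trace available), in staged models (unadjusted;
  age + sex; full: age, sex, work status, day type).
- :func:`fit_ilr_models` fits one OLS regression per coordinate.
- :func:`adjusted_group_means` predicts each group's five adjusted mean ilr
  coordinates on a least-squares-means reference grid (continuous
  covariates at their sample mean, binary factors weighted equally by
  default) and back-transforms them to model-adjusted compositional means
  closed to 1440 min.
- :func:`log_ratio_difference` and :func:`bootstrap_log_ratio_ci` give the
  per-component ln(some/none) contrasts with stratified percentile
  bootstrap 95% CIs; a CI excluding zero flags a component whose relative
  share of the day differs between groups.
- :func:`interaction_and_stratify` adds exposure x modifier interactions
  and, when significant, reruns the adjusted analysis per stratum.

Every statistic here is invariant to the orthonormal ilr basis chosen, so
the particular sequential binary partition only affects how individual
coordinates read, never the group-level results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .coda import close, ilr, ilr_inverse, make_ilr_basis
from .taxonomy import COMPONENTS
from .zeros import ImputedCompositions

__all__ = [
    "STAGES",
    "ManovaResult",
    "IlrModelFit",
    "AdjustedGroupMeans",
    "LogRatioDifferenceResult",
    "InteractionResult",
    "fit_ilr_models",
    "compositional_manova",
    "adjusted_group_means",
    "log_ratio_difference",
    "bootstrap_log_ratio_ci",
    "interaction_and_stratify",
]

MINUTES_PER_DAY = 1440.0

#: Adjustment stages: covariate columns added on top of the exposure term.
STAGES: dict[str, list[str]] = {
    "unadjusted": [],
    "age_sex": ["age", "female"],
    "full": ["age", "female", "working", "weekend"],
}

_BINARY_COLS = ("female", "working", "weekend")


def _table(data) -> pd.DataFrame:
    if isinstance(data, ImputedCompositions):
        return data.data
    return data


def _encode(df: pd.DataFrame) -> pd.DataFrame:
    """Numeric design columns from the compositions table."""
    enc = pd.DataFrame(index=df.index)
    enc["exposure"] = df["active_travel"].astype(float)
    enc["age"] = df["age"].astype(float)
    enc["female"] = (df["sex"] == "female").astype(float)
    enc["working"] = (df["work_status"] == "working_or_studying").astype(float)
    enc["weekend"] = (df["day_type"] == "weekend").astype(float)
    return enc


def _ilr_matrix(df: pd.DataFrame, basis: np.ndarray) -> np.ndarray:
    parts = df[list(COMPONENTS)].to_numpy(dtype=float)
    if np.any(parts <= 0):
        raise ValueError(
            "compositions contain zero parts; run zero imputation before inference"
        )
    return ilr(close(parts, 1.0), basis)


def _design(enc: pd.DataFrame, stage: str) -> tuple[np.ndarray, list[str]]:
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {sorted(STAGES)}")
    cols = ["const", "exposure"] + STAGES[stage]
    X = np.column_stack([np.ones(len(enc))] + [enc[c].to_numpy() for c in cols[1:]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design for stage {stage!r} (constant column?)")
    return X, cols


def _ols_multi(X: np.ndarray, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Multivariate OLS: coefficients and residual cross-product matrix."""
    beta, *_ = np.linalg.lstsq(X, Z, rcond=None)
    R = Z - X @ beta
    return beta, R.T @ R


@dataclass(frozen=True)
class ManovaResult:
    statistic: str  # wilks | pillai
    value: float  # lambda or trace
    f_value: float
    df_num: float
    df_den: float
    p_value: float
    stage: str
    term: str = "exposure"

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _wilks_f(E: np.ndarray, H: np.ndarray, q: int, ve: int) -> tuple[float, float, float, float, float]:
    p = E.shape[0]
    lam = float(np.linalg.det(E) / np.linalg.det(E + H))
    lam = min(max(lam, np.finfo(float).tiny), 1.0)
    den = p * p + q * q - 5
    t = np.sqrt((p * p * q * q - 4.0) / den) if den > 0 else 1.0
    w = ve + q - (p + q + 1) / 2.0
    df1 = p * q
    df2 = w * t - (p * q) / 2.0 + 1.0
    lam_t = lam ** (1.0 / t)
    F = (1.0 - lam_t) / lam_t * df2 / df1
    pval = float(sps.f.sf(F, df1, df2))
    return lam, float(F), float(df1), float(df2), pval


def _pillai_f(E: np.ndarray, H: np.ndarray, q: int, ve: int) -> tuple[float, float, float, float, float]:
    p = E.shape[0]
    V = float(np.trace(H @ np.linalg.inv(H + E)))
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    nn = (ve - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    F = (2 * nn + s + 1) / (2 * m + s + 1) * V / (s - V)
    pval = float(sps.f.sf(F, df1, df2))
    return V, float(F), float(df1), float(df2), pval


def compositional_manova(
    data,
    basis: np.ndarray | None = None,
    stage: str = "full",
    statistic: str = "wilks",
) -> ManovaResult:
    """Multivariate test of the exposure term across the 5 ilr coordinates.

    Compares the residual cross-products of the model with and without the
    exposure indicator (covariates per ``stage`` always retained), giving
    Wilks' lambda (default) or Pillai's trace with the standard F
    approximation.  The F statistic is invariant (to numerical precision)
    under any orthonormal change of ilr basis.
    """
    df = _table(data)
    basis = make_ilr_basis(len(COMPONENTS)) if basis is None else basis
    Z = _ilr_matrix(df, basis)
    enc = _encode(df)
    X, cols = _design(enc, stage)
    X_red = np.delete(X, cols.index("exposure"), axis=1)
    _, E = _ols_multi(X, Z)
    _, E_red = _ols_multi(X_red, Z)
    H = E_red - E
    ve = len(df) - X.shape[1]
    fn = {"wilks": _wilks_f, "pillai": _pillai_f}[statistic]
    value, F, df1, df2, p = fn(E, H, 1, ve)
    return ManovaResult(statistic, value, F, df1, df2, p, stage)


@dataclass
class IlrModelFit:
    """Five per-coordinate OLS fits sharing one design matrix."""

    stage: str
    basis: np.ndarray = field(repr=False)
    design_cols: list[str]
    X: np.ndarray = field(repr=False)
    Z: np.ndarray = field(repr=False)
    beta: np.ndarray = field(repr=False)  # p x 5
    models: list = field(repr=False)  # statsmodels OLSResults per coordinate
    enc: pd.DataFrame = field(repr=False)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def exposure_coefficients(self) -> np.ndarray:
        return self.beta[self.design_cols.index("exposure")]


def fit_ilr_models(data, basis: np.ndarray | None = None, stage: str = "full") -> IlrModelFit:
    """Fit one linear regression per ilr coordinate (five models).

    Each coordinate is the outcome of an OLS model with the active-travel
    indicator plus the stage's covariates.  Requires an imputed (strictly
    positive) compositions table.
    """
    df = _table(data)
    basis = make_ilr_basis(len(COMPONENTS)) if basis is None else basis
    Z = _ilr_matrix(df, basis)
    enc = _encode(df)
    X, cols = _design(enc, stage)
    if len(df) <= X.shape[1]:
        raise ValueError("need more observations than design parameters")
    beta, _ = _ols_multi(X, Z)
    models = [sm.OLS(Z[:, k], X).fit() for k in range(Z.shape[1])]
    return IlrModelFit(stage, basis, cols, X, Z, beta, models, enc)


@dataclass(frozen=True)
class AdjustedGroupMeans:
    """Model-adjusted mean ilr sets and compositional means per group."""

    ilr_some: np.ndarray
    ilr_none: np.ndarray
    composition_some: np.ndarray  # minutes/day, sums to 1440
    composition_none: np.ndarray
    stage: str
    grid: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": list(COMPONENTS),
                "no_active_travel_min": self.composition_none,
                "some_active_travel_min": self.composition_some,
            }
        )


def _reference_row(
    enc: pd.DataFrame, design_cols: list[str], exposure: float, grid: str
) -> np.ndarray:
    row = []
    for c in design_cols:
        if c == "const":
            row.append(1.0)
        elif c == "exposure":
            row.append(exposure)
        elif c in _BINARY_COLS and grid == "equal":
            row.append(0.5)
        else:  # continuous covariates, or observed-proportion weighting
            row.append(float(enc[c].mean()))
    return np.array(row)


def adjusted_group_means(fit: IlrModelFit, grid: str = "equal") -> AdjustedGroupMeans:
    """Back-transformed adjusted compositional means for both groups.

    Predicts the five ilr coordinates at exposure 0 and 1 on the reference
    grid — continuous covariates at their sample mean; binary factors
    weighted equally across levels (``grid='equal'``, the conventional
    least-squares-means grid) or at observed proportions
    (``grid='observed'``) — then inverse-ilr-transforms each set and closes
    to 1440 minutes.
    """
    if grid not in ("equal", "observed"):
        raise ValueError("grid must be 'equal' or 'observed'")
    x1 = _reference_row(fit.enc, fit.design_cols, 1.0, grid)
    x0 = _reference_row(fit.enc, fit.design_cols, 0.0, grid)
    z1 = x1 @ fit.beta
    z0 = x0 @ fit.beta
    return AdjustedGroupMeans(
        ilr_some=z1,
        ilr_none=z0,
        composition_some=ilr_inverse(z1, fit.basis, MINUTES_PER_DAY),
        composition_none=ilr_inverse(z0, fit.basis, MINUTES_PER_DAY),
        stage=fit.stage,
        grid=grid,
    )


def log_ratio_difference(some: np.ndarray, none: np.ndarray) -> np.ndarray:
    """Per-component ln(some_i / none_i) of two compositions.

    Positive values mean relatively more time in the exposed group; zero
    means no relative difference.  Invariant to the closure constant as
    long as both inputs share it.
    """
    some = np.asarray(some, dtype=float)
    none = np.asarray(none, dtype=float)
    if some.shape != none.shape:
        raise ValueError("compositions must have the same length")
    if np.any(some <= 0) or np.any(none <= 0):
        raise ValueError("log-ratio difference needs strictly positive parts")
    return np.log(some / none)


@dataclass(frozen=True)
class LogRatioDifferenceResult:
    """Per-component log-ratio differences with bootstrap 95% CIs."""

    table: pd.DataFrame  # component, estimate, lower, upper, significant
    stage: str
    n_bootstrap: int
    seed: int
    n_redraws: int = 0

    def significant_components(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "component"])


def bootstrap_log_ratio_ci(
    data,
    basis: np.ndarray | None = None,
    stage: str = "full",
    B: int = 1000,
    seed: int = 0,
    grid: str = "equal",
    ci_level: float = 0.95,
) -> LogRatioDifferenceResult:
    """Stratified percentile bootstrap CIs for the log-ratio differences.

    Resamples participants with replacement within each exposure group
    (original group sizes preserved), reruns the full adjusted-means
    pipeline — fit five coordinate models, predict adjusted ilr sets,
    back-transform, take log-ratio differences — on every resample, and
    reports the percentile 2.5/97.5 interval per component.  A component is
    flagged significant when its CI excludes zero.  Rank-deficient
    resamples are redrawn (counted, capped at 10*B).
    """
    import warnings

    if B < 100:
        warnings.warn(f"B={B} bootstrap replicates is small for stable CIs", stacklevel=2)
    df = _table(data)
    basis = make_ilr_basis(len(COMPONENTS)) if basis is None else basis
    Z = _ilr_matrix(df, basis)
    enc = _encode(df)
    X, cols = _design(enc, stage)
    exposure = enc["exposure"].to_numpy() > 0
    idx_e = np.flatnonzero(exposure)
    idx_u = np.flatnonzero(~exposure)
    if len(idx_e) == 0 or len(idx_u) == 0:
        raise ValueError("both exposure groups must be non-empty")

    # full-sample estimate
    beta, _ = _ols_multi(X, Z)
    fit = IlrModelFit(stage, basis, cols, X, Z, beta, [], enc)
    means = adjusted_group_means(fit, grid)
    estimate = log_ratio_difference(means.composition_some, means.composition_none)

    age_like = [
        (k, c) for k, c in enumerate(cols) if c not in ("const", "exposure")
    ]
    x1 = _reference_row(enc, cols, 1.0, grid)
    x0 = _reference_row(enc, cols, 0.0, grid)

    rng = np.random.default_rng(seed)
    draws = np.empty((B, len(COMPONENTS)))
    redraws = 0
    b = 0
    while b < B:
        take = np.concatenate(
            [rng.choice(idx_e, len(idx_e)), rng.choice(idx_u, len(idx_u))]
        )
        Xb, Zb = X[take], Z[take]
        XtX = Xb.T @ Xb
        if np.linalg.cond(XtX) > 1e12:
            redraws += 1
            if redraws > 10 * B:
                raise RuntimeError("too many rank-deficient bootstrap resamples")
            continue
        beta_b = np.linalg.solve(XtX, Xb.T @ Zb)
        r1, r0 = x1.copy(), x0.copy()
        for k, c in age_like:  # reference grid recomputed on the resample
            if c not in _BINARY_COLS or grid == "observed":
                r1[k] = r0[k] = Xb[:, k].mean()
        z1, z0 = r1 @ beta_b, r0 @ beta_b
        draws[b] = log_ratio_difference(
            ilr_inverse(z1, basis, MINUTES_PER_DAY), ilr_inverse(z0, basis, MINUTES_PER_DAY)
        )
        b += 1

    alpha = 1.0 - ci_level
    lower, upper = np.percentile(draws, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
    table = pd.DataFrame(
        {
            "component": list(COMPONENTS),
            "estimate": estimate,
            "lower": lower,
            "upper": upper,
            "significant": (lower > 0) | (upper < 0),
        }
    )
    return LogRatioDifferenceResult(table, stage, B, seed, redraws)


# ---------------------------------------------------------------------------
# Effect modification
# ---------------------------------------------------------------------------

_MODIFIERS = ("sex", "work_status", "age_group", "day_type")

#: age strata bounds (years): 16-29, 30-59, 60+
_AGE_BINS = [-np.inf, 30, 60, np.inf]
_AGE_LABELS = ["16-29", "30-59", "60+"]


def _modifier_levels(df: pd.DataFrame, modifier: str) -> pd.Series:
    if modifier == "age_group":
        return pd.cut(df["age"], _AGE_BINS, right=False, labels=_AGE_LABELS).astype(str)
    if modifier not in _MODIFIERS:
        raise ValueError(f"modifier must be one of {_MODIFIERS}")
    return df[modifier].astype(str)


@dataclass(frozen=True)
class StratumResult:
    level: str
    n: int
    means: AdjustedGroupMeans
    log_ratio: LogRatioDifferenceResult


@dataclass(frozen=True)
class InteractionResult:
    modifier: str
    manova: ManovaResult  # joint test of the exposure x modifier term
    strata: dict[str, StratumResult] | None  # populated when interaction significant


def interaction_and_stratify(
    data,
    modifier: str,
    basis: np.ndarray | None = None,
    stage: str = "full",
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    statistic: str = "wilks",
    force_strata: bool = False,
) -> InteractionResult:
    """Exposure x modifier interaction test, with stratified reruns.

    Adds modifier main-effect and exposure x modifier columns to the staged
    MANOVA and jointly tests the interaction block.  When the interaction is
    significant at ``alpha`` (or ``force_strata``), the adjusted-means and
    bootstrap log-ratio analysis is rerun within each modifier level, with
    the modifier (age for ``age_group``) dropped from the covariates.
    """
    df = _table(data)
    basis = make_ilr_basis(len(COMPONENTS)) if basis is None else basis
    Z = _ilr_matrix(df, basis)
    enc = _encode(df)
    X, cols = _design(enc, stage)

    levels = _modifier_levels(df, modifier)
    uniq = sorted(levels.unique())
    if len(uniq) < 2:
        raise ValueError(f"modifier {modifier!r} has fewer than 2 levels")
    cross = pd.crosstab(levels, df["active_travel"])
    if (cross == 0).any().any() or cross.shape[1] < 2:
        raise ValueError(f"empty stratum-by-exposure cell for modifier {modifier!r}")

    # dummy-code modifier levels beyond the first; drop collinear main
    # effects already in the design (e.g. sex when stage includes it)
    dummies = pd.get_dummies(levels, drop_first=True).astype(float)
    main_blocks, inter_blocks = [], []
    exposure = enc["exposure"].to_numpy()
    for c in dummies.columns:
        v = dummies[c].to_numpy()
        trial = np.column_stack([X, v])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            main_blocks.append(v)
            X = trial
        inter_blocks.append(exposure * v)
    inter = np.column_stack(inter_blocks)
    X_full = np.column_stack([X, inter])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("rank-deficient interaction design")

    _, E = _ols_multi(X_full, Z)
    _, E_red = _ols_multi(X, Z)
    H = E_red - E
    ve = len(df) - X_full.shape[1]
    fn = {"wilks": _wilks_f, "pillai": _pillai_f}[statistic]
    value, F, df1, df2, p = fn(E, H, inter.shape[1], ve)
    manova = ManovaResult(
        statistic, value, F, df1, df2, p, stage, term=f"exposure:{modifier}"
    )

    strata = None
    if p < alpha or force_strata:
        drop = {"sex": "female", "work_status": "working", "day_type": "weekend"}.get(
            modifier, "age"
        )
        sub_stage_cols = [c for c in STAGES[stage] if c != drop]
        stratum_stage = _register_stage(stage, drop, sub_stage_cols)
        strata = {}
        rng = np.random.default_rng(seed)
        for lv in uniq:
            sub = df[levels == lv]
            fit = fit_ilr_models(sub, basis, stratum_stage)
            means = adjusted_group_means(fit)
            lr = bootstrap_log_ratio_ci(
                sub, basis, stratum_stage, B=B, seed=int(rng.integers(2**31 - 1))
            )
            strata[lv] = StratumResult(lv, len(sub), means, lr)
    return InteractionResult(modifier, manova, strata)


def _register_stage(stage: str, dropped: str, cols: list[str]) -> str:
    """Stage variant with one covariate removed (for stratified reruns)."""
    name = f"{stage}_minus_{dropped}"
    STAGES.setdefault(name, cols)
    return name
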