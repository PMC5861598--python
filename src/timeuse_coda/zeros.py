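"""Rounded-zero detection and replacement for slot-diary compositions.

A 10-minute slot diary cannot record activities shorter than one slot, so a
recorded zero in a small component (leisure MVPA above all) is treated as a
*rounded* zero: a positive duration below the 10-minute detection limit.
Log-ratio machinery requires strictly positive parts, so zeros are replaced
before analysis:

- :func:`impute_augmentation` — the primary method: each zero is replaced
  by a draw from a lognormal distribution conditioned on the row's non-zero
  log-ratio structure and truncated to (0, detection limit), iteratively
  refitted over a fixed number of sweeps (a bounded conditional-redraw
  interpretation of log-ratio data-augmentation; see docs/methods.md).
- :func:`impute_fixed` — the sensitivity analysis: every zero becomes a
  fixed small value (default 1 minute).

Both draw the replacement time multiplicatively from the other components,
so each imputed row still sums to 1440 and the ratios among originally
positive parts are untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .taxonomy import COMPONENTS

__all__ = [
    "ZeroPatternSummary",
    "ImputedCompositions",
    "zero_pattern_summary",
    "impute_augmentation",
    "impute_fixed",
]

MINUTES_PER_DAY = 1440.0


def _parts_matrix(X) -> tuple[np.ndarray, pd.DataFrame | None]:
    """Accept an N x 6 array or a compositions DataFrame with part columns."""
    if isinstance(X, pd.DataFrame):
        M = X[list(COMPONENTS)].to_numpy(dtype=float)
        return M, X
    M = np.atleast_2d(np.asarray(X, dtype=float))
    if M.shape[1] != len(COMPONENTS):
        raise ValueError(f"expected {len(COMPONENTS)} part columns, got {M.shape[1]}")
    return M, None


def _check_rows(M: np.ndarray) -> None:
    if np.any(M < 0):
        raise ValueError("negative part minutes")
    if not np.allclose(M.sum(axis=1), MINUTES_PER_DAY, atol=1e-6):
        raise ValueError("every row must sum to 1440 minutes before imputation")
    if np.any((M > 0).sum(axis=1) == 0):
        raise ValueError("a row of all zeros cannot be imputed")


@dataclass(frozen=True)
class ZeroPatternSummary:
    """Zero counts per component and the frequency table of zero patterns."""

    n: int
    zero_counts: pd.Series  # per component
    zero_pct: pd.Series
    patterns: pd.DataFrame  # one row per distinct zero/non-zero pattern

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "zero_counts": self.zero_counts.to_dict(),
            "zero_pct": self.zero_pct.round(2).to_dict(),
            "n_patterns": len(self.patterns),
        }


def zero_pattern_summary(X) -> ZeroPatternSummary:
    """Tabulate per-component zeros and the distinct zero/non-zero patterns.

    Patterns are reported as boolean columns (True = component reported,
    i.e. non-zero) sorted by frequency, the standard way of showing that
    e.g. 'everything but leisure MVPA' dominates a diary sample.
    """
    M, _ = _parts_matrix(X)
    _check_rows(M)
    nz = M > 0
    zero_counts = pd.Series((~nz).sum(axis=0), index=list(COMPONENTS), name="zeros")
    pat = pd.DataFrame(nz, columns=list(COMPONENTS))
    patterns = (
        pat.value_counts()
        .rename("count")
        .reset_index()
        .sort_values("count", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    patterns["pct"] = 100.0 * patterns["count"] / len(M)
    return ZeroPatternSummary(
        n=len(M),
        zero_counts=zero_counts,
        zero_pct=100.0 * zero_counts / len(M),
        patterns=patterns,
    )


@dataclass(frozen=True)
class ImputedCompositions:
    """Strictly positive minute matrix with per-cell imputation flags."""

    data: pd.DataFrame  # same layout as the input compositions table
    imputed: np.ndarray = field(repr=False)  # boolean N x 6, True where replaced
    method: str = "augmentation"
    detection_limit: float = 10.0
    seed: int | None = None

    @property
    def parts(self) -> np.ndarray:
        return self.data[list(COMPONENTS)].to_numpy(dtype=float)

    def n_imputed(self) -> int:
        return int(self.imputed.sum())


def _assemble(X, M_new, zeros, method, limit, seed) -> ImputedCompositions:
    _, df = _parts_matrix(X)
    if df is not None:
        out = df.copy()
        out[list(COMPONENTS)] = M_new
    else:
        out = pd.DataFrame(M_new, columns=list(COMPONENTS))
    return ImputedCompositions(
        data=out, imputed=zeros, method=method, detection_limit=limit, seed=seed
    )


def _rescale_rows(M: np.ndarray, zeros: np.ndarray, filled: np.ndarray) -> np.ndarray:
    """Insert imputed values and shrink the non-zero parts multiplicatively
    so each row again totals 1440 (ratios among them preserved exactly)."""
    out = M.astype(float).copy()
    out[zeros] = filled[zeros]
    imputed_total = np.where(zeros, out, 0.0).sum(axis=1)
    pos_total = np.where(zeros, 0.0, M).sum(axis=1)
    scale = (MINUTES_PER_DAY - imputed_total) / pos_total
    out[~zeros] = (M * scale[:, None])[~zeros]
    return out


def impute_fixed(X, value: float = 1.0) -> ImputedCompositions:
    """Replace every zero with a fixed small value (default 1 minute).

    Deterministic sensitivity-analysis companion to the augmentation
    method.  Warns (does not fail) when ``value`` is at least as large as
    the smallest positive observed part, since that would invert orderings.
    """
    M, _ = _parts_matrix(X)
    _check_rows(M)
    if value <= 0:
        raise ValueError("imputation value must be positive")
    smallest_pos = M[M > 0].min()
    if value >= smallest_pos:
        warnings.warn(
            f"imputed value {value} >= smallest positive part {smallest_pos}; "
            "component orderings may invert",
            stacklevel=2,
        )
    zeros = M == 0
    filled = np.full_like(M, value)
    out = _rescale_rows(M, zeros, filled)
    return _assemble(X, out, zeros, "fixed", value, None)


def impute_augmentation(
    X, detection_limit: float = 10.0, seed: int = 0, sweeps: int = 10
) -> ImputedCompositions:
    """Replace zeros with conditioned draws below the detection limit.

    Algorithm (all on the log scale; fully seeded):

    1. initialise every zero cell at 65% of the detection limit;
    2. for each sweep, compute each row's reference level (mean log of the
       current parts) and fit, per component with zeros, the mean and SD of
       the log-ratio to the row reference using only originally observed
       cells; redraw every zero cell from the implied lognormal truncated
       above at the detection limit;
    3. after the final sweep, shrink the originally positive parts of each
       affected row multiplicatively so the row totals 1440 again.

    Imputed values are strictly inside (0, detection_limit); originally
    positive parts never increase and keep their mutual ratios exactly.
    """
    if detection_limit <= 0:
        raise ValueError("detection_limit must be positive")
    M, _ = _parts_matrix(X)
    _check_rows(M)
    zeros = M == 0
    if not zeros.any():
        return _assemble(X, M.copy(), zeros, "augmentation", detection_limit, seed)

    rng = np.random.default_rng(seed)
    W = M.astype(float).copy()
    W[zeros] = 0.65 * detection_limit
    obs = ~zeros
    log_limit = np.log(detection_limit)

    for _ in range(max(1, sweeps)):
        L = np.log(W)
        row_ref = L.mean(axis=1)  # current row reference (clr denominator)
        # per-component log-ratio moments from originally observed cells
        for j in np.flatnonzero(zeros.any(axis=0)):
            oj = obs[:, j]
            ratios = L[oj, j] - row_ref[oj]
            mu = ratios.mean() if oj.any() else 0.0
            sd = ratios.std(ddof=1) if oj.sum() > 1 else 1.0
            sd = max(sd, 1e-6)
            rows = np.flatnonzero(zeros[:, j])
            loc = mu + row_ref[rows]
            b = (log_limit - loc) / sd
            draw = stats.truncnorm.rvs(-np.inf, b, loc=loc, scale=sd, random_state=rng)
            W[rows, j] = np.exp(draw)

    out = _rescale_rows(M, zeros, W)
    # numerical guard: draws are strictly below the limit by construction
    assert np.all(out[zeros] > 0) and np.all(out[zeros] < detection_limit)
    return _assemble(X, out, zeros, "augmentation", detection_limit, seed)
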