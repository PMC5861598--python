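"""Synthetic harmonised time-use diary generator with known ground truth.

Emulates the structure of a harmonised national time-use survey: each
participant keeps one weekday and one weekend diary of 144 ten-minute slots
starting at 4 am, each slot carrying a numeric primary-activity ('what')
code and a location/mode ('where') code.  The statistical model mirrors the
downstream analysis: a participant's latent six-part composition is a
logistic-normal draw whose ilr-scale mean is

    ilr(base) + exposed * ilr(perturbation) + covariate_effects' c,

with c = (standardised age, female, working, weekend) and multivariate
normal noise on the ilr scale.  Active-travel exposure follows a logistic
model on the covariates.  Latent proportions are discretised to 10-minute
slots by largest remainder — the same rounding that manufactures the
characteristic zero inflation of leisure MVPA in slot diaries — and laid
out into a plausible daily schedule that passes every quality-control rule.

``corrupt_diaries`` then injects diaries that fail each QC rule at
configurable rates, recording which rule each corrupted diary should fail,
so QC accounting can be tested against known counts.

Default parameter values are calibrated to a large UK 2014/15 time-use
survey analysis of active travel: the dispersion comes from its published
pairwise variation matrix, the base composition and group perturbation are
tuned so that the *pipeline's* post-imputation adjusted-mean contrast and
the ~69% leisure-MVPA zero share reproduce the survey-scale pattern, and
exposure prevalence is ~40%.  See docs/methods.md for the calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coda import close, ilr, ilr_inverse, make_ilr_basis
from .taxonomy import (
    COMPONENTS,
    DEFAULT_MAPPING,
    WHERE_BICYCLE,
    WHERE_CAR,
    WHERE_HOME,
    WHERE_ON_FOOT,
    WHERE_OTHER,
    WHERE_PUBLIC_TRANSPORT,
    WHERE_WORK,
    ComponentMapping,
)

__all__ = [
    "GeneratorConfig",
    "CorruptionRates",
    "GroundTruth",
    "generate_population",
    "generate_compositions",
    "corrupt_diaries",
    "implied_prevalence",
    "ilr_covariance_from_variation",
    "DEFAULT_VARIATION_MATRIX",
]

N_SLOTS = 144
MISSING_CODE = -1

# ---------------------------------------------------------------------------
# Default calibration constants (see docs/methods.md, "Generator calibration")
# ---------------------------------------------------------------------------

#: Published pairwise log-ratio variation matrix of the six-part time-use
#: composition (order: sleep, leisure MVPA, screen, non-discretionary,
#: travel, other) used to calibrate the default dispersion.
DEFAULT_VARIATION_MATRIX = np.array(
    [
        [0.00, 1.35, 0.79, 0.34, 1.63, 1.40],
        [1.35, 0.00, 3.60, 1.86, 3.63, 3.75],
        [0.79, 3.60, 0.00, 1.52, 3.34, 2.70],
        [0.34, 1.86, 1.52, 0.00, 1.66, 2.12],
        [1.63, 3.63, 3.34, 1.66, 0.00, 2.87],
        [1.40, 3.75, 2.70, 2.12, 2.87, 0.00],
    ]
)

#: Latent no-active-travel mean composition (proportions of the day).
#: Sleep/screen/non-discretionary/travel/other levels follow the
#: survey-scale adjusted means; the (small) latent MVPA level is calibrated
#: so 10-min slot rounding reproduces the ~69% MVPA zero share.
DEFAULT_BASE_COMPOSITION = (0.426928, 0.000622, 0.112986, 0.344469, 0.029727, 0.085269)

#: Multiplicative latent group contrast (active-travel vs not), calibrated
#: so the *pipeline's* post-imputation adjusted-mean log-ratio differences
#: match the survey-scale pattern.  The latent MVPA factor is much larger
#: than the post-imputation ratio it produces because slot rounding and
#: zero imputation strongly attenuate contrasts in a zero-heavy component.
DEFAULT_GROUP_PERTURBATION = (0.97808, 14.18386, 0.92521, 1.05312, 1.54534, 1.25585)

#: Variant of the default contrast with the non-discretionary component
#: calibrated so its post-pipeline adjusted-mean contrast is null.  The
#: survey analysis found no distinguishable non-discretionary difference,
#: so emulations of its *significance pattern* (five components different,
#: non-discretionary not) inject no non-discretionary effect.
GROUP_PERTURBATION_NULL_NONDISC = (0.97808, 14.18386, 0.92521, 1.04437, 1.54534, 1.25585)

#: Logistic model for exposure: intercept + coefficients on
#: (standardised age, female, working).  Intercept calibrated to ~40%
#: prevalence given the default covariate distribution.
DEFAULT_ACTIVE_TRAVEL_LOGIT = (-0.6685, -0.30, 0.10, 0.40)

#: Covariate effects on the 5 ilr coordinates; rows = (age_z, female,
#: working, weekend).  Modest, plausible shifts (working days reallocate
#: time into non-discretionary activity, weekends out of it, etc.).
DEFAULT_COVARIATE_EFFECTS = np.array(
    [
        [0.05, -0.10, 0.15, -0.15, -0.05],  # age (per SD)
        [0.02, -0.05, -0.08, 0.10, 0.00],  # female
        [-0.10, -0.05, -0.15, 0.35, 0.05],  # working or studying
        [0.15, 0.05, 0.10, -0.40, -0.05],  # weekend diary day
    ]
)


#: Survey-scale model-adjusted compositional means (minutes/day) used as
#: the calibration target for the default group contrast.
STUDY_ADJUSTED_MEANS_NONE = (615.7, 9.5, 163.1, 497.0, 42.9, 111.9)
STUDY_ADJUSTED_MEANS_SOME = (577.2, 20.8, 144.7, 502.6, 62.2, 132.5)


def ilr_covariance_from_variation(
    T: np.ndarray, basis: np.ndarray | None = None, eig_floor: float = 1e-6
) -> np.ndarray:
    """ilr-scale covariance implied by a pairwise variation matrix.

    Double-centres -T/2 to the clr covariance (the classical-scaling
    identity T_ij = S_ii + S_jj - 2 S_ij) and projects onto the ilr basis.
    A printed, rounded variation matrix need not be exactly Euclidean-
    embeddable, so eigenvalues are floored at ``eig_floor`` to return a
    symmetric positive-definite matrix.
    """
    T = np.asarray(T, dtype=float)
    D = T.shape[0]
    G = np.eye(D) - np.ones((D, D)) / D
    S = -0.5 * G @ T @ G
    V = make_ilr_basis(D) if basis is None else basis
    Si = V @ S @ V.T
    w, U = np.linalg.eigh(Si)
    Si = (U * np.maximum(w, eig_floor)) @ U.T
    return 0.5 * (Si + Si.T)


DEFAULT_NOISE_COVARIANCE = ilr_covariance_from_variation(DEFAULT_VARIATION_MATRIX)


@dataclass(frozen=True)
class CorruptionRates:
    """Per-rule probabilities that a diary is degraded to fail that QC rule.

    Defaults emulate the survey-scale removal pattern: rare general-QC
    failures, a large share of diaries with ineligible (unreported) time and
    a handful reporting no sleep.
    """

    missing_time: float = 0.0005
    few_episodes: float = 0.0005
    missing_basic: float = 0.0004
    ineligible: float = 0.30
    no_sleep: float = 0.001

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.missing_time,
                self.few_episodes,
                self.missing_basic,
                self.ineligible,
                self.no_sleep,
            ]
        )

    def validate(self) -> None:
        r = self.as_array()
        if np.any((r < 0) | (r > 1)):
            raise ValueError("corruption rates must lie in [0, 1]")


RULE_NAMES = ("missing_time", "few_episodes", "missing_basic", "ineligible", "no_sleep")

_NONE_RATES = CorruptionRates(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth parameters of the synthetic diary population."""

    n_participants: int = 2000
    base_composition: tuple[float, ...] = DEFAULT_BASE_COMPOSITION
    group_perturbation: tuple[float, ...] = DEFAULT_GROUP_PERTURBATION
    covariate_effects: np.ndarray = field(
        default_factory=lambda: DEFAULT_COVARIATE_EFFECTS.copy()
    )
    noise_covariance: np.ndarray = field(
        default_factory=lambda: DEFAULT_NOISE_COVARIANCE.copy()
    )
    active_travel_logit: tuple[float, ...] = DEFAULT_ACTIVE_TRAVEL_LOGIT
    corruption_rates: CorruptionRates = field(default_factory=CorruptionRates)
    seed: int = 0
    age_range: tuple[float, float] = (16.0, 90.0)
    p_female: float = 0.5
    p_working: float = 0.5
    #: fraction of an exposed participant's travel slots done by active mode
    active_fraction_of_travel: float = 0.8
    #: exposed participants' mode mix: P(walk only), P(cycle only), P(both)
    mode_split: tuple[float, float, float] = (0.94, 0.035, 0.025)

    def validate(self) -> None:
        base = np.asarray(self.base_composition, dtype=float)
        if base.shape != (6,) or np.any(base <= 0):
            raise ValueError("base_composition must be 6 strictly positive parts")
        pert = np.asarray(self.group_perturbation, dtype=float)
        if pert.shape != (6,) or np.any(pert <= 0):
            raise ValueError("group_perturbation must be 6 positive reals")
        S = np.asarray(self.noise_covariance, dtype=float)
        if S.shape != (5, 5) or not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("noise_covariance must be symmetric 5x5")
        if np.linalg.eigvalsh(S).min() <= 0:
            raise ValueError("noise_covariance must be positive definite")
        C = np.asarray(self.covariate_effects, dtype=float)
        if C.shape != (4, 5):
            raise ValueError("covariate_effects must be 4x5 (age_z, female, working, weekend)")
        if len(self.active_travel_logit) != 4:
            raise ValueError("active_travel_logit must be (intercept, age_z, female, working)")
        self.corruption_rates.validate()
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        if not 0 < self.active_fraction_of_travel <= 1:
            raise ValueError("active_fraction_of_travel must be in (0, 1]")

    def age_standardiser(self) -> tuple[float, float]:
        lo, hi = self.age_range
        return (lo + hi) / 2.0, (hi - lo) / np.sqrt(12.0)


@dataclass(frozen=True)
class GroundTruth:
    """Exact group-level parameters used by the generator."""

    mean_composition_none: np.ndarray  # minutes/day at covariate reference
    mean_composition_some: np.ndarray
    mean_ilr_none: np.ndarray
    mean_ilr_some: np.ndarray
    delta_ilr: np.ndarray
    log_ratio_difference: np.ndarray  # ln(some_i / none_i), latent scale
    implied_prevalence: float

    def to_dict(self) -> dict:
        return {
            "components": list(COMPONENTS),
            "mean_composition_none_min": self.mean_composition_none.tolist(),
            "mean_composition_some_min": self.mean_composition_some.tolist(),
            "mean_ilr_none": self.mean_ilr_none.tolist(),
            "mean_ilr_some": self.mean_ilr_some.tolist(),
            "delta_ilr": self.delta_ilr.tolist(),
            "log_ratio_difference": self.log_ratio_difference.tolist(),
            "implied_prevalence": self.implied_prevalence,
        }


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def implied_prevalence(config: GeneratorConfig, n_nodes: int = 64) -> float:
    """Exposure prevalence implied by the logistic model and covariate mix.

    Integrates the logistic mean over standardised age (uniform on the
    configured range) with Gauss-Legendre quadrature, averaging over the
    four female x working cells at their Bernoulli weights.
    """
    b0, b_age, b_fem, b_work = config.active_travel_logit
    mid, sd = config.age_standardiser()
    lo, hi = config.age_range
    zlo, zhi = (lo - mid) / sd, (hi - mid) / sd
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    z = 0.5 * (zhi - zlo) * nodes + 0.5 * (zhi + zlo)
    w = weights / weights.sum()
    total = 0.0
    for fem, p_f in ((0, 1 - config.p_female), (1, config.p_female)):
        for wk, p_w in ((0, 1 - config.p_working), (1, config.p_working)):
            eta = b0 + b_age * z + b_fem * fem + b_work * wk
            total += p_f * p_w * float(_sigmoid(eta) @ w)
    return total


def _ground_truth(config: GeneratorConfig) -> GroundTruth:
    base = close(np.asarray(config.base_composition, dtype=float))
    pert = close(np.asarray(config.group_perturbation, dtype=float))
    z_none = ilr(base)
    z_some = z_none + ilr(pert)
    comp_none = ilr_inverse(z_none, kappa=1440.0)
    comp_some = ilr_inverse(z_some, kappa=1440.0)
    return GroundTruth(
        mean_composition_none=comp_none,
        mean_composition_some=comp_some,
        mean_ilr_none=z_none,
        mean_ilr_some=z_some,
        delta_ilr=ilr(pert),
        log_ratio_difference=np.log(comp_some / comp_none),
        implied_prevalence=implied_prevalence(config),
    )


def _sample_cohort(config: GeneratorConfig, rng: np.random.Generator):
    """Sample covariates and exposure for the participant cohort."""
    n = config.n_participants
    lo, hi = config.age_range
    age = rng.uniform(lo, hi, n)
    female = rng.random(n) < config.p_female
    working = rng.random(n) < config.p_working
    mid, sd = config.age_standardiser()
    age_z = (age - mid) / sd
    b0, b_age, b_fem, b_work = config.active_travel_logit
    eta = b0 + b_age * age_z + b_fem * female + b_work * working
    exposed = rng.random(n) < _sigmoid(eta)
    return age, age_z, female, working, exposed


def largest_remainder(P: np.ndarray, total: int = N_SLOTS) -> np.ndarray:
    """Discretise row proportions into integer counts summing to ``total``.

    Floors the raw counts, then hands the remaining units to the largest
    fractional parts (ties broken by part order).  This is exactly the
    rounding a 10-minute slot diary imposes: latent durations below about
    half a slot round to zero, which is the mechanism behind rounded zeros
    in small components such as leisure MVPA.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    raw = P * total
    base = np.floor(raw).astype(np.int64)
    short = total - base.sum(axis=1)
    rem = raw - base
    ranks = np.argsort(np.argsort(-rem, axis=1, kind="stable"), axis=1, kind="stable")
    base += ranks < short[:, None]
    return base


def _slot_counts(
    config: GeneratorConfig,
    rng: np.random.Generator,
    age_z: np.ndarray,
    female: np.ndarray,
    working: np.ndarray,
    weekend: np.ndarray,
    exposed: np.ndarray,
) -> np.ndarray:
    """Realise each diary's 6-part slot counts from the latent model."""
    config.validate()
    z_base = ilr(close(np.asarray(config.base_composition, dtype=float)))
    delta = ilr(close(np.asarray(config.group_perturbation, dtype=float)))
    C = np.asarray(config.covariate_effects, dtype=float)
    covs = np.column_stack(
        [age_z, female.astype(float), working.astype(float), weekend.astype(float)]
    )
    mean_z = z_base + np.outer(exposed.astype(float), delta) + covs @ C
    L = np.linalg.cholesky(np.asarray(config.noise_covariance, dtype=float))
    z = mean_z + rng.standard_normal(mean_z.shape) @ L.T
    p = ilr_inverse(z)
    counts = largest_remainder(p, N_SLOTS)

    idx = np.arange(len(counts))
    # sleep is never entirely absent in a valid diary day
    no_sleep = counts[:, 0] == 0
    if no_sleep.any():
        donor = counts[no_sleep].copy()
        donor[:, 0] = -1
        j = donor.argmax(axis=1)
        counts[no_sleep, j] -= 1
        counts[no_sleep, 0] += 1
    # eating and personal care happen every day: keep >= 2 'other' slots so
    # the basic-activity categories of a valid diary are always present
    o = COMPONENTS.index("other")
    for _ in range(2):
        low = counts[:, o] < 2
        if not low.any():
            break
        donor = counts[low].copy()
        donor[:, o] = -1
        donor[:, 0] = np.where(donor[:, 0] > 1, donor[:, 0], -1)
        j = donor.argmax(axis=1)
        counts[idx[low], j] -= 1
        counts[idx[low], o] += 1
    # an exposed participant's mode codes require at least one travel slot
    t = COMPONENTS.index("travel")
    need = exposed & (counts[:, t] == 0)
    if need.any():
        donor = counts[need].copy()
        donor[:, t] = -1
        donor[:, 0] = np.where(donor[:, 0] > 1, donor[:, 0], -1)  # keep sleep >= 1
        j = donor.argmax(axis=1)
        counts[idx[need], j] -= 1
        counts[idx[need], t] += 1
    return counts


# Alternate same-component codes used to split long runs so every generated
# diary reports at least seven activity episodes.
_PARTNER = {
    110: 120, 120: 110,
    210: 531, 231: 525,
    310: 331, 331: 310, 341: 361, 361: 331, 321: 310,
    510: 525, 525: 531, 531: 510,
    611: 621, 621: 611,
    821: 831, 831: 821,
    901: 921, 911: 921, 921: 901,
}


def _runs(codes: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of identical codes as (start, length, code)."""
    out = []
    start = 0
    for i in range(1, len(codes) + 1):
        if i == len(codes) or codes[i] != codes[start]:
            out.append((start, i - start, int(codes[start])))
            start = i
    return out


def _layout_day(
    counts: np.ndarray,
    exposed: bool,
    active_codes: np.ndarray | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Arrange component slot counts into a plausible 144-slot day.

    The template day starts with the tail of the night's sleep, runs through
    personal care, meals, travel legs, work/chores, leisure and screen time,
    and ends with the evening's sleep.  Runs are split with alternate
    same-component codes until at least seven episodes are present, so an
    uncorrupted diary always passes general quality control.
    """
    sleep, mvpa, screen, nond, trav, other = (int(c) for c in counts)

    def split(n: int, frac: float) -> tuple[int, int]:
        a = min(n, int(round(n * frac)))
        return a, n - a

    sleep_m, sleep_n = split(sleep, 0.35)
    eat1 = min(1, other)
    rest = other - eat1
    pc = min(1, rest)
    rest -= pc
    eat2 = min(3, rest)
    social = rest - eat2
    t1, t2 = split(trav, 0.5)
    n1, n2 = split(nond, 0.6)
    s1, s2 = split(screen, 0.5)

    blocks = [
        (110, sleep_m, WHERE_HOME),
        (210, eat1, WHERE_HOME),
        (231, pc, WHERE_HOME),
        (901, t1, None),
        (310, n1, WHERE_WORK),
        (210, eat2, WHERE_WORK),
        (341, n2, WHERE_HOME),
        (911, t2, None),
        (621, mvpa, WHERE_OTHER),
        (821, s1, WHERE_HOME),
        (510, social, WHERE_HOME),
        (831, s2, WHERE_HOME),
        (110, sleep_n, WHERE_HOME),
    ]
    what = np.concatenate([np.full(n, code) for code, n, _ in blocks if n > 0])
    where = np.concatenate([np.full(n, -1 if w is None else w) for code, n, w in blocks if n > 0])

    # guarantee >= 7 episodes by splitting the longest runs in half with an
    # alternate code from the same component (composition unchanged)
    for _ in range(20):
        runs = _runs(what)
        if len(runs) >= 7:
            break
        start, length, code = max(runs, key=lambda r: r[1])
        if length < 2:
            break
        half = start + length // 2
        what[half : start + length] = _PARTNER[code]

    # travel mode codes
    travel_pos = np.flatnonzero(where == -1)
    if travel_pos.size:
        modes = rng.choice([WHERE_CAR, WHERE_PUBLIC_TRANSPORT], size=travel_pos.size)
        if exposed and active_codes is not None:
            n_active = min(travel_pos.size, len(active_codes))
            modes[:n_active] = active_codes[:n_active]
        where[travel_pos] = modes
    return what, where


def _active_mode_codes(
    config: GeneratorConfig, rng: np.random.Generator, n_travel: int
) -> np.ndarray:
    """Active-mode where-codes for one exposed diary."""
    n_active = max(1, int(round(config.active_fraction_of_travel * n_travel)))
    n_active = min(n_active, max(n_travel, 1))
    p_walk, p_cycle, p_both = config.mode_split
    del p_both  # remainder of the unit interval
    u = rng.random()
    if u < p_walk:
        codes = np.full(n_active, WHERE_ON_FOOT)
    elif u < p_walk + p_cycle:
        codes = np.full(n_active, WHERE_BICYCLE)
    else:  # both modes; needs >= 2 active slots, otherwise degrade to walking
        codes = np.full(n_active, WHERE_ON_FOOT)
        if n_active >= 2:
            codes[0] = WHERE_BICYCLE
    return codes


def generate_population(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate the full diary population: one weekday and one weekend diary
    per participant.

    Returns ``(participants, diaries, truth)``: a participant covariate
    table, a long-format diary table (one row per 10-minute slot) and the
    exact ground-truth record used.  Deterministic for a fixed config.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    age, age_z, female, working, exposed = _sample_cohort(config, rng)

    participants = pd.DataFrame(
        {
            "participant_id": np.arange(1, n + 1),
            "age": np.round(age, 1),
            "sex": np.where(female, "female", "male"),
            "work_status": np.where(working, "working_or_studying", "other"),
            "active_travel_truth": exposed,
        }
    )

    frames = []
    for day_idx, day_type in enumerate(("weekday", "weekend"), start=1):
        weekend = np.full(n, day_type == "weekend")
        counts = _slot_counts(config, rng, age_z, female, working, weekend, exposed)
        what = np.empty((n, N_SLOTS), dtype=np.int64)
        where = np.empty((n, N_SLOTS), dtype=np.int64)
        t = COMPONENTS.index("travel")
        for i in range(n):
            active = (
                _active_mode_codes(config, rng, int(counts[i, t])) if exposed[i] else None
            )
            what[i], where[i] = _layout_day(counts[i], bool(exposed[i]), active, rng)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.repeat(np.arange(1, n + 1), N_SLOTS),
                    "diary_id": np.repeat(np.arange(1, n + 1) * 10 + day_idx, N_SLOTS),
                    "day_type": day_type,
                    "slot_index": np.tile(np.arange(N_SLOTS), n),
                    "what_code": what.ravel(),
                    "where_code": where.ravel(),
                    "missing": False,
                }
            )
        )
    diaries = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["participant_id", "diary_id", "slot_index"], kind="stable")
        .reset_index(drop=True)
    )
    return participants, diaries, _ground_truth(config)


def generate_compositions(
    config: GeneratorConfig, n: int | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Fast path: draw one diary day per participant and return the built
    six-part compositions directly, skipping the slot layout.

    Statistically identical to generate -> QC -> build -> select-one-diary on
    an uncorrupted population (slot counts come from the same latent model
    and largest-remainder rounding); used for Monte-Carlo experiments where
    only compositions and covariates matter.
    """
    if n is not None or seed is not None:
        config = replace(
            config,
            n_participants=n or config.n_participants,
            seed=config.seed if seed is None else seed,
        )
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.n_participants
    age, age_z, female, working, exposed = _sample_cohort(config, rng)
    weekend = rng.random(m) < 0.5
    counts = _slot_counts(config, rng, age_z, female, working, weekend, exposed)
    minutes = counts * 10.0
    df = pd.DataFrame(minutes, columns=list(COMPONENTS))
    df.insert(0, "participant_id", np.arange(1, m + 1))
    df["active_travel"] = exposed
    df["age"] = np.round(age, 1)
    df["sex"] = np.where(female, "female", "male")
    df["work_status"] = np.where(working, "working_or_studying", "other")
    df["day_type"] = np.where(weekend, "weekend", "weekday")
    return df, _ground_truth(config)


# ---------------------------------------------------------------------------
# Corruption: inject diaries that fail each QC rule
# ---------------------------------------------------------------------------


def _diary_arrays(diaries: pd.DataFrame):
    d = diaries.sort_values(["diary_id", "slot_index"], kind="stable")
    ids = d["diary_id"].to_numpy()[:: N_SLOTS]
    shape = (-1, N_SLOTS)
    return (
        d,
        ids,
        d["what_code"].to_numpy().reshape(shape).copy(),
        d["where_code"].to_numpy().reshape(shape).copy(),
        d["missing"].to_numpy().reshape(shape).copy(),
    )


def corrupt_diaries(
    diaries: pd.DataFrame,
    rates: CorruptionRates | None = None,
    seed: int = 0,
    mapping: ComponentMapping = DEFAULT_MAPPING,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Degrade randomly selected diaries so they fail specific QC rules.

    For each diary the five rules are tried in a fixed order and the first
    one triggered (independent Bernoulli draws at the configured rates) is
    applied, so each corrupted diary fails at a known stage:

    - ``missing_time``: 10 slots flagged missing (100 min > 90-min limit)
    - ``few_episodes``: day collapsed to 4 long episodes (< 7)
    - ``missing_basic``: eating and personal-care slots relabelled within the
      'other' component, leaving >= 2 of the 4 basic activities absent
    - ``ineligible``: 3 slots overwritten with placeholder code 9990, chosen
      among codes without a basic-activity category so no general rule trips
    - ``no_sleep``: all sleep slots relabelled to a hobby code

    Returns ``(diaries, log)`` where ``log`` lists (diary_id, rule) for each
    corrupted diary.  All rates zero returns the input unchanged.
    """
    rates = rates or _NONE_RATES
    rates.validate()
    r = rates.as_array()
    if not r.any():
        return diaries.copy(), pd.DataFrame({"diary_id": [], "rule": []}).astype(
            {"diary_id": np.int64, "rule": str}
        )

    rng = np.random.default_rng(seed)
    d, ids, W, Wh, M = _diary_arrays(diaries)
    u = rng.random((len(ids), 5))
    hit = u < r[None, :]
    rule_idx = np.where(hit.any(axis=1), hit.argmax(axis=1), -1)

    basic_of = mapping.basic_category
    log_rows = []
    for i in np.flatnonzero(rule_idx >= 0):
        rule = RULE_NAMES[rule_idx[i]]
        log_rows.append((int(ids[i]), rule))
        if rule == "missing_time":
            pos = rng.choice(N_SLOTS, size=10, replace=False)
            M[i, pos] = True
            W[i, pos] = MISSING_CODE
        elif rule == "few_episodes":
            W[i] = np.repeat([110, 210, 231, 310], [60, 6, 6, 72])
            Wh[i] = np.repeat([WHERE_HOME, WHERE_WORK], [72, 72])
            M[i] = False
        elif rule == "missing_basic":
            sel = np.isin(W[i], [210, 231])
            W[i, sel] = 525
        elif rule == "ineligible":
            cand = np.flatnonzero(
                ~M[i] & np.array([basic_of.get(int(c)) is None for c in W[i]])
            )
            if cand.size < 3:
                vals, cnt = np.unique(W[i][~M[i]], return_counts=True)
                cand = np.flatnonzero(W[i] == vals[cnt.argmax()])
            pos = rng.choice(cand, size=min(3, cand.size), replace=False)
            W[i, pos] = 9990
        elif rule == "no_sleep":
            sel = np.isin(W[i], mapping.codes_for("sleep"))
            W[i, sel] = 525

    out = d.copy()
    out["what_code"] = W.ravel()
    out["where_code"] = Wh.ravel()
    out["missing"] = M.ravel()
    log = pd.DataFrame(log_rows, columns=["diary_id", "rule"])
    return out.reset_index(drop=True), log
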