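"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a two-wave school cohort: correlated, bounded,
integer questionnaire subscale scores whose marginal means/SDs match the
published sample characteristics; a T1->T2 retest process whose change SD
equals Sdiff = SD*sqrt(2*(1-r)); severity-dependent help-seeking (more
symptomatic students are more likely to report support, mimicking the
confound by which deterioration prompts contact with services);
planted-effect machinery for parameter-recovery studies; and a differential
attrition mechanism (male, deprived, Black/Other-ethnicity and more
symptomatic students are less likely to be retained at follow-up).

Scores are realized as latent Gaussians, rounded and clipped to the
integer scale range.  Rounding and clipping distort moments, so the latent
location/scale — and the latent retest correlation — are solved numerically
so that the *discrete* scores hit the configured targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .cohort import (
    DURATION_LEVELS,
    ETHNICITY_LEVELS,
    OUTCOME_SUBSCALES,
    SUBSCALE_RANGES,
    StudentRecord,
    SubscaleScores,
)
from .reliable import DEFAULT_SDIFF

N_SCHOOLS = 118

#: Table-1 moments of the analysed sample.
DEFAULT_SUBSCALE_MEANS = {
    "emotional": 2.61,
    "conduct": 1.96,
    "hyperactivity": 3.72,
    "peer": 1.81,
    "impact": 0.72,
}
DEFAULT_SUBSCALE_SDS = {
    "emotional": 2.18,
    "conduct": 1.88,
    "hyperactivity": 2.35,
    "peer": 1.74,
    "impact": 1.71,
}


def reliability_from_sdiff(sd: float, sdiff: float) -> float:
    """Retest reliability implied by a scale SD and its Sdiff."""
    return 1.0 - sdiff**2 / (2.0 * sd**2)


def sdiff_from_reliability(sd: float, r: float) -> float:
    """Sdiff = SD * sqrt(2 * (1 - r))."""
    return sd * math.sqrt(2.0 * (1.0 - r))


#: Outcome-subscale reliabilities back-derived from the published Sdiff
#: values and SDs (r = 1 - Sdiff^2 / (2 SD^2)); peer/impact have no
#: published Sdiff and get a conventional 0.70.
DEFAULT_RETEST_RELIABILITY = {
    name: reliability_from_sdiff(DEFAULT_SUBSCALE_SDS[name], DEFAULT_SDIFF[name])
    for name in OUTCOME_SUBSCALES
} | {"peer": 0.70, "impact": 0.70}

DEFAULT_ETHNICITY_PREVALENCE = {
    "White": 0.7871,
    "Asian": 0.0972,
    "Black": 0.0606,
    "Mixed": 0.0402,
    "Other": 0.0149,
}
DEFAULT_DURATION_PREVALENCE = {
    "none": 0.5788,
    "<1mo": 0.1812,
    "1-5mo": 0.0964,
    "6-12mo": 0.0408,
    ">1yr": 0.1028,
}
DEFAULT_SUPPORT_PREVALENCE = {
    "counsellor": 0.1241,
    "peer_mentor": 0.1002,
    "other": 0.1469,
}

#: Category-propensity intercepts (improvement, deterioration) vs no change,
#: set to the full-sample change rates (10.03% / 11.14% / 78.83%).
DEFAULT_CATEGORY_LOGITS = (-2.062, -1.957)

#: Attrition log-odds (dropout direction) fixed once to reproduce ~63%
#: retention with the published sign pattern; z_* terms act per SD of the
#: baseline score.
DEFAULT_ATTRITION_LOG_ODDS = {
    "male": 0.25,
    "fsm": 0.30,
    "ethnicity_black": 0.35,
    "ethnicity_other": 0.35,
    "z_emotional": 0.10,
    "z_conduct": 0.15,
    "z_hyperactivity": 0.10,
    "z_peer": 0.10,
    "z_impact": 0.10,
}
#: Tuned once against the log-odds above so that overall retention is 0.63.
DEFAULT_ATTRITION_INTERCEPT = -0.751

#: Planted-effect term vocabulary (continuous terms act per SD around the
#: configured moments).
EFFECT_TERMS = (
    "t1_emotional",
    "t1_conduct",
    "t1_hyperactivity",
    "t1_peer",
    "t1_impact",
    "gender_female",
    "ethnicity_other",
    "fsm",
    "sen",
    "attainment",
    "school_climate",
    "quality_of_life",
    "duration_<1mo",
    "duration_1-5mo",
    "duration_6-12mo",
    "duration_>1yr",
    "support_counsellor",
    "support_peer_mentor",
    "support_other",
)


class CohortConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class AttritionConfig:
    """Differential loss to follow-up.

    Dropout probability is inverse-logit(intercept + sum of log-odds
    terms); positive log-odds increase dropout.
    """

    enabled: bool = True
    intercept: float = DEFAULT_ATTRITION_INTERCEPT
    log_odds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ATTRITION_LOG_ODDS)
    )


@dataclass(frozen=True)
class CohortConfig:
    """Everything the generator needs; defaults emulate the study sample."""

    n: int = 9074
    seed: int = 0
    subscale_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBSCALE_MEANS)
    )
    subscale_sds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBSCALE_SDS)
    )
    retest_reliability: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RETEST_RELIABILITY)
    )
    inter_subscale_corr: float = 0.3
    female_prevalence: float = 0.5192
    fsm_prevalence: float = 0.1812
    sen_prevalence: float = 0.2128
    ethnicity_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ETHNICITY_PREVALENCE)
    )
    duration_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DURATION_PREVALENCE)
    )
    support_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUPPORT_PREVALENCE)
    )
    attainment_mean: float = 28.29
    attainment_sd: float = 5.44
    school_climate_mean: float = 9.44
    school_climate_sd: float = 3.09
    quality_of_life_mean: float = 25.38
    quality_of_life_sd: float = 5.50
    helpseek_severity_slope: float = 0.5
    effect_log_odds: Mapping[str, Tuple[float, float]] = field(
        default_factory=dict
    )
    #: "auto": the change category is driven by the latent propensity iff
    #: some planted effect is nonzero, otherwise T2 follows the pure retest
    #: process (change SD = Sdiff).  "propensity" forces the category draw
    #: even with zero effects — the exact no-association null in which the
    #: change category is independent of every predictor.  "retest" forces
    #: the pure retest process, ignoring planted effects.
    change_process: str = "auto"
    category_logits: Tuple[float, float] = DEFAULT_CATEGORY_LOGITS
    attrition: AttritionConfig = field(default_factory=AttritionConfig)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise CohortConfigError(f"n must be >= 0, got {self.n}")
        for label, vec in (
            ("ethnicity_prevalence", self.ethnicity_prevalence),
            ("duration_prevalence", self.duration_prevalence),
        ):
            total = sum(vec.values())
            if abs(total - 1.0) > 1e-9:
                raise CohortConfigError(
                    f"{label} must sum to 1 (got {total!r})"
                )
            if any(not 0.0 <= p <= 1.0 for p in vec.values()):
                raise CohortConfigError(f"{label} entries must lie in [0, 1]")
        for label, p in (
            ("female_prevalence", self.female_prevalence),
            ("fsm_prevalence", self.fsm_prevalence),
            ("sen_prevalence", self.sen_prevalence),
            *((f"support {k}", v) for k, v in self.support_prevalence.items()),
        ):
            if not 0.0 <= p <= 1.0:
                raise CohortConfigError(f"{label} must lie in [0, 1], got {p}")
        for name, r in self.retest_reliability.items():
            if not 0.0 < r < 1.0:
                raise CohortConfigError(
                    f"retest reliability for {name} must lie strictly in "
                    f"(0, 1), got {r}"
                )
        for term in self.effect_log_odds:
            if term not in EFFECT_TERMS:
                raise CohortConfigError(
                    f"unknown effect term {term!r}; known terms: {EFFECT_TERMS}"
                )
        if self.change_process not in ("auto", "retest", "propensity"):
            raise CohortConfigError(
                f"unknown change_process {self.change_process!r}"
            )

    @property
    def propensity_active(self) -> bool:
        if self.change_process == "propensity":
            return True
        if self.change_process == "retest":
            return False
        return any(
            b_imp != 0.0 or b_det != 0.0
            for b_imp, b_det in self.effect_log_odds.values()
        )


# --------------------------------------------------------------------------
# Numerical calibration of the latent-Gaussian discretization
# --------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(80)
_GH_WEIGHTS = _GH_WEIGHTS / math.sqrt(2.0 * math.pi)


def _discrete_cell_probs(mu: float, sigma: float, lo: int, hi: int) -> np.ndarray:
    """P(round+clip(N(mu, sigma)) = k) for k = lo..hi (tails absorbed)."""
    k = np.arange(lo, hi + 1)
    upper = stats.norm.cdf((k + 0.5 - mu) / sigma)
    lower = stats.norm.cdf((k - 0.5 - mu) / sigma)
    p = upper - lower
    p[0] = upper[0]
    p[-1] = 1.0 - lower[-1]
    return p


def _discrete_moments(mu: float, sigma: float, lo: int, hi: int) -> Tuple[float, float]:
    k = np.arange(lo, hi + 1)
    p = _discrete_cell_probs(mu, sigma, lo, hi)
    mean = float(p @ k)
    var = float(p @ k**2) - mean**2
    return mean, math.sqrt(max(var, 0.0))


@lru_cache(maxsize=None)
def latent_moments(mean: float, sd: float, lo: int, hi: int) -> Tuple[float, float]:
    """Latent (mu, sigma) whose round+clip discretization hits (mean, sd)."""

    def objective(theta):
        mu, log_sigma = theta
        m, s = _discrete_moments(mu, math.exp(log_sigma), lo, hi)
        return [m - mean, s - sd]

    sol = optimize.root(objective, [mean, math.log(sd)], method="hybr")
    if not sol.success:  # pragma: no cover - defensive
        raise CohortConfigError(
            f"could not calibrate latent moments for target ({mean}, {sd}) "
            f"on [{lo}, {hi}]: {sol.message}"
        )
    mu, log_sigma = sol.x
    return float(mu), float(math.exp(log_sigma))


def _discrete_retest_corr(
    rho: float, mu: float, sigma: float, lo: int, hi: int,
    mean: float, sd: float,
) -> float:
    """Pearson correlation of two discretized scores with latent corr rho.

    Uses the shared-factor representation Z_i = mu + sigma*(sqrt(rho)*U +
    sqrt(1-rho)*V_i): conditional on U the two scores are independent with
    a smooth conditional mean, so a 1-D Gauss-Hermite rule converges fast.
    """
    a = mu + sigma * math.sqrt(rho) * _GH_NODES  # conditional location
    b = sigma * math.sqrt(1.0 - rho)  # conditional scale
    k = np.arange(lo, hi + 1)
    upper = stats.norm.cdf((k[None, :] + 0.5 - a[:, None]) / b)
    lower = stats.norm.cdf((k[None, :] - 0.5 - a[:, None]) / b)
    p = upper - lower
    p[:, 0] = upper[:, 0]
    p[:, -1] = 1.0 - lower[:, -1]
    g = p @ k  # E[score | U]
    e_prod = float(_GH_WEIGHTS @ g**2)
    return (e_prod - mean**2) / sd**2


@lru_cache(maxsize=None)
def latent_retest_corr(
    mean: float, sd: float, lo: int, hi: int, target_r: float
) -> float:
    """Latent correlation giving discrete retest correlation target_r."""
    mu, sigma = latent_moments(mean, sd, lo, hi)

    def gap(rho):
        return _discrete_retest_corr(rho, mu, sigma, lo, hi, mean, sd) - target_r

    lo_b = max(target_r - 0.05, 1e-6)
    hi_b = 1.0 - 1e-9
    if gap(lo_b) > 0:
        lo_b = 1e-6
    return float(optimize.brentq(gap, lo_b, hi_b, xtol=1e-10))


@lru_cache(maxsize=None)
def _support_intercept(prevalence: float, slope: float, z_sd: float) -> float:
    """Intercept a with E[invlogit(a + slope * z)] = prevalence, z ~ N(0, z_sd^2)."""
    if slope == 0.0 or z_sd == 0.0:
        return float(math.log(prevalence / (1.0 - prevalence)))

    def gap(a):
        lp = a + slope * z_sd * _GH_NODES
        return float(_GH_WEIGHTS @ (1.0 / (1.0 + np.exp(-lp)))) - prevalence

    return float(optimize.brentq(gap, -30.0, 30.0, xtol=1e-12))


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------

_STRUCTURE_STREAM, _NOISE_STREAM, _ATTRITION_STREAM = 0, 1, 2


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def _standardized(values: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return (values - mean) / sd


def _effect_columns(
    config: CohortConfig,
    t1: Dict[str, np.ndarray],
    female: np.ndarray,
    ethnicity: np.ndarray,
    fsm: np.ndarray,
    sen: np.ndarray,
    attainment: np.ndarray,
    climate: np.ndarray,
    qol: np.ndarray,
    duration: np.ndarray,
    support: Dict[str, np.ndarray],
) -> Dict[str, np.ndarray]:
    cols: Dict[str, np.ndarray] = {}
    for name in SUBSCALE_RANGES:
        cols[f"t1_{name}"] = _standardized(
            t1[name].astype(float),
            config.subscale_means[name],
            config.subscale_sds[name],
        )
    cols["gender_female"] = female.astype(float)
    cols["ethnicity_other"] = (ethnicity != "White").astype(float)
    cols["fsm"] = fsm.astype(float)
    cols["sen"] = sen.astype(float)
    cols["attainment"] = _standardized(
        attainment, config.attainment_mean, config.attainment_sd
    )
    cols["school_climate"] = _standardized(
        climate.astype(float), config.school_climate_mean, config.school_climate_sd
    )
    cols["quality_of_life"] = _standardized(
        qol.astype(float), config.quality_of_life_mean, config.quality_of_life_sd
    )
    for level in DURATION_LEVELS[1:]:
        cols[f"duration_{level}"] = (duration == level).astype(float)
    for key in ("counsellor", "peer_mentor", "other"):
        cols[f"support_{key}"] = support[key].astype(float)
    return cols


def generate(config: CohortConfig) -> list[StudentRecord]:
    """Generate a cohort; deterministic given ``config.seed``.

    Structure (T1 scores, demographics, covariates, support flags) and
    noise (T2 innovations, planted-category draws) use independent
    sub-streams of the seed, so toggling effects leaves the baseline cohort
    untouched.  With no planted effects, T2 follows the pure retest process
    and the population change SD equals SD*sqrt(2*(1-r)) per subscale.
    """
    n = config.n
    if n == 0:
        return []
    structure = _rng(config.seed, _STRUCTURE_STREAM)
    noise = _rng(config.seed, _NOISE_STREAM)
    scales = list(SUBSCALE_RANGES)

    # Latent T1: single "distress" factor with loading sqrt(c) on every scale.
    c = config.inter_subscale_corr
    factor = structure.standard_normal(n)
    z1 = {
        name: math.sqrt(c) * factor + math.sqrt(1.0 - c) * structure.standard_normal(n)
        for name in scales
    }
    t1: Dict[str, np.ndarray] = {}
    for name in scales:
        lo, hi = SUBSCALE_RANGES[name]
        mu, sigma = latent_moments(
            config.subscale_means[name], config.subscale_sds[name], lo, hi
        )
        t1[name] = np.clip(np.rint(mu + sigma * z1[name]), lo, hi).astype(int)

    # Demographics and covariates.
    female = structure.random(n) < config.female_prevalence
    eth_levels = list(ETHNICITY_LEVELS)
    eth_p = np.array([config.ethnicity_prevalence[e] for e in eth_levels])
    ethnicity = structure.choice(eth_levels, size=n, p=eth_p / eth_p.sum())
    fsm = structure.random(n) < config.fsm_prevalence
    sen = structure.random(n) < config.sen_prevalence
    dur_levels = list(DURATION_LEVELS)
    dur_p = np.array([config.duration_prevalence[d] for d in dur_levels])
    duration = structure.choice(dur_levels, size=n, p=dur_p / dur_p.sum())
    attainment = config.attainment_mean + config.attainment_sd * structure.standard_normal(n)
    cl_mu, cl_sigma = latent_moments(
        config.school_climate_mean, config.school_climate_sd, 0, 14
    )
    climate = np.clip(
        np.rint(cl_mu + cl_sigma * structure.standard_normal(n)), 0, 14
    ).astype(int)
    q_mu, q_sigma = latent_moments(
        config.quality_of_life_mean, config.quality_of_life_sd, 0, 36
    )
    qol = np.clip(
        np.rint(q_mu + q_sigma * structure.standard_normal(n)), 0, 36
    ).astype(int)
    school_id = structure.integers(1, N_SCHOOLS + 1, size=n)

    # Support flags: P(flag) = invlogit(a + slope * mean standardized T1
    # severity); a is solved so the marginal prevalence stays on target.
    z_sev = np.mean(
        [
            _standardized(
                t1[name].astype(float),
                config.subscale_means[name],
                config.subscale_sds[name],
            )
            for name in OUTCOME_SUBSCALES
        ],
        axis=0,
    )
    z_sd = math.sqrt((3.0 + 6.0 * c) / 9.0)
    support: Dict[str, np.ndarray] = {}
    for key in ("counsellor", "peer_mentor", "other"):
        a = _support_intercept(
            config.support_prevalence[key], config.helpseek_severity_slope, z_sd
        )
        p_flag = 1.0 / (1.0 + np.exp(-(a + config.helpseek_severity_slope * z_sev)))
        support[key] = structure.random(n) < p_flag

    # Base T2 process: latent AR(1) with the calibrated latent retest
    # correlation, so the discrete T1-T2 correlation hits the configured r.
    t2 = {}
    for name in scales:
        lo, hi = SUBSCALE_RANGES[name]
        rho = latent_retest_corr(
            config.subscale_means[name],
            config.subscale_sds[name],
            lo,
            hi,
            config.retest_reliability[name],
        )
        mu, sigma = latent_moments(
            config.subscale_means[name], config.subscale_sds[name], lo, hi
        )
        z2 = rho * z1[name] + math.sqrt(1.0 - rho**2) * noise.standard_normal(n)
        t2[name] = np.clip(np.rint(mu + sigma * z2), lo, hi).astype(int)

    if config.propensity_active:
        cols = _effect_columns(
            config, t1, female, ethnicity, fsm, sen, attainment, climate,
            qol, duration, support,
        )
        _apply_planted_effects(config, t1, t2, cols, noise)

    records = []
    for i in range(n):
        records.append(
            StudentRecord(
                id=f"S{i + 1:06d}",
                school_id=f"SCH{school_id[i]:03d}",
                t1=SubscaleScores(**{s: int(t1[s][i]) for s in scales}),
                t2=SubscaleScores(**{s: int(t2[s][i]) for s in scales}),
                gender="female" if female[i] else "male",
                ethnicity=str(ethnicity[i]),
                fsm=bool(fsm[i]),
                sen=bool(sen[i]),
                attainment=float(attainment[i]),
                school_climate=int(climate[i]),
                quality_of_life=int(qol[i]),
                duration=str(duration[i]),
                support_counsellor=bool(support["counsellor"][i]),
                support_peer_mentor=bool(support["peer_mentor"][i]),
                support_other=bool(support["other"][i]),
            )
        )
    return records


def _apply_planted_effects(
    config: CohortConfig,
    t1: Dict[str, np.ndarray],
    t2: Dict[str, np.ndarray],
    cols: Dict[str, np.ndarray],
    noise: np.random.Generator,
    rcc: int = 3,
) -> None:
    """Drive the change category by a latent multinomial propensity.

    Draws each record's target category from a multinomial logit
    (intercepts + planted log-odds terms), then realizes outcome-subscale
    T2 scores so downstream classification reproduces the drawn category.
    Records for which a drawn category is arithmetically infeasible (e.g.
    improvement with every baseline outcome score below the criterion — the
    floor effect) are redrawn among feasible categories with unchanged
    relative odds, which leaves the planted log-odds-ratios intact.
    """
    n = next(iter(t1.values())).shape[0]
    s_imp = np.full(n, config.category_logits[0])
    s_det = np.full(n, config.category_logits[1])
    for term, (b_imp, b_det) in config.effect_log_odds.items():
        s_imp += b_imp * cols[term]
        s_det += b_det * cols[term]

    t1_mat = np.stack([t1[s] for s in OUTCOME_SUBSCALES], axis=1)
    feasible_imp = t1_mat.max(axis=1) >= rcc
    feasible_det = t1_mat.min(axis=1) <= SUBSCALE_RANGES["conduct"][1] - rcc

    logits = np.stack([np.zeros(n), s_imp, s_det], axis=1)
    logits[~feasible_imp, 1] = -np.inf
    logits[~feasible_det, 2] = -np.inf
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    u = noise.random(n)
    cum = np.cumsum(probs, axis=1)
    category = (u[:, None] > cum).sum(axis=1)  # 0 no_change, 1 imp, 2 det

    base_delta = np.stack(
        [t2[s] - t1[s] for s in OUTCOME_SUBSCALES], axis=1
    )
    hi = SUBSCALE_RANGES["conduct"][1]
    new_t2 = t1_mat + np.clip(base_delta, -(rcc - 1), rcc - 1)
    new_t2 = np.clip(new_t2, 0, hi)  # no_change default: no reliable movement

    imp = category == 1
    if imp.any():
        target = np.argmax(t1_mat[imp], axis=1)
        rows = np.where(imp)[0]
        others = np.clip(
            t1_mat[imp] + np.clip(base_delta[imp], -hi, rcc - 1), 0, hi
        )
        new_t2[rows] = others
        t1_star = t1_mat[rows, target]
        magnitude = np.clip(-base_delta[rows, target], rcc, t1_star)
        new_t2[rows, target] = t1_star - magnitude

    det = category == 2
    if det.any():
        rows = np.where(det)[0]
        target = np.argmin(t1_mat[det], axis=1)
        new_t2[rows] = np.clip(t1_mat[rows] + base_delta[rows], 0, hi)
        t1_star = t1_mat[rows, target]
        magnitude = np.clip(base_delta[rows, target], rcc, hi - t1_star)
        new_t2[rows, target] = t1_star + magnitude

    for j, s in enumerate(OUTCOME_SUBSCALES):
        t2[s] = new_t2[:, j].astype(int)


def apply_attrition(
    records: Sequence[StudentRecord], config: CohortConfig
) -> list[StudentRecord]:
    """Blank T2 with record-level probability from the attrition model.

    Deterministic given ``config.seed`` (own sub-stream: toggling attrition
    never changes the underlying cohort).  Identity when the switch is off.
    """
    if not config.attrition.enabled:
        return list(records)
    for r in records:
        if r.t2 is None:
            raise CohortConfigError(
                f"record {r.id} already lacks T2; apply_attrition expects a "
                "complete cohort"
            )
    rng = _rng(config.seed, _ATTRITION_STREAM)
    att = config.attrition
    out = []
    u = rng.random(len(records))
    for r, ui in zip(records, u):
        lp = att.intercept
        lo = att.log_odds
        lp += lo.get("male", 0.0) * (r.gender == "male")
        lp += lo.get("fsm", 0.0) * r.fsm
        lp += lo.get("ethnicity_black", 0.0) * (r.ethnicity == "Black")
        lp += lo.get("ethnicity_other", 0.0) * (r.ethnicity == "Other")
        for name in SUBSCALE_RANGES:
            key = f"z_{name}"
            if key in lo:
                z = (getattr(r.t1, name) - config.subscale_means[name]) / (
                    config.subscale_sds[name]
                )
                lp += lo[key] * z
        p_drop = 1.0 / (1.0 + math.exp(-lp))
        out.append(r.drop_t2() if ui < p_drop else r)
    return out
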