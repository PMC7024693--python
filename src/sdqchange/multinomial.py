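"""Multinomial logistic regression of the 3-way change category.

"No change" is the reference level; the two estimated contrasts are
improvement-vs-no-change and deterioration-vs-no-change.  Fitting is direct
maximization of the multinomial log-likelihood with Newton iterations and
step-halving; the covariance is the inverse observed information, and
inference is Wald (z tests, exp-transformed CIs), matching the usual
OR [95% CI] presentation.  Predictors are added in the fixed stage sequence
null -> baseline severity -> + socio-demographics -> + functioning/context
-> + support receipt, compared by likelihood-ratio (deviance) tests and AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DURATION_LEVELS, StudentRecord
from .reliable import CATEGORIES, Category, ChangeResult

#: Outcome coding; index 0 is the reference level.
OUTCOME_LEVELS: Tuple[Category, ...] = ("no_change", "improvement", "deterioration")

#: The full 19-term predictor vocabulary (Table-3 shaped).
SEVERITY_TERMS = ("t1_emotional", "t1_conduct", "t1_hyperactivity")
DEMOGRAPHIC_TERMS = ("gender_female", "ethnicity_other", "fsm")
CONTEXT_TERMS = (
    "sen",
    "attainment",
    "school_climate",
    "quality_of_life",
    "t1_peer",
    "t1_impact",
    "duration_<1mo",
    "duration_1-5mo",
    "duration_6-12mo",
    "duration_>1yr",
)
SUPPORT_TERMS = ("support_counsellor", "support_peer_mentor", "support_other")
FULL_TERMS = SEVERITY_TERMS + DEMOGRAPHIC_TERMS + CONTEXT_TERMS + SUPPORT_TERMS

#: Continuous predictors, standardized within the analysis sample so one
#: unit is one sample SD.
CONTINUOUS_TERMS = (
    "t1_emotional",
    "t1_conduct",
    "t1_hyperactivity",
    "t1_peer",
    "t1_impact",
    "attainment",
    "school_climate",
    "quality_of_life",
)

STAGES: Dict[str, Tuple[str, ...]] = {
    "null": (),
    "severity": SEVERITY_TERMS,
    "severity+demographics": SEVERITY_TERMS + DEMOGRAPHIC_TERMS,
    "severity+demographics+context": SEVERITY_TERMS + DEMOGRAPHIC_TERMS + CONTEXT_TERMS,
    "full": FULL_TERMS,
}

WALD_Z = 1.96  # conventional 95% normal quantile used throughout reporting


class ModelError(ValueError):
    """Design or fitting failure."""


@dataclass(frozen=True)
class ModelSpec:
    """Which predictors enter one multinomial fit."""

    predictors: Tuple[str, ...]
    stage: str = "custom"
    reference_level: Category = "no_change"
    ethnicity_binary: bool = True

    def __post_init__(self) -> None:
        unknown = [t for t in self.predictors if t not in FULL_TERMS]
        if unknown:
            raise ModelError(f"unknown predictor terms: {unknown}")

    @classmethod
    def for_stage(cls, stage: str) -> "ModelSpec":
        if stage not in STAGES:
            raise ModelError(
                f"unknown stage {stage!r}; known stages: {list(STAGES)}"
            )
        return cls(predictors=STAGES[stage], stage=stage)


def _raw_term_value(record: StudentRecord, term: str) -> float:
    if term.startswith("t1_"):
        return float(getattr(record.t1, term[3:]))
    if term == "gender_female":
        return float(record.gender == "female")
    if term == "ethnicity_other":
        return float(record.ethnicity != "White")
    if term == "fsm":
        return float(record.fsm)
    if term == "sen":
        return float(record.sen)
    if term == "attainment":
        return float(record.attainment)
    if term == "school_climate":
        return float(record.school_climate)
    if term == "quality_of_life":
        return float(record.quality_of_life)
    if term.startswith("duration_"):
        level = term[len("duration_"):]
        if level not in DURATION_LEVELS:
            raise ModelError(f"unknown duration level in term {term!r}")
        return float(record.duration == level)
    if term.startswith("support_"):
        return float(getattr(record, term))
    raise ModelError(f"unknown term {term!r}")


def standardize_continuous(
    X: pd.DataFrame, terms: Sequence[str] = CONTINUOUS_TERMS
) -> Tuple[pd.DataFrame, Dict[str, Tuple[float, float]]]:
    """Standardize continuous columns in place of their raw values.

    Moments are taken from the sample being fitted (each unit becomes one
    sample SD); they are returned for reporting.  A zero-SD predictor is a
    hard failure naming the column.
    """
    if X.shape[0] == 0:
        raise ModelError("cannot standardize an empty sample")
    out = X.copy()
    moments: Dict[str, Tuple[float, float]] = {}
    for term in terms:
        if term not in out.columns:
            continue
        mean = float(out[term].mean())
        sd = float(out[term].std(ddof=1))
        if sd == 0.0 or not np.isfinite(sd):
            raise ModelError(f"predictor {term!r} has zero variance")
        out[term] = (out[term] - mean) / sd
        moments[term] = (mean, sd)
    return out, moments


def build_design(
    records: Sequence[StudentRecord],
    results: Sequence[ChangeResult],
    spec: ModelSpec,
    standardize: bool = True,
) -> Tuple[pd.DataFrame, np.ndarray, Dict[str, Tuple[float, float]]]:
    """Design frame (with intercept), outcome codes, and scaling moments."""
    if len(records) != len(results):
        raise ModelError("records and results must align one-to-one")
    raw = pd.DataFrame(
        {
            term: [_raw_term_value(r, term) for r in records]
            for term in spec.predictors
        },
        index=range(len(records)),
    )
    moments: Dict[str, Tuple[float, float]] = {}
    if standardize and spec.predictors:
        raw, moments = standardize_continuous(raw)
    raw.insert(0, "intercept", 1.0)
    y = np.array([OUTCOME_LEVELS.index(res.overall) for res in results])
    return raw, y, moments


@dataclass(frozen=True)
class MultinomialFit:
    """A converged maximum-likelihood multinomial fit.

    ``coefficients`` has one row per non-reference contrast (improvement,
    deterioration) and one column per term (intercept first).  The
    covariance is the inverse observed information over the flattened
    parameter vector, contrast-major.
    """

    terms: Tuple[str, ...]
    contrasts: Tuple[Category, ...]
    coefficients: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    log_likelihood_null: float
    n: int
    spec: Optional[ModelSpec] = None
    scaling: Mapping[str, Tuple[float, float]] = field(default_factory=dict)
    n_iterations: int = 0

    @property
    def n_params(self) -> int:
        return self.coefficients.size

    @property
    def aic(self) -> float:
        return -2.0 * self.log_likelihood + 2.0 * self.n_params

    @property
    def mcfadden_r2(self) -> float:
        return 1.0 - self.log_likelihood / self.log_likelihood_null

    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance)).reshape(self.coefficients.shape)

    def summary_frame(self, alpha: float = 0.05) -> pd.DataFrame:
        """Table-shaped summary: per contrast and term, OR, 95% Wald CI,
        z, p and a significance flag at ``alpha``."""
        se = self.standard_errors()
        rows = []
        old_err = np.seterr(over="ignore")  # wide CIs may overflow to inf
        for i, contrast in enumerate(self.contrasts):
            for j, term in enumerate(self.terms):
                b = self.coefficients[i, j]
                s = se[i, j]
                z = b / s
                p = 2.0 * stats.norm.sf(abs(z))
                rows.append(
                    {
                        "contrast": f"{contrast} vs no_change",
                        "term": term,
                        "coef": b,
                        "se": s,
                        "odds_ratio": float(np.exp(b)),
                        "ci_low": float(np.exp(b - WALD_Z * s)),
                        "ci_high": float(np.exp(b + WALD_Z * s)),
                        "z": z,
                        "p": p,
                        "significant": bool(p < alpha),
                    }
                )
        np.seterr(**old_err)
        return pd.DataFrame(rows)


def _null_log_likelihood(y: np.ndarray) -> float:
    n = y.shape[0]
    ll = 0.0
    for k in range(len(OUTCOME_LEVELS)):
        nk = int(np.sum(y == k))
        if nk > 0:
            ll += nk * np.log(nk / n)
    return float(ll)


def _log_likelihood(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta.T  # (n, 2)
    m = np.maximum(eta.max(axis=1), 0.0)
    lse = m + np.log(
        np.exp(-m) + np.exp(eta[:, 0] - m) + np.exp(eta[:, 1] - m)
    )
    pick = np.zeros(X.shape[0])
    pick[y == 1] = eta[y == 1, 0]
    pick[y == 2] = eta[y == 2, 1]
    return float(np.sum(pick - lse))


def _probabilities(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    eta = np.column_stack([np.zeros(X.shape[0]), X @ beta.T])
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    return p  # (n, 3): no_change, improvement, deterioration


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ModelError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear terms: {bad or 'unidentified'}"
        )


def fit_multinomial_arrays(
    X: np.ndarray,
    y: np.ndarray,
    terms: Sequence[str],
    tol: float = 1e-8,
    max_iter: int = 100,
    spec: Optional[ModelSpec] = None,
    scaling: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> MultinomialFit:
    """Newton maximization of the multinomial log-likelihood.

    Converges when the gradient max-norm drops below ``tol``; raises with
    an iteration trace otherwise.  Separation (coefficients running away)
    is reported as a diagnostic failure.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    observed = np.unique(y)
    if observed.size < 2:
        raise ModelError(
            f"outcome has a single observed category "
            f"({OUTCOME_LEVELS[int(observed[0])]}); nothing to contrast"
        )
    _check_rank(X, terms)
    beta = np.zeros((2, p))
    ll = _log_likelihood(X, y, beta)
    trace = [ll]
    ind = np.column_stack([y == 1, y == 2]).astype(float)
    for iteration in range(1, max_iter + 1):
        probs = _probabilities(X, beta)[:, 1:]  # (n, 2)
        grad = np.concatenate(
            [X.T @ (ind[:, j] - probs[:, j]) for j in range(2)]
        )
        if np.max(np.abs(grad)) < tol:
            info = _information(X, probs)
            cov = np.linalg.inv(info)
            return MultinomialFit(
                terms=tuple(terms),
                contrasts=("improvement", "deterioration"),
                coefficients=beta,
                covariance=cov,
                log_likelihood=ll,
                log_likelihood_null=_null_log_likelihood(y),
                n=n,
                spec=spec,
                scaling=dict(scaling or {}),
                n_iterations=iteration - 1,
            )
        info = _information(X, probs)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ModelError(f"singular information matrix: {exc}") from None
        # step-halving keeps Newton monotone far from the optimum
        scale = 1.0
        for _ in range(30):
            candidate = beta + scale * step.reshape(2, p)
            ll_new = _log_likelihood(X, y, candidate)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step.reshape(2, p)
        ll = ll_new
        trace.append(ll)
        if np.max(np.abs(beta)) > 30.0:
            raise ModelError(
                "coefficients diverging (|beta| > 30): quasi-complete "
                "separation or an empty covariate cell; inspect the design"
            )
    raise ModelError(
        f"Newton iterations did not converge in {max_iter} steps; "
        f"log-likelihood trace tail: {[round(v, 6) for v in trace[-5:]]}"
    )


def _information(X: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Observed (= expected) information over the flattened parameters."""
    p = X.shape[1]
    info = np.empty((2 * p, 2 * p))
    for j in range(2):
        for k in range(2):
            w = probs[:, j] * ((j == k) - probs[:, k])
            info[j * p:(j + 1) * p, k * p:(k + 1) * p] = X.T @ (X * w[:, None])
    return info


def fit_multinomial(
    spec: ModelSpec,
    records: Sequence[StudentRecord],
    results: Sequence[ChangeResult],
    standardize: bool = True,
) -> MultinomialFit:
    """Fit one staged model to a classified sample."""
    X, y, moments = build_design(records, results, spec, standardize=standardize)
    return fit_multinomial_arrays(
        X.to_numpy(), y, tuple(X.columns), spec=spec, scaling=moments
    )


def null_fit_from_counts(counts: Mapping[Category, int]) -> MultinomialFit:
    """Closed-form intercept-only fit from category counts.

    The saturated intercept model's fitted probabilities are the sample
    proportions; with the 2-free-parameter convention the AIC is
    -2 * sum n_j log(n_j / n) + 4.
    """
    for cat in CATEGORIES:
        if counts.get(cat, 0) <= 0:
            raise ModelError(
                f"category {cat!r} has no observations; intercepts undefined"
            )
    n = sum(counts[c] for c in CATEGORIES)
    n_no, n_imp, n_det = (
        counts["no_change"],
        counts["improvement"],
        counts["deterioration"],
    )
    beta = np.array([[np.log(n_imp / n_no)], [np.log(n_det / n_no)]])
    ll = float(
        sum(counts[c] * np.log(counts[c] / n) for c in CATEGORIES)
    )
    p_hat = np.array([n_imp, n_det]) / n
    X = np.ones((1, 1))
    info = _information(X, p_hat[None, :]) * n
    return MultinomialFit(
        terms=("intercept",),
        contrasts=("improvement", "deterioration"),
        coefficients=beta,
        covariance=np.linalg.inv(info),
        log_likelihood=ll,
        log_likelihood_null=ll,
        n=n,
        spec=ModelSpec(predictors=(), stage="null"),
    )


@dataclass(frozen=True)
class LRTestResult:
    lr_statistic: float
    df: int
    p_value: float


def likelihood_ratio_test(
    fit_reduced: MultinomialFit, fit_full: MultinomialFit
) -> LRTestResult:
    """Deviance test of nested fits on the same records."""
    if fit_reduced.n != fit_full.n:
        raise ModelError(
            f"fits use different samples (n={fit_reduced.n} vs {fit_full.n})"
        )
    if not set(fit_reduced.terms) <= set(fit_full.terms):
        raise ModelError(
            "models are not nested: reduced terms "
            f"{set(fit_reduced.terms) - set(fit_full.terms)} missing from full"
        )
    lr = 2.0 * (fit_full.log_likelihood - fit_reduced.log_likelihood)
    lr = max(lr, 0.0)
    df = fit_full.n_params - fit_reduced.n_params
    p = 1.0 if df == 0 else float(stats.chi2.sf(lr, df))
    return LRTestResult(lr_statistic=lr, df=df, p_value=p)


def staged_comparison(
    records: Sequence[StudentRecord],
    results: Sequence[ChangeResult],
    sample_label: str = "full",
) -> pd.DataFrame:
    """Fit the null -> severity -> +demographics -> +context -> full
    sequence and tabulate AIC and the LR of each stage against the full
    model."""
    alpha = significance_policy(sample_label)
    fits = {
        stage: fit_multinomial(ModelSpec.for_stage(stage), records, results)
        for stage in STAGES
    }
    full = fits["full"]
    rows = []
    for stage, fit in fits.items():
        if stage == "full":
            lr, df, p = np.nan, 0, np.nan
        else:
            test = likelihood_ratio_test(fit, full)
            lr, df, p = test.lr_statistic, test.df, test.p_value
        rows.append(
            {
                "sample": sample_label,
                "stage": stage,
                "n_params": fit.n_params,
                "log_likelihood": fit.log_likelihood,
                "aic": fit.aic,
                "mcfadden_r2": fit.mcfadden_r2,
                "lr_vs_full": lr,
                "df": df,
                "p": p,
                "alpha": alpha,
            }
        )
    return pd.DataFrame(rows)


def significance_policy(sample_label: str) -> float:
    """0.05 for the full sample; Bonferroni 0.025 for the two sub-samples."""
    policy = {"full": 0.05, "above": 0.025, "below": 0.025}
    if sample_label not in policy:
        raise ModelError(
            f"unknown sample label {sample_label!r}; expected one of "
            f"{sorted(policy)}"
        )
    return policy[sample_label]
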