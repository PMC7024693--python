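"""Depth-limited conditional-inference classification trees.

Recursive partitioning in the permutation-test framework: at each node the
association between every candidate predictor and the 3-category change
outcome is scored with the standardized linear statistic T = sum_i g(x_i)
h(y_i)^T (h = outcome indicators; g = identity for numeric/ordinal
predictors, level indicators for categorical ones), standardized by its
exact permutation mean and covariance and referred, as a quadratic form, to
a chi-square with rank degrees of freedom.  Variable selection (smallest
Bonferroni-adjusted p-value <= alpha) is separated from split-point search
(the binary split maximizing the standardized two-sample statistic), which
removes the variable-selection bias of exhaustive-search trees.  A seeded
permutation-resampling p-value is available for small nodes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Literal, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .cohort import DURATION_LEVELS, StudentRecord
from .multinomial import FULL_TERMS, _raw_term_value
from .reliable import ChangeResult

#: Display order of outcome classes in distributions and renderings.
CLASS_ORDER = ("no_change", "deterioration", "improvement")
_CLASS_ABBREV = {"no_change": "no", "deterioration": "det", "improvement": "imp"}

PredictorKind = Literal["numeric", "ordinal", "categorical"]

#: Default tree predictor vocabulary: the model terms, but with ethnicity
#: kept categorical (5 levels) and problem duration as ordinal ranks.
TREE_PREDICTORS: Dict[str, PredictorKind] = {
    "t1_emotional": "numeric",
    "t1_conduct": "numeric",
    "t1_hyperactivity": "numeric",
    "t1_peer": "numeric",
    "t1_impact": "numeric",
    "gender_female": "numeric",
    "ethnicity": "categorical",
    "fsm": "numeric",
    "sen": "numeric",
    "attainment": "numeric",
    "school_climate": "numeric",
    "quality_of_life": "numeric",
    "duration": "ordinal",
    "support_counsellor": "numeric",
    "support_peer_mentor": "numeric",
    "support_other": "numeric",
}


class TreeError(ValueError):
    """Invalid tree configuration or input."""


@dataclass(frozen=True)
class TreeConfig:
    """Stopping and testing parameters for tree growth."""

    alpha: float = 0.05
    max_depth: int = 3
    min_node: int = 20
    multiplicity: Literal["bonferroni", "none"] = "bonferroni"
    seed: int = 0
    #: nodes smaller than this use a seeded permutation p-value (9,999
    #: resamples) instead of the chi-square approximation; 0 disables.
    monte_carlo_below: int = 0
    n_permutations: int = 9999

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise TreeError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.max_depth < 1:
            raise TreeError(f"max_depth must be >= 1, got {self.max_depth}")
        if self.min_node < 2:
            raise TreeError(f"min_node must be >= 2, got {self.min_node}")
        if self.multiplicity not in ("bonferroni", "none"):
            raise TreeError(f"unknown multiplicity {self.multiplicity!r}")


@dataclass(frozen=True)
class TreeNode:
    """One node; a leaf iff ``split_variable`` is absent."""

    depth: int
    n: int
    class_distribution: Mapping[str, int]
    split_variable: Optional[str] = None
    split_point: Union[float, frozenset, None] = None
    adjusted_p: Optional[float] = None
    children: Optional[Tuple["TreeNode", "TreeNode"]] = None

    @property
    def is_leaf(self) -> bool:
        return self.split_variable is None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.children[0].leaves() + self.children[1].leaves()

    def max_depth(self) -> int:
        if self.is_leaf:
            return self.depth
        return max(child.max_depth() for child in self.children)


# --------------------------------------------------------------------------
# Permutation-framework association test
# --------------------------------------------------------------------------

def _outcome_indicators(y: np.ndarray) -> np.ndarray:
    h = np.zeros((y.shape[0], 3))
    h[np.arange(y.shape[0]), y] = 1.0
    return h


def _transform(x: np.ndarray, kind: PredictorKind) -> np.ndarray:
    """g(x): identity column for numeric/ordinal, level indicators else."""
    if kind in ("numeric", "ordinal"):
        return np.asarray(x, dtype=float).reshape(-1, 1)
    levels = np.unique(x)
    return (np.asarray(x).reshape(-1, 1) == levels.reshape(1, -1)).astype(float)


def _quadratic_statistic(
    g: np.ndarray, h: np.ndarray
) -> Tuple[float, int]:
    """Standardized quadratic form and its rank degrees of freedom."""
    n = g.shape[0]
    T = g.T @ h
    gsum = g.sum(axis=0)
    mu_h = h.mean(axis=0)
    Vh = (h - mu_h).T @ (h - mu_h) / n
    d = (T - np.outer(gsum, mu_h)).ravel()
    Sg = g.T @ g
    A = (n / (n - 1)) * Sg - (1.0 / (n - 1)) * np.outer(gsum, gsum)
    cov = np.kron(A, Vh)
    scale = np.max(np.abs(cov))
    if scale == 0.0:
        return 0.0, 0
    # cov is structurally rank deficient (indicator sums are fixed); a
    # common spectral cutoff keeps the statistic invariant to level order
    eigvals, eigvecs = np.linalg.eigh(cov)
    keep = eigvals > 1e-8 * eigvals.max()
    rank = int(keep.sum())
    if rank == 0:
        return 0.0, 0
    proj = eigvecs[:, keep].T @ d
    stat = float(np.sum(proj**2 / eigvals[keep]))
    return max(stat, 0.0), rank


def association_test(
    x: np.ndarray,
    y: np.ndarray,
    kind: PredictorKind = "numeric",
    method: Literal["asymptotic", "permutation"] = "asymptotic",
    n_permutations: int = 9999,
    seed: int = 0,
) -> Tuple[float, float]:
    """Permutation-framework association test of one predictor vs outcome.

    Returns ``(statistic, p_value)``.  Degenerate inputs (constant
    predictor, or a single outcome class) give p = 1 by convention.  The
    statistic is invariant to relabeling of categorical levels and, for
    ordinal ranks, to any strictly monotone recoding.
    """
    x = np.asarray(x)
    y = np.asarray(y, dtype=int)
    if x.shape[0] != y.shape[0]:
        raise TreeError("predictor and outcome lengths differ")
    if np.unique(y).size < 2 or np.unique(x).size < 2:
        return 0.0, 1.0
    g = _transform(x, kind)
    h = _outcome_indicators(y)
    stat, df = _quadratic_statistic(g, h)
    if df == 0:
        return 0.0, 1.0
    if method == "asymptotic":
        return stat, float(stats.chi2.sf(stat, df))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        s, _ = _quadratic_statistic(g, h[rng.permutation(h.shape[0])])
        if s >= stat - 1e-12:
            exceed += 1
    return stat, (1.0 + exceed) / (n_permutations + 1.0)


# --------------------------------------------------------------------------
# Split-point search
# --------------------------------------------------------------------------

def _two_sample_stats(
    d: np.ndarray, nA: np.ndarray, n: int, Vh_pinv: np.ndarray
) -> np.ndarray:
    """Standardized two-sample statistic for prefix sums d (m x 3)."""
    denom = nA * (n - nA) / (n - 1.0)
    quad = np.einsum("ij,jk,ik->i", d, Vh_pinv, d)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, quad / denom, -np.inf)
    return out


def best_split(
    x: np.ndarray,
    y: np.ndarray,
    kind: PredictorKind = "numeric",
    min_node: int = 20,
) -> Optional[Tuple[Union[float, frozenset], float]]:
    """Best admissible binary split of an already-selected variable.

    Numeric/ordinal: ``x <= c`` with c the midpoint between adjacent
    observed values, maximizing the standardized two-sample statistic
    between the child outcome distributions (ties -> smallest c).
    Categorical: the best binary partition of observed levels (ties ->
    lexicographically first).  Returns None when no split leaves both
    children with at least ``min_node`` cases.
    """
    x = np.asarray(x)
    y = np.asarray(y, dtype=int)
    n = x.shape[0]
    h = _outcome_indicators(y)
    mu_h = h.mean(axis=0)
    Vh = (h - mu_h).T @ (h - mu_h) / n
    scale = np.max(np.abs(Vh))
    if scale == 0.0:
        return None
    Vh_pinv = np.linalg.pinv(Vh, hermitian=True)

    if kind in ("numeric", "ordinal"):
        order = np.argsort(x, kind="stable")
        xs = np.asarray(x, dtype=float)[order]
        hs = h[order]
        csum = np.cumsum(hs, axis=0)
        # candidate prefixes: last index of each run of equal values
        boundary = np.nonzero(np.diff(xs))[0]
        if boundary.size == 0:
            return None
        nA = boundary + 1.0
        ok = (nA >= min_node) & (n - nA >= min_node)
        if not ok.any():
            return None
        boundary = boundary[ok]
        nA = nA[ok]
        d = csum[boundary] - nA[:, None] * mu_h
        statvals = _two_sample_stats(d, nA, n, Vh_pinv)
        best = int(np.argmax(statvals))  # argmax returns first max: smallest c
        c = 0.5 * (xs[boundary[best]] + xs[boundary[best] + 1])
        return float(c), float(statvals[best])

    levels = sorted(np.unique(x).tolist())
    if len(levels) < 2:
        return None
    first = levels[0]
    best_part: Optional[frozenset] = None
    best_stat = -np.inf
    for size in range(1, len(levels)):
        for combo in itertools.combinations(levels[1:], size - 1):
            subset = (first,) + combo  # anchor on first level: no mirror dups
            mask = np.isin(x, subset)
            nA = float(mask.sum())
            if nA < min_node or n - nA < min_node:
                continue
            d = (h[mask].sum(axis=0) - nA * mu_h)[None, :]
            s = float(_two_sample_stats(d, np.array([nA]), n, Vh_pinv)[0])
            if s > best_stat + 1e-12:
                best_stat = s
                best_part = frozenset(subset)
    if best_part is None:
        return None
    return best_part, best_stat


# --------------------------------------------------------------------------
# Tree growth
# --------------------------------------------------------------------------

def _class_distribution(y: np.ndarray) -> Dict[str, int]:
    return {
        name: int(np.sum(y == code))
        for name, code in (("no_change", 0), ("improvement", 1), ("deterioration", 2))
    }


def grow_tree_arrays(
    predictors: Mapping[str, Tuple[np.ndarray, PredictorKind]],
    y: np.ndarray,
    config: TreeConfig = TreeConfig(),
) -> TreeNode:
    """Grow a tree from raw predictor arrays and outcome codes (0 =
    no_change, 1 = improvement, 2 = deterioration)."""
    y = np.asarray(y, dtype=int)
    if y.shape[0] == 0:
        raise TreeError("cannot grow a tree on an empty sample")
    names = list(predictors)

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        y_node = y[idx]
        dist = _class_distribution(y_node)
        leaf = TreeNode(depth=depth, n=idx.size, class_distribution=dist)
        if depth >= config.max_depth or idx.size < 2 * config.min_node:
            return leaf
        if np.unique(y_node).size < 2:
            return leaf
        best_name, best_p = None, np.inf
        for name in names:
            values, kind = predictors[name]
            method = (
                "permutation"
                if 0 < idx.size < config.monte_carlo_below
                else "asymptotic"
            )
            _, p = association_test(
                values[idx],
                y_node,
                kind,
                method=method,
                n_permutations=config.n_permutations,
                seed=config.seed + depth,
            )
            if config.multiplicity == "bonferroni":
                p = min(1.0, p * len(names))
            if p < best_p - 1e-15:
                best_name, best_p = name, p
        if best_name is None or best_p > config.alpha:
            return leaf
        values, kind = predictors[best_name]
        found = best_split(values[idx], y_node, kind, config.min_node)
        if found is None:
            return leaf
        point, _ = found
        if isinstance(point, frozenset):
            mask = np.isin(values[idx], sorted(point))
        else:
            mask = np.asarray(values[idx], dtype=float) <= point
        left = build(idx[mask], depth + 1)
        right = build(idx[~mask], depth + 1)
        return TreeNode(
            depth=depth,
            n=idx.size,
            class_distribution=dist,
            split_variable=best_name,
            split_point=point,
            adjusted_p=float(best_p),
            children=(left, right),
        )

    return build(np.arange(y.shape[0]), 0)


def _tree_predictor_value(record: StudentRecord, name: str) -> object:
    if name == "ethnicity":
        return record.ethnicity
    if name == "duration":
        return float(DURATION_LEVELS.index(record.duration))
    return _raw_term_value(record, name)


def grow_tree(
    records: Sequence[StudentRecord],
    results: Sequence[ChangeResult],
    predictors: Optional[Mapping[str, PredictorKind]] = None,
    config: TreeConfig = TreeConfig(),
) -> TreeNode:
    """Grow a conditional-inference tree on a classified sample."""
    if len(records) != len(results):
        raise TreeError("records and results must align one-to-one")
    if predictors is None:
        predictors = TREE_PREDICTORS
    from .multinomial import OUTCOME_LEVELS

    y = np.array([OUTCOME_LEVELS.index(r.overall) for r in results])
    arrays = {}
    for name, kind in predictors.items():
        values = [_tree_predictor_value(r, name) for r in records]
        arrays[name] = (
            np.array(values) if kind == "categorical" else np.array(values, float),
            kind,
        )
    return grow_tree_arrays(arrays, y, config)


# --------------------------------------------------------------------------
# Rendering and serialization
# --------------------------------------------------------------------------

def render_tree(tree: TreeNode) -> str:
    """Indented text rendering with no/det/imp class proportions."""
    lines: list[str] = []

    def proportions(node: TreeNode) -> str:
        return " ".join(
            f"{_CLASS_ABBREV[c]}={node.class_distribution[c] / max(node.n, 1):.3f}"
            for c in CLASS_ORDER
        )

    def walk(node: TreeNode, prefix: str, branch: str) -> None:
        if node.is_leaf:
            lines.append(
                f"{prefix}{branch}leaf n={node.n} [{proportions(node)}]"
            )
            return
        if isinstance(node.split_point, frozenset):
            cond = f"{node.split_variable} in {sorted(node.split_point)}"
        else:
            cond = f"{node.split_variable} <= {node.split_point:g}"
        lines.append(
            f"{prefix}{branch}{cond} (adj. p = {node.adjusted_p:.4g}) "
            f"n={node.n} [{proportions(node)}]"
        )
        child_prefix = prefix + ("    " if branch else "")
        walk(node.children[0], child_prefix, "yes: ")
        walk(node.children[1], child_prefix, "no:  ")

    walk(tree, "", "")
    return "\n".join(lines)


def tree_to_dict(node: TreeNode) -> dict:
    """JSON-serializable nested representation (round-trips exactly)."""
    out: dict = {
        "depth": node.depth,
        "n": node.n,
        "class_distribution": dict(node.class_distribution),
    }
    if not node.is_leaf:
        out["split_variable"] = node.split_variable
        out["split_point"] = (
            sorted(node.split_point)
            if isinstance(node.split_point, frozenset)
            else node.split_point
        )
        out["split_kind"] = (
            "categorical" if isinstance(node.split_point, frozenset) else "numeric"
        )
        out["adjusted_p"] = node.adjusted_p
        out["children"] = [tree_to_dict(c) for c in node.children]
    return out


def tree_from_dict(data: dict) -> TreeNode:
    if "split_variable" not in data:
        return TreeNode(
            depth=data["depth"],
            n=data["n"],
            class_distribution=dict(data["class_distribution"]),
        )
    point = data["split_point"]
    if data.get("split_kind") == "categorical":
        point = frozenset(point)
    return TreeNode(
        depth=data["depth"],
        n=data["n"],
        class_distribution=dict(data["class_distribution"]),
        split_variable=data["split_variable"],
        split_point=point,
        adjusted_p=data["adjusted_p"],
        children=tuple(tree_from_dict(c) for c in data["children"]),
    )
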