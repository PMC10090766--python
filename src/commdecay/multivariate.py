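"""Permutational multivariate statistics on dissimilarity matrices.

Implements, from their defining sums of squares:

* one-way PERMANOVA (pseudo-F with label-permutation p value),
* pairwise PERMANOVA with Bonferroni adjustment,
* PERMDISP (homogeneity of multivariate dispersions via distances to group
  centroids in principal-coordinate space, with Anderson's correction for
  negative eigenvalues),
* classical scaling / PCoA (Gower double-centering),
* UPGMA (average-linkage) hierarchical clustering.

Permutation p values follow the (1 + count) / (1 + n_perm) convention, so
999 permutations floor at p = 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import DistanceMatrix
from .exceptions import DesignError, DomainError


def _group_vector(d: DistanceMatrix, groups: Mapping[str, str]) -> np.ndarray:
    try:
        return np.asarray([groups[l] for l in d.labels])
    except KeyError as e:
        raise DesignError(f"label {e.args[0]!r} has no group assignment") from None


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    df_between: int
    df_within: int
    ss_total: float
    ss_between: float
    ss_within: float
    p_perm: float
    n_permutations: int
    group_a: str | None = None  # filled for pairwise comparisons
    group_b: str | None = None
    p_adjusted: float | None = None

    def to_dict(self) -> dict:
        out = {
            "pseudo_F": self.pseudo_F,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "ss_total": self.ss_total,
            "ss_between": self.ss_between,
            "ss_within": self.ss_within,
            "p_perm": self.p_perm,
            "n_permutations": self.n_permutations,
        }
        if self.group_a is not None:
            out.update(group_a=self.group_a, group_b=self.group_b, p_adjusted=self.p_adjusted)
        return out


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """(SS_total, SS_within) from squared dissimilarities and group codes."""
    n = d2.shape[0]
    ss_t = d2.sum() / (2 * n)
    ss_w = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size:
            ss_w += d2[np.ix_(idx, idx)].sum() / (2 * idx.size)
    return ss_t, ss_w


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_t, ss_w = _permanova_ss(d2, codes, n_groups)
    ss_a = ss_t - ss_w
    return (ss_a / (n_groups - 1)) / (ss_w / (n - n_groups))


def permanova(
    d: DistanceMatrix,
    groups: Mapping[str, str],
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a dissimilarity matrix.

    SS_total = sum of squared dissimilarities / N over all pairs; SS_within
    sums the analogous terms within each group; pseudo-F compares the
    between/within mean squares. The p value permutes group labels of the
    observations (single fixed effect, no strata).
    """
    gvec = _group_vector(d, groups)
    names, codes = np.unique(gvec, return_inverse=True)
    a = len(names)
    n = len(d.labels)
    if a < 2:
        raise DesignError("PERMANOVA needs at least two groups")
    if n - a <= 0:
        raise DesignError("degenerate design: no within-group degrees of freedom")

    d2 = d.values**2
    ss_t, ss_w = _permanova_ss(d2, codes, a)
    ss_a = ss_t - ss_w
    f_obs = (ss_a / (a - 1)) / (ss_w / (n - a))

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _pseudo_f(d2, codes[perm], a) >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)

    return PermanovaResult(
        pseudo_F=float(f_obs),
        df_between=a - 1,
        df_within=n - a,
        ss_total=float(ss_t),
        ss_between=float(ss_a),
        ss_within=float(ss_w),
        p_perm=float(p),
        n_permutations=n_perm,
    )


def pairwise_permanova(
    d: DistanceMatrix,
    groups: Mapping[str, str],
    n_perm: int = 999,
    seed: int | None = None,
    adjust: str = "bonferroni",
) -> list[PermanovaResult]:
    """All pairwise two-group PERMANOVAs with Bonferroni-adjusted p values."""
    if adjust != "bonferroni":
        raise DomainError(f"unknown adjustment {adjust!r}")
    gvec = _group_vector(d, groups)
    names = sorted(set(gvec))
    if len(names) < 2:
        raise DesignError("need at least two groups")
    pairs = [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]
    rng = np.random.default_rng(seed)
    results = []
    for ga, gb in pairs:
        labels = [l for l, g in zip(d.labels, gvec) if g in (ga, gb)]
        sub = d.submatrix(labels)
        res = permanova(sub, groups, n_perm=n_perm, seed=int(rng.integers(2**31)))
        results.append(
            PermanovaResult(
                **{**res.__dict__, "group_a": ga, "group_b": gb,
                   "p_adjusted": min(1.0, res.p_perm * len(pairs))}
            )
        )
    return results


# ---------------------------------------------------------------------------
# PCoA (classical scaling)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrdinationResult:
    labels: list[str]
    coordinates: np.ndarray  # points x retained positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (may be negative)
    goodness: float  # retained / total positive-eigenvalue variance (nan if degenerate)
    stress1: float  # Kruskal stress-1 of the retained configuration

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis_{i+1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def _double_center(dmat: np.ndarray) -> np.ndarray:
    n = dmat.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (dmat**2) @ j


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Principal-coordinates analysis (classical MDS).

    Gower double-centering followed by eigendecomposition; coordinates come
    from positive eigenvalues only. Kruskal stress-1 of the retained
    configuration is reported as a diagnostic.
    """
    if n_axes < 1:
        raise DomainError("n_axes must be >= 1")
    b = _double_center(d.values)
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = 1e-9 * max(1.0, abs(eigval[0]))
    positive = eigval > tol
    k = min(n_axes, int(positive.sum()))
    n = len(d.labels)
    if k == 0:
        # all points coincide: degenerate configuration at the origin
        coords = np.zeros((n, n_axes))
        return OrdinationResult(list(d.labels), coords, eigval, float("nan"), 0.0)

    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    goodness = float(eigval[:k].sum() / eigval[positive].sum())

    from scipy.spatial.distance import pdist, squareform

    fitted = squareform(pdist(coords))
    iu = np.triu_indices(n, k=1)
    denom = float((d.values[iu] ** 2).sum())
    stress1 = (
        float(np.sqrt(((d.values[iu] - fitted[iu]) ** 2).sum() / denom)) if denom > 0 else 0.0
    )
    return OrdinationResult(list(d.labels), coords, eigval, goodness, stress1)


# ---------------------------------------------------------------------------
# PERMDISP
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PermdispResult:
    labels: list[str]
    centroid_distances: np.ndarray
    F: float
    df_between: int
    df_within: int
    p_anova: float
    p_perm: float
    n_permutations: int

    def to_dict(self) -> dict:
        return {
            "F": self.F,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "p_anova": self.p_anova,
            "p_perm": self.p_perm,
            "n_permutations": self.n_permutations,
        }


def _anova_f(values: np.ndarray, codes: np.ndarray, a: int) -> float:
    n = values.size
    grand = values.mean()
    ss_b = 0.0
    ss_w = 0.0
    for g in range(a):
        sub = values[codes == g]
        ss_b += sub.size * (sub.mean() - grand) ** 2
        ss_w += ((sub - sub.mean()) ** 2).sum()
    tiny = 1e-12 * max(1.0, float(np.abs(values).max(initial=0.0)) ** 2)
    if ss_w <= tiny:
        return 0.0 if ss_b <= tiny else float("inf")
    return (ss_b / (a - 1)) / (ss_w / (n - a))


def centroid_distances(
    d: DistanceMatrix, groups: Mapping[str, str], bias_adjust: bool = True
) -> np.ndarray:
    """Distance of each observation to its group centroid in PCoA space.

    Axes with negative eigenvalues are retained as imaginary coordinates and
    their squared contribution is subtracted (Anderson's correction); the
    squared distance is clamped at zero before the square root.

    ``bias_adjust`` multiplies each distance by sqrt(n_g / (n_g - 1)),
    compensating the downward bias of distances to a centroid fitted from
    few points; without it the dispersion test is anticonservative when
    group sizes are very unequal.
    """
    gvec = _group_vector(d, groups)
    names, codes = np.unique(gvec, return_inverse=True)
    b = _double_center(d.values)
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = 1e-9 * max(1.0, float(np.abs(eigval).max(initial=1.0)))
    pos = eigval > tol
    neg = eigval < -tol
    real = eigvec[:, pos] * np.sqrt(eigval[pos])
    imag = eigvec[:, neg] * np.sqrt(-eigval[neg])

    n = len(gvec)
    out = np.zeros(n)
    for g in range(len(names)):
        idx = np.flatnonzero(codes == g)
        c_real = real[idx].mean(axis=0) if real.size else np.zeros(0)
        c_imag = imag[idx].mean(axis=0) if imag.size else np.zeros(0)
        d2_real = ((real[idx] - c_real) ** 2).sum(axis=1) if real.size else np.zeros(idx.size)
        d2_imag = ((imag[idx] - c_imag) ** 2).sum(axis=1) if imag.size else np.zeros(idx.size)
        out[idx] = np.sqrt(np.maximum(0.0, d2_real - d2_imag))
        if bias_adjust and idx.size > 1:
            out[idx] *= np.sqrt(idx.size / (idx.size - 1))
    return out


def permdisp(
    d: DistanceMatrix,
    groups: Mapping[str, str],
    n_perm: int = 999,
    seed: int | None = None,
    bias_adjust: bool = True,
) -> PermdispResult:
    """Test of homogeneity of multivariate dispersions (PERMDISP2).

    One-way ANOVA on (bias-adjusted) distances to group centroids gives F
    and a parametric p; the permutation p relabels the centroid distances
    across groups.
    """
    gvec = _group_vector(d, groups)
    names, codes = np.unique(gvec, return_inverse=True)
    a = len(names)
    if a < 2:
        raise DesignError("PERMDISP needs at least two groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = [names[i] for i in np.flatnonzero(sizes < 2)]
        raise DesignError(f"every group needs >= 2 members; too small: {small}")

    z = centroid_distances(d, groups, bias_adjust=bias_adjust)
    n = z.size
    f_obs = _anova_f(z, codes, a)
    p_anova = float(stats.f.sf(f_obs, a - 1, n - a)) if np.isfinite(f_obs) else 0.0
    if f_obs == 0.0:
        p_anova = 1.0

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _anova_f(z, codes[perm], a) >= f_obs - 1e-12:
            count += 1
    p_perm = (1 + count) / (1 + n_perm)

    return PermdispResult(
        labels=list(d.labels),
        centroid_distances=z,
        F=float(f_obs),
        df_between=a - 1,
        df_within=n - a,
        p_anova=p_anova,
        p_perm=float(p_perm),
        n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# UPGMA / average-linkage clustering
# ---------------------------------------------------------------------------


@dataclass
class DendrogramNode:
    """Binary dendrogram node; leaves have ``label`` set and height 0."""

    merge_height: float
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None
    label: str | None = None
    leaves: tuple[str, ...] = field(default_factory=tuple)

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def newick(self) -> str:
        return self._newick(parent_height=self.merge_height) + ";"

    def _newick(self, parent_height: float) -> str:
        branch = parent_height - self.merge_height
        if self.is_leaf:
            return f"{self.label}:{parent_height:.6g}"
        inner = ",".join(c._newick(self.merge_height) for c in self.children)
        return f"({inner}):{branch:.6g}"


def hac_average_linkage(d: DistanceMatrix) -> tuple[DendrogramNode, np.ndarray]:
    """UPGMA clustering of a dissimilarity matrix.

    Repeatedly merges the pair of clusters with the smallest arithmetic
    mean of cross-pair dissimilarities; ties break on the lexicographically
    smallest (label, label) pair, where a cluster is named by its smallest
    leaf label. Returns the root node and a scipy-style linkage matrix
    (child_a, child_b, height, size).
    """
    labels = list(d.labels)
    n = len(labels)
    if n < 2:
        raise DesignError("clustering needs at least two labels")

    nodes: dict[int, DendrogramNode] = {
        i: DendrogramNode(0.0, label=labels[i], leaves=(labels[i],)) for i in range(n)
    }
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    minlab: dict[int, str] = {i: labels[i] for i in range(n)}
    scipy_id = {i: i for i in range(n)}
    dvals = d.values
    linkage = np.zeros((n - 1, 4))
    next_id = n

    active = list(range(n))
    for step in range(n - 1):
        best = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                a_id, b_id = active[ii], active[jj]
                block = dvals[np.ix_(members[a_id], members[b_id])]
                mean = block.mean()
                pair_key = tuple(sorted((minlab[a_id], minlab[b_id])))
                key = (mean, pair_key)
                if best is None or key < best[0]:
                    best = (key, a_id, b_id)
        (height, _), a_id, b_id = best
        node = DendrogramNode(
            float(height),
            children=(nodes[a_id], nodes[b_id]),
            leaves=tuple(nodes[a_id].leaves) + tuple(nodes[b_id].leaves),
        )
        linkage[step] = (
            scipy_id[a_id],
            scipy_id[b_id],
            height,
            len(node.leaves),
        )
        nodes[next_id] = node
        members[next_id] = members[a_id] + members[b_id]
        minlab[next_id] = min(minlab[a_id], minlab[b_id])
        scipy_id[next_id] = n + step
        active = [x for x in active if x not in (a_id, b_id)] + [next_id]
        next_id += 1

    return nodes[next_id - 1], linkage


def merge_heights(root: DendrogramNode) -> list[float]:
    """All internal merge heights, root-last (for monotonicity checks)."""
    out: list[float] = []

    def walk(node: DendrogramNode) -> None:
        if not node.is_leaf:
            for c in node.children:
                walk(c)
            out.append(node.merge_height)

    walk(root)
    return out
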