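"""Distance-decay regressions of community similarity.

The headline analysis: for every unordered pair of host species, compute a
community similarity (Jaccard on presence/absence, or Bray-Curtis on
prevalence or mean abundance), log-transform it, and regress it on the
pair's phylogenetic distance (uncorrected p-distance) and geographic
distance (km) in one multiple linear regression. Because each species
enters many pairs, the rows are not independent; inference therefore also
uses permutation tests, by default Mantel-style joint permutation of the
species labels of the similarity matrix.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_io import DistanceMatrix
from .descriptors import ComponentProfile
from .distances import log_transform_similarity, similarity_matrix
from .exceptions import ConfigError, ConsistencyError, DesignError, SingularDesignError

DECAY_METRICS = {
    "jaccard_presence": ("presence", "jaccard"),
    "braycurtis_prevalence": ("prevalence", "braycurtis"),
    "braycurtis_meanabundance": ("mean_abundance", "braycurtis"),
}


@dataclass(frozen=True)
class DecayFit:
    """Result of one multiple regression of log-similarity on two distances."""

    metric: str
    n_pairs: int
    intercept: float
    slope_phylo: float
    slope_geo: float
    r2: float
    effect_size_phylo: float  # |standardized partial coefficient|
    effect_size_geo: float
    p_param_phylo: float
    p_param_geo: float
    p_perm_phylo: float | None = None
    p_perm_geo: float | None = None
    n_perm: int | None = None
    seed: int | None = None
    scheme: str | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def build_decay_table(
    profiles: Mapping[str, ComponentProfile],
    metric: str,
    dphylo: DistanceMatrix,
    dgeo: DistanceMatrix,
    epsilon: float = 0.0,
) -> pd.DataFrame:
    """One row per unordered species pair with similarity and both distances.

    Columns: species_a, species_b, similarity, log_similarity, d_phylo,
    d_geo. All inputs must cover exactly the same species set.
    """
    if metric not in DECAY_METRICS:
        raise ConfigError(f"unknown decay metric {metric!r}; choose from {sorted(DECAY_METRICS)}")
    descriptor, simfun = DECAY_METRICS[metric]

    species = sorted(profiles)
    for name, labels in (("phylogenetic", dphylo.labels), ("geographic", dgeo.labels)):
        if set(labels) != set(species):
            raise ConsistencyError(
                f"{name} distance matrix covers {sorted(labels)}, profiles cover {species}"
            )

    sim = similarity_matrix(
        {sp: profiles[sp].vector(descriptor).to_numpy() for sp in species}, metric=simfun
    )
    rows = []
    for a, b in itertools.combinations(species, 2):
        rows.append((a, b, sim.loc(a, b), dphylo.loc(a, b), dgeo.loc(a, b)))
    table = pd.DataFrame(rows, columns=["species_a", "species_b", "similarity", "d_phylo", "d_geo"])
    table["log_similarity"] = log_transform_similarity(table["similarity"].to_numpy(), epsilon)
    return table[["species_a", "species_b", "similarity", "log_similarity", "d_phylo", "d_geo"]]


def _design(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    x = np.column_stack(
        [np.ones(len(table)), table["d_phylo"].to_numpy(), table["d_geo"].to_numpy()]
    )
    y = table["log_similarity"].to_numpy()
    return x, y


def fit_decay_regression(table: pd.DataFrame, metric: str = "") -> DecayFit:
    """OLS of log-similarity on phylogenetic and geographic distance.

    Effect sizes are absolute standardized partial coefficients,
    |beta_j| * sd(x_j) / sd(y); parametric p values come from the
    coefficient t statistics.
    """
    if len(table) < 4:
        raise DesignError("need at least 4 species pairs to fit two predictors")
    x, y = _design(table)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise SingularDesignError(
            "collinear predictors (e.g. all species at one site gives constant d_geo)"
        )
    res = sm.OLS(y, x).fit()
    sd_y = float(np.std(y, ddof=1))
    eff = [
        abs(res.params[j]) * float(np.std(x[:, j], ddof=1)) / sd_y if sd_y > 0 else 0.0
        for j in (1, 2)
    ]
    return DecayFit(
        metric=metric,
        n_pairs=len(table),
        intercept=float(res.params[0]),
        slope_phylo=float(res.params[1]),
        slope_geo=float(res.params[2]),
        r2=float(res.rsquared),
        effect_size_phylo=eff[0],
        effect_size_geo=eff[1],
        p_param_phylo=float(res.pvalues[1]),
        p_param_geo=float(res.pvalues[2]),
    )


def _t_stats(x: np.ndarray, y_cols: np.ndarray) -> np.ndarray:
    """t statistics of the two slope coefficients for each response column.

    ``y_cols`` is (n, m): m response vectors sharing the design ``x``.
    Returns (2, m).
    """
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y_cols  # (p, m)
    resid = y_cols - x @ beta
    rss = (resid**2).sum(axis=0)
    sigma2 = rss / (n - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.outer(np.diag(xtx_inv)[1:], sigma2))
        t = beta[1:] / se
    t[~np.isfinite(t)] = 0.0
    return t


def permutation_regression_test(
    table: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    scheme: str = "matrix_permute",
    metric: str = "",
) -> DecayFit:
    """Permutation inference for the decay regression.

    ``matrix_permute`` (default) permutes species labels jointly in the
    similarity matrix, preserving its pairwise structure (Mantel-style) —
    appropriate because each species appears in many pairs. ``row_permute``
    shuffles the response rows independently. Two-sided p values on the
    slope t statistics, with the (1 + count) / (1 + n_perm) convention.
    """
    if scheme not in ("matrix_permute", "row_permute"):
        raise ConfigError(f"unknown permutation scheme {scheme!r}")
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")

    fit = fit_decay_regression(table, metric=metric)
    x, y = _design(table)
    n = len(y)
    t_obs = _t_stats(x, y[:, None])[:, 0]

    rng = np.random.default_rng(seed)
    if scheme == "row_permute":
        y_perm = np.empty((n, n_perm))
        for k in range(n_perm):
            y_perm[:, k] = y[rng.permutation(n)]
    else:
        species = sorted(set(table["species_a"]) | set(table["species_b"]))
        s_index = {sp: i for i, sp in enumerate(species)}
        pair_value: dict[tuple[int, int], float] = {}
        row_pairs = []
        for row, val in zip(table.itertuples(), y):
            i, j = s_index[row.species_a], s_index[row.species_b]
            pair_value[(min(i, j), max(i, j))] = val
            row_pairs.append((i, j))
        y_perm = np.empty((n, n_perm))
        ns = len(species)
        for k in range(n_perm):
            pi = rng.permutation(ns)
            for r, (i, j) in enumerate(row_pairs):
                a, b = pi[i], pi[j]
                y_perm[r, k] = pair_value[(min(a, b), max(a, b))]

    t_perm = _t_stats(x, y_perm)  # (2, n_perm)
    p_perm = (1 + (np.abs(t_perm) >= np.abs(t_obs)[:, None] - 1e-12).sum(axis=1)) / (1 + n_perm)

    return replace(
        fit,
        p_perm_phylo=float(p_perm[0]),
        p_perm_geo=float(p_perm[1]),
        n_perm=n_perm,
        seed=seed,
        scheme=scheme,
    )


def plot_decay(table: pd.DataFrame, fit: DecayFit, path: str) -> None:
    """Scatter of log-similarity against each predictor with the fitted line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, col, slope, label in (
        (axes[0], "d_phylo", fit.slope_phylo, "phylogenetic distance (p-distance)"),
        (axes[1], "d_geo", fit.slope_geo, "geographic distance (km)"),
    ):
        xs = table[col].to_numpy()
        ys = table["log_similarity"].to_numpy()
        ax.scatter(xs, ys, s=18, alpha=0.8)
        other = "d_geo" if col == "d_phylo" else "d_phylo"
        grid = np.linspace(xs.min(), xs.max(), 50)
        partial = fit.intercept + slope * grid + (
            fit.slope_geo if col == "d_phylo" else fit.slope_phylo
        ) * table[other].mean()
        ax.plot(grid, partial, color="crimson")
        ax.set_xlabel(label)
    axes[0].set_ylabel("ln similarity")
    fig.suptitle(fit.metric or "distance decay")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
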