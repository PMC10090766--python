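"""Similarity and distance matrices.

Three families of pairwise quantity drive the distance-decay analysis:

* community similarity between host species (Jaccard on presence/absence,
  Bray-Curtis on prevalence or mean abundance);
* phylogenetic distance between host species (uncorrected p-distance from
  an equal-length marker alignment, pairwise deletion of gaps/ambiguities);
* geographic distance between capture sites (great-circle, haversine on a
  sphere of mean radius 6371.0088 km).
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import DistanceMatrix, InfectionTable, SequenceAlignment, SiteTable
from .exceptions import (
    DimensionError,
    DomainError,
    UndefinedDistanceError,
    UndefinedSimilarityError,
)

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


# ---------------------------------------------------------------------------
# Element-wise similarity
# ---------------------------------------------------------------------------


def jaccard_similarity(x, y) -> float:
    """Jaccard similarity ``a / (a + b + c)`` between two 0/1 vectors.

    ``a`` counts shared presences, ``b`` and ``c`` the presences unique to
    each community. Two empty communities are defined as identical (J = 1);
    downstream analyses exclude uninfected hosts before this matters.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise DimensionError(f"length mismatch: {x.shape} vs {y.shape}")
    xb = x > 0
    yb = y > 0
    union = int(np.sum(xb | yb))
    if union == 0:
        return 1.0
    return float(np.sum(xb & yb) / union)


def bray_curtis_similarity(x, y) -> float:
    """Bray-Curtis similarity ``1 - sum|x - y| / sum(x + y)`` on abundances."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DimensionError(f"length mismatch: {x.shape} vs {y.shape}")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundance vectors must be nonnegative")
    denom = float(np.sum(x + y))
    if denom == 0:
        raise UndefinedSimilarityError("Bray-Curtis undefined for two all-zero vectors")
    return 1.0 - float(np.sum(np.abs(x - y)) / denom)


_METRICS = {"jaccard": jaccard_similarity, "braycurtis": bray_curtis_similarity}


def similarity_matrix(
    profiles: Mapping[str, Sequence[float] | pd.Series | np.ndarray],
    metric: str = "jaccard",
) -> DistanceMatrix:
    """Pairwise similarity matrix among labelled descriptor vectors.

    The companion dissimilarity (1 - S) used by ordination and PERMANOVA is
    available as ``result.to_dissimilarity()``.
    """
    if metric not in _METRICS:
        raise DomainError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    labels = list(profiles)
    mat = np.asarray([np.asarray(profiles[l], dtype=float) for l in labels])
    n = len(labels)
    if metric == "jaccard":
        b = (mat > 0).astype(float)
        shared = b @ b.T
        sizes = b.sum(axis=1)
        union = sizes[:, None] + sizes[None, :] - shared
        with np.errstate(invalid="ignore"):
            values = np.where(union > 0, shared / np.maximum(union, 1e-300), 1.0)
    else:
        if (mat < 0).any():
            raise ValueError("abundance vectors must be nonnegative")
        from scipy.spatial.distance import cdist

        absdiff = cdist(mat, mat, metric="cityblock")
        sums = mat.sum(axis=1)
        denom = sums[:, None] + sums[None, :]
        if (np.diag(denom) == 0).any():
            raise UndefinedSimilarityError("Bray-Curtis undefined for an all-zero vector")
        values = 1.0 - absdiff / denom
    np.fill_diagonal(values, 1.0)
    values = (values + values.T) / 2  # exact symmetry against float noise
    values = np.clip(values, 0.0, 1.0)  # guard float spill just outside [0, 1]
    return DistanceMatrix(labels, values, "similarity")


def individual_similarity_matrix(
    table: InfectionTable, data: str = "presence", metric: str = "jaccard"
) -> DistanceMatrix:
    """Among-individual similarity (infracommunity level).

    ``data`` selects presence/absence or raw counts (total abundance).
    """
    mat = table.presence if data == "presence" else table.counts
    return similarity_matrix({ind: mat.loc[ind].to_numpy() for ind in mat.index}, metric)


# ---------------------------------------------------------------------------
# Phylogenetic distance
# ---------------------------------------------------------------------------


def p_distance(seq_a: str, seq_b: str) -> float:
    """Uncorrected p-distance between two aligned sequences.

    Sites where either sequence has a gap or an N are excluded (pairwise
    deletion); the distance is mismatches / compared sites.
    """
    a = np.frombuffer(seq_a.encode(), dtype="S1")
    b = np.frombuffer(seq_b.encode(), dtype="S1")
    if a.shape != b.shape:
        raise DimensionError("sequences differ in length")
    usable = ~(np.isin(a, [b"-", b"N"]) | np.isin(b, [b"-", b"N"]))
    n = int(usable.sum())
    if n == 0:
        raise UndefinedDistanceError("no comparable sites after pairwise deletion")
    return float(np.sum(a[usable] != b[usable]) / n)


def p_distance_matrix(aln: SequenceAlignment) -> DistanceMatrix:
    """Pairwise uncorrected p-distances among all species in an alignment."""
    codes = aln.species
    if len(codes) < 2:
        raise DomainError("need at least two sequences")
    n = len(codes)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = p_distance(aln[codes[i]], aln[codes[j]])
    return DistanceMatrix(codes, values, "p_distance")


# ---------------------------------------------------------------------------
# Geographic distance
# ---------------------------------------------------------------------------


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance between two decimal-degree points, in km."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def majority_site(table: InfectionTable) -> dict[str, str]:
    """Species -> site assignment by majority vote among conspecifics.

    Generalizes the convention of treating a single individual caught at an
    odd site as if captured with its conspecifics; ties break to the
    lexicographically smallest site id.
    """
    out: dict[str, str] = {}
    for sp in table.species:
        inds = table.host_species_of.index[table.host_species_of == sp]
        sites = table.site_of.loc[inds]
        counts = sites.value_counts()
        top = counts[counts == counts.max()].index
        out[sp] = sorted(top)[0]
    return out


def geographic_distance_matrix(
    sites: SiteTable, site_of_species: Mapping[str, str]
) -> DistanceMatrix:
    """Great-circle distances (km) between the sites of each species pair."""
    species = list(site_of_species)
    for sp, site in site_of_species.items():
        if site not in sites:
            raise KeyError(f"species {sp!r} mapped to unknown site {site!r}")
    n = len(species)
    values = np.zeros((n, n))
    for i in range(n):
        lat1, lon1 = sites[site_of_species[species[i]]]
        for j in range(i + 1, n):
            lat2, lon2 = sites[site_of_species[species[j]]]
            values[i, j] = values[j, i] = haversine_km(lat1, lon1, lat2, lon2)
    return DistanceMatrix(species, values, "geographic_km")


# ---------------------------------------------------------------------------
# Transform
# ---------------------------------------------------------------------------


def log_transform_similarity(values, epsilon: float = 0.0) -> np.ndarray:
    """ln(S + epsilon) applied to similarity values in [0, 1].

    ``epsilon`` defaults to 0 and a zero similarity then raises, so the
    handling of empty overlap is an explicit user decision rather than a
    silent offset.
    """
    if epsilon < 0:
        raise DomainError("epsilon must be >= 0")
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any() or (arr > 1 + 1e-12).any():
        raise DomainError("similarities must lie in [0, 1]")
    shifted = arr + epsilon
    if (shifted <= 0).any():
        raise DomainError(
            "log of zero similarity: pass epsilon > 0 or drop zero-similarity pairs"
        )
    return np.log(shifted)
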