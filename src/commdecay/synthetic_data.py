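"""Synthetic host-parasite assemblage generator.

Emulates a single-survey study design: a handful of related host species
captured at largely species-segregated sites, one marker sequence per
species, and overdispersed parasite counts whose community similarity
between host species decays at configurable rates with host phylogenetic
distance and site separation.

The generative model:

1. A Yule (pure-birth) tree over the host species, scaled to a chosen
   root-to-tip depth in expected substitutions/site; one marker sequence per
   species evolved along the tree under Jukes-Cantor.
2. Capture sites drawn uniformly in a bounding box; each species assigned
   one site.
3. Each parasite taxon draws an affinity species and an affinity site. Its
   occurrence probability in host species ``s`` is
   ``p0 * exp(-lambda_phylo * d_phylo(s, affinity))
        * exp(-lambda_geo * d_geo(site_s, affinity_site))``.
   Where a taxon occurs in a species, per-individual counts are negative
   binomial (mean ``mu0``, dispersion ``k``; variance mu + mu^2/k). A
   fraction of host individuals is forced uninfected, mirroring hosts with
   no worms at necropsy.

Defaults reproduce the scale of the motivating survey: 8 species, 52 host
individuals, 35 parasite taxa, 585 bp marker, around a thousand parasite
individuals in total.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    HostMetadata,
    InfectionTable,
    SequenceAlignment,
    SiteTable,
)
from .exceptions import ConfigError

_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters of the synthetic assemblage model."""

    n_species: int = 8
    # per-species examined hosts; study-scale default sums to 52
    n_individuals_per_species: int | Sequence[int] = (3, 5, 6, 8, 7, 12, 4, 7)
    n_sites: int = 8
    lat_range: tuple[float, float] = (-44.5, -43.0)
    lon_range: tuple[float, float] = (174.0, 180.0)
    seq_length: int = 585
    tree_depth: float = 0.12  # expected substitutions/site, root to tip
    n_parasites: int = 35
    base_occurrence: float = 0.65  # p0
    lambda_phylo: float = 8.0  # per unit p-distance
    lambda_geo: float = 0.0  # per km
    mean_abundance: float = 2.0  # mu0, per infected-species host
    nb_dispersion: float = 0.7  # k; variance = mu + mu^2/k
    p_uninfected_host: float = 6 / 52
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ConfigError("n_species must be >= 2")
        if not 0.0 <= self.base_occurrence <= 1.0:
            raise ConfigError("base_occurrence must lie in [0, 1]")
        if not 0.0 <= self.p_uninfected_host <= 1.0:
            raise ConfigError("p_uninfected_host must lie in [0, 1]")
        for name in ("lambda_phylo", "lambda_geo", "tree_depth"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("mean_abundance", "nb_dispersion"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")

    @property
    def individuals_per_species(self) -> list[int]:
        if isinstance(self.n_individuals_per_species, int):
            return [self.n_individuals_per_species] * self.n_species
        counts = list(self.n_individuals_per_species)
        if len(counts) != self.n_species:
            raise ConfigError(
                f"n_individuals_per_species has {len(counts)} entries for "
                f"{self.n_species} species"
            )
        return counts

    @property
    def species_codes(self) -> list[str]:
        return [f"SP{i+1:02d}" for i in range(self.n_species)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_individuals_per_species"] = self.individuals_per_species
        return d


# ---------------------------------------------------------------------------
# Host phylogeny and sequences
# ---------------------------------------------------------------------------


@dataclass
class _Node:
    height: float = 0.0  # distance above the tips (ultrametric)
    children: tuple["_Node", "_Node"] | None = None
    tip: int | None = None


def _yule_tree(n: int, rng: np.random.Generator) -> tuple[_Node, np.ndarray]:
    """Ultrametric Yule tree normalized to unit root-to-tip height.

    Pure-birth forward simulation: with ``k`` lineages the next split waits
    Exp(k); a uniformly chosen lineage bifurcates. Returns the root and the
    (n, n) patristic distance matrix in units of tree height.
    """
    t = 0.0
    split_times = []
    for k in range(1, n):
        t += rng.exponential(1.0 / k)
        split_times.append(t)
    total = t + rng.exponential(1.0 / n)  # tips observed after the last split

    root = _Node()
    active = [root]
    for st in split_times:
        parent = active.pop(int(rng.integers(len(active))))
        parent.height = total - st
        parent.children = (_Node(), _Node())
        active.extend(parent.children)
    for idx, leaf in enumerate(active):
        leaf.tip = idx

    scale = root.height if root.height > 0 else 1.0

    def rescale(node: _Node) -> None:
        node.height /= scale
        if node.children:
            for c in node.children:
                rescale(c)

    rescale(root)

    dmat = np.zeros((n, n))

    def tips_under(node: _Node) -> list[int]:
        if node.children is None:
            return [node.tip]
        return tips_under(node.children[0]) + tips_under(node.children[1])

    def fill(node: _Node) -> None:
        if node.children is None:
            return
        for i in tips_under(node.children[0]):
            for j in tips_under(node.children[1]):
                dmat[i, j] = dmat[j, i] = 2 * node.height
        for c in node.children:
            fill(c)

    fill(root)
    return root, dmat


def _evolve_jc(seq: np.ndarray, branch: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve a sequence along a branch of given expected substitutions/site."""
    p_change = 0.75 * (1.0 - np.exp(-4.0 * branch / 3.0))
    out = seq.copy()
    hit = rng.random(seq.size) < p_change
    if hit.any():
        # substitute to one of the three other bases, uniformly
        idx = np.flatnonzero(hit)
        current = np.searchsorted(_BASES, out[idx])
        shift = rng.integers(1, 4, size=idx.size)
        out[idx] = _BASES[(current + shift) % 4]
    return out


def simulate_host_phylogeny(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[SequenceAlignment, np.ndarray]:
    """Yule tree + Jukes-Cantor sequences for the host species.

    Returns the alignment and the true patristic distance matrix in
    expected substitutions/site (tree scaled so root-to-tip =
    ``cfg.tree_depth``). Species order matches ``cfg.species_codes``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    root, dmat = _yule_tree(cfg.n_species, rng)
    dmat = dmat * cfg.tree_depth

    codes = cfg.species_codes
    seqs: dict[str, str] = {}
    root_seq = _BASES[rng.integers(0, 4, size=cfg.seq_length)]

    def descend(node: _Node, seq: np.ndarray) -> None:
        if node.children is None:
            seqs[codes[node.tip]] = seq.tobytes().decode()
            return
        for child in node.children:
            branch = (node.height - child.height) * cfg.tree_depth
            descend(child, _evolve_jc(seq, branch, rng))

    descend(root, root_seq)
    ordered = {c: seqs[c] for c in codes}
    return SequenceAlignment(ordered), dmat


def simulate_sites(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[SiteTable, dict[str, str]]:
    """Uniform sites in the bounding box and a species -> site assignment.

    Species are site-segregated: with at least as many sites as species the
    assignment is injective (a random matching); otherwise sites are drawn
    with replacement.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if cfg.n_sites < 1:
        raise ConfigError("n_sites must be >= 1")
    lat = rng.uniform(*cfg.lat_range, size=cfg.n_sites)
    lon = rng.uniform(*cfg.lon_range, size=cfg.n_sites)
    site_ids = [f"T{i+1:03d}" for i in range(cfg.n_sites)]
    sites = SiteTable({s: (float(a), float(o)) for s, a, o in zip(site_ids, lat, lon)})

    codes = cfg.species_codes
    if cfg.n_sites >= cfg.n_species:
        chosen = rng.permutation(cfg.n_sites)[: cfg.n_species]
    else:
        chosen = rng.integers(0, cfg.n_sites, size=cfg.n_species)
    site_of_species = {sp: site_ids[int(c)] for sp, c in zip(codes, chosen)}
    return sites, site_of_species


# ---------------------------------------------------------------------------
# Assemblages
# ---------------------------------------------------------------------------


def _taxon_groups(n_parasites: int) -> list[str]:
    """Digenean/cestode/nematode assignment in survey-like proportions."""
    n_dig = round(0.40 * n_parasites)
    n_ces = round(0.31 * n_parasites)
    groups = ["digenean"] * n_dig + ["cestode"] * n_ces
    groups += ["nematode"] * (n_parasites - len(groups))
    return groups


def simulate_assemblages(
    cfg: SimulationConfig,
    aln: SequenceAlignment,
    sites: SiteTable,
    site_of_species: dict[str, str],
    rng: np.random.Generator | None = None,
) -> InfectionTable:
    """Draw an infection table under the occurrence-decay model."""
    from .distances import geographic_distance_matrix, p_distance_matrix

    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    codes = cfg.species_codes
    dphylo = p_distance_matrix(aln).submatrix(codes)
    dgeo = geographic_distance_matrix(sites, {c: site_of_species[c] for c in codes})

    per_species = cfg.individuals_per_species
    individuals: list[str] = []
    species_of: dict[str, str] = {}
    site_of: dict[str, str] = {}
    for sp, n_ind in zip(codes, per_species):
        for i in range(n_ind):
            ind = f"{sp}_{i+1:02d}"
            individuals.append(ind)
            species_of[ind] = sp
            site_of[ind] = site_of_species[sp]

    taxa = [f"par{j+1:02d}" for j in range(cfg.n_parasites)]
    groups = dict(zip(taxa, _taxon_groups(cfg.n_parasites)))
    counts = pd.DataFrame(0, index=individuals, columns=taxa, dtype=np.int64)

    site_ids = sites.site_ids
    sp_index = {c: i for i, c in enumerate(codes)}
    from .distances import haversine_km

    for taxon in taxa:
        affinity_sp = codes[int(rng.integers(len(codes)))]
        affinity_site = site_ids[int(rng.integers(len(site_ids)))]
        for sp, n_ind in zip(codes, per_species):
            d_ph = dphylo.values[sp_index[sp], sp_index[affinity_sp]]
            lat1, lon1 = sites[site_of_species[sp]]
            lat2, lon2 = sites[affinity_site]
            d_km = haversine_km(lat1, lon1, lat2, lon2)
            p_occ = (
                cfg.base_occurrence
                * np.exp(-cfg.lambda_phylo * d_ph)
                * np.exp(-cfg.lambda_geo * d_km)
            )
            if rng.random() < p_occ:
                mu, k = cfg.mean_abundance, cfg.nb_dispersion
                draws = rng.negative_binomial(k, k / (k + mu), size=n_ind)
                inds = [f"{sp}_{i+1:02d}" for i in range(n_ind)]
                counts.loc[inds, taxon] = draws

    # force a fraction of hosts to be uninfected (kept in the table)
    n_total = len(individuals)
    n_clear = int(round(cfg.p_uninfected_host * n_total))
    if n_clear:
        cleared = rng.choice(n_total, size=n_clear, replace=False)
        counts.iloc[cleared] = 0

    # keep only taxa actually observed
    counts = counts.loc[:, counts.sum(axis=0) > 0]
    groups = {t: groups[t] for t in counts.columns}

    return InfectionTable(
        counts=counts,
        host_species_of=pd.Series(species_of),
        site_of=pd.Series(site_of),
        group_of_taxon=groups,
    )


# ---------------------------------------------------------------------------
# Bundled dataset
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    infections: InfectionTable
    sites: SiteTable
    site_of_species: dict[str, str]
    alignment: SequenceAlignment
    metadata: HostMetadata
    truth: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the CSV/FASTA files the core readers consume."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "infections": out / "infections.csv",
            "sites": out / "sites.csv",
            "alignment": out / "alignment.fasta",
            "hosts": out / "hosts.csv",
            "truth": out / "truth.json",
        }
        self.infections.write_csv(paths["infections"])
        self.sites.write_csv(paths["sites"])
        self.alignment.write_fasta(paths["alignment"])
        self.metadata.write_csv(paths["hosts"])
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=2, default=float)
        return paths


def _simulate_metadata(
    cfg: SimulationConfig, individuals_by_species: dict[str, list[str]], rng: np.random.Generator
) -> HostMetadata:
    """Per-individual lengths (species-specific lognormal) and F-biased sex."""
    length: dict[str, float] = {}
    sex: dict[str, str] = {}
    base = rng.uniform(25.0, 70.0, size=len(individuals_by_species))
    for (sp, inds), mu in zip(individuals_by_species.items(), base):
        for ind in inds:
            if rng.random() < 0.8:  # some lengths missing, as in field data
                length[ind] = float(np.round(mu * np.exp(rng.normal(0, 0.12)), 1))
            if rng.random() < 0.8:
                sex[ind] = "F" if rng.random() < 0.75 else "M"
    return HostMetadata(length_cm=length, sex=sex)


def generate_dataset(cfg: SimulationConfig, out_dir: str | Path | None = None) -> SyntheticDataset:
    """Generate a complete dataset (alignment, sites, infections, metadata).

    All randomness flows from ``cfg.seed``. The returned bundle carries the
    ground-truth generative parameters and the true patristic distances for
    parameter-recovery tests; ``out_dir`` optionally writes the same
    CSV/FASTA files the readers in ``core_io`` consume.
    """
    rng = np.random.default_rng(cfg.seed)
    aln, true_dist = simulate_host_phylogeny(cfg, rng)
    sites, site_of_species = simulate_sites(cfg, rng)
    infections = simulate_assemblages(cfg, aln, sites, site_of_species, rng)

    inds_by_sp = {
        sp: [i for i in infections.individuals if infections.host_species_of[i] == sp]
        for sp in cfg.species_codes
    }
    metadata = _simulate_metadata(cfg, inds_by_sp, rng)

    truth = {
        "config": cfg.to_dict(),
        "true_patristic_distances": {
            "labels": cfg.species_codes,
            "values": true_dist.tolist(),
        },
        "site_of_species": site_of_species,
    }
    dataset = SyntheticDataset(
        config=cfg,
        infections=infections,
        sites=sites,
        site_of_species=site_of_species,
        alignment=aln,
        metadata=metadata,
        truth=truth,
    )
    if out_dir is not None:
        dataset.write(out_dir)
    return dataset
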