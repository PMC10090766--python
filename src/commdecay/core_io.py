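"""Data model and file I/O for host-parasite community datasets.

The dataset for a survey of parasite assemblages consists of three files:

* a long-format infection table (CSV): one row per host individual and
  parasite taxon with a count of parasite individuals recovered;
* a site table (CSV): trawl/capture locations in decimal degrees;
* a host marker alignment (FASTA): one pre-aligned, equal-length sequence
  per host species, used for uncorrected p-distances.

Uninfected host individuals are first-class citizens: they are declared in
the infection CSV with ``count=0`` rows and retained in the table, because
community descriptors include them while some multivariate analyses exclude
them downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .exceptions import (
    AlignmentError,
    AlphabetError,
    ConsistencyError,
    DimensionError,
    RangeError,
    SchemaError,
)

TAXON_GROUPS = ("digenean", "cestode", "nematode", "other")

_INFECTION_COLUMNS = ("individual_id", "host_species", "site_id", "parasite_taxon", "count")
_SITE_COLUMNS = ("site_id", "latitude", "longitude")
_ALLOWED_BASES = set("ACGTN-")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class InfectionTable:
    """Counts of each parasite taxon in each host individual.

    Attributes
    ----------
    counts
        Integer DataFrame indexed by individual id with one column per
        parasite taxon. Absent pairs are 0.
    host_species_of
        Series mapping individual id -> host species code.
    site_of
        Series mapping individual id -> site id.
    group_of_taxon
        Mapping taxon -> higher group (digenean/cestode/nematode/other).
    """

    counts: pd.DataFrame
    host_species_of: pd.Series
    site_of: pd.Series
    group_of_taxon: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative parasite counts")
        idx = self.counts.index
        for name, series in (("host_species_of", self.host_species_of), ("site_of", self.site_of)):
            missing = idx.difference(series.index)
            if len(missing):
                raise ConsistencyError(f"{name} missing for individuals: {sorted(missing)[:5]}")
        self.host_species_of = self.host_species_of.reindex(idx)
        self.site_of = self.site_of.reindex(idx)
        for taxon in self.taxa:
            self.group_of_taxon.setdefault(taxon, "other")

    # -- views ------------------------------------------------------------

    @property
    def individuals(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def species(self) -> list[str]:
        return sorted(self.host_species_of.unique())

    @property
    def presence(self) -> pd.DataFrame:
        """0/1 presence matrix, same shape as ``counts``."""
        return (self.counts > 0).astype(np.int64)

    def total_parasites(self) -> int:
        return int(self.counts.to_numpy().sum())

    def uninfected_individuals(self) -> list[str]:
        mask = self.counts.sum(axis=1) == 0
        return list(self.counts.index[mask])

    def drop_uninfected(self) -> "InfectionTable":
        """Copy without fully uninfected individuals (used before PERMANOVA)."""
        keep = self.counts.sum(axis=1) > 0
        return InfectionTable(
            counts=self.counts.loc[keep].copy(),
            host_species_of=self.host_species_of.loc[keep].copy(),
            site_of=self.site_of.loc[keep].copy(),
            group_of_taxon=dict(self.group_of_taxon),
        )

    def subset_group(self, group: str) -> "InfectionTable":
        """Restrict to one parasite group (digenean/cestode/nematode)."""
        taxa = [t for t in self.taxa if self.group_of_taxon.get(t) == group]
        return InfectionTable(
            counts=self.counts[taxa].copy(),
            host_species_of=self.host_species_of.copy(),
            site_of=self.site_of.copy(),
            group_of_taxon={t: group for t in taxa},
        )

    def merge_taxa(self, merge_map: Mapping[str, str]) -> "InfectionTable":
        """Merge morphologically indistinguishable taxa.

        ``merge_map`` maps source taxon -> target taxon; counts are summed.
        """
        counts = self.counts.copy()
        groups = dict(self.group_of_taxon)
        for src, dst in merge_map.items():
            if src not in counts.columns:
                continue
            if dst not in counts.columns:
                counts[dst] = 0
                groups[dst] = groups.get(src, "other")
            counts[dst] = counts[dst] + counts[src]
            counts = counts.drop(columns=[src])
            groups.pop(src, None)
        return InfectionTable(counts, self.host_species_of.copy(), self.site_of.copy(), groups)

    # -- I/O ---------------------------------------------------------------

    def to_long(self) -> pd.DataFrame:
        """Long-format frame with zero-count declaration rows for uninfected hosts."""
        rows = []
        for ind in self.individuals:
            sp = self.host_species_of[ind]
            site = self.site_of[ind]
            row = self.counts.loc[ind]
            positive = row[row > 0]
            if positive.empty:
                first = self.taxa[0] if self.taxa else "none"
                rows.append((ind, sp, site, first, 0, self.group_of_taxon.get(first, "other")))
            for taxon, n in positive.items():
                rows.append((ind, sp, site, taxon, int(n), self.group_of_taxon.get(taxon, "other")))
        return pd.DataFrame(
            rows,
            columns=list(_INFECTION_COLUMNS) + ["taxon_group"],
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, index=False)


@dataclass(frozen=True)
class SiteTable:
    """Capture sites with decimal-degree coordinates."""

    coordinates: dict[str, tuple[float, float]]  # site_id -> (lat, lon)

    def __post_init__(self) -> None:
        for site, (lat, lon) in self.coordinates.items():
            if not -90.0 <= lat <= 90.0:
                raise RangeError(f"site {site!r}: latitude {lat} outside [-90, 90]")
            if not -180.0 <= lon <= 180.0:
                raise RangeError(f"site {site!r}: longitude {lon} outside [-180, 180]")

    @property
    def site_ids(self) -> list[str]:
        return list(self.coordinates)

    def __len__(self) -> int:
        return len(self.coordinates)

    def __contains__(self, site: str) -> bool:
        return site in self.coordinates

    def __getitem__(self, site: str) -> tuple[float, float]:
        return self.coordinates[site]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s, lat, lon) for s, (lat, lon) in self.coordinates.items()],
            columns=list(_SITE_COLUMNS),
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class SequenceAlignment:
    """Equal-length marker sequences keyed by host species code."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
        for code, seq in self.sequences.items():
            bad = set(seq) - _ALLOWED_BASES
            if bad:
                raise AlphabetError(f"sequence {code!r}: invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def species(self) -> list[str]:
        return list(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, code: str) -> str:
        return self.sequences[code]

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for code, seq in self.sequences.items():
                fh.write(f">{code}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")


@dataclass(frozen=True)
class HostMetadata:
    """Per-individual length (cm) and sex; either may be missing."""

    length_cm: dict[str, float]  # only individuals with a measurement
    sex: dict[str, str]  # values in {"F", "M"}

    def __post_init__(self) -> None:
        for ind, length in self.length_cm.items():
            if not length > 0:
                raise RangeError(f"individual {ind!r}: nonpositive length {length}")
        for ind, s in self.sex.items():
            if s not in {"F", "M"}:
                raise RangeError(f"individual {ind!r}: sex must be F or M, got {s!r}")

    def to_frame(self) -> pd.DataFrame:
        inds = sorted(set(self.length_cm) | set(self.sex))
        return pd.DataFrame(
            {
                "individual_id": inds,
                "length_cm": [self.length_cm.get(i, np.nan) for i in inds],
                "sex": [self.sex.get(i, "") for i in inds],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class DistanceMatrix:
    """Labelled symmetric nonnegative matrix.

    ``kind`` distinguishes similarity (diagonal 1, values in [0, 1]) from
    dissimilarity / p-distance / geographic matrices (diagonal 0).
    """

    labels: list[str]
    values: np.ndarray
    kind: str  # similarity | dissimilarity | p_distance | geographic_km

    _KINDS = ("similarity", "dissimilarity", "p_distance", "geographic_km")

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.values.shape != (n, n):
            raise DimensionError(f"expected {n}x{n} matrix, got shape {self.values.shape}")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("matrix is not symmetric")
        if (self.values < -1e-12).any():
            raise ValueError("matrix has negative entries")
        diag = np.diag(self.values)
        expected = 1.0 if self.kind == "similarity" else 0.0
        if not np.allclose(diag, expected, atol=1e-10):
            raise ValueError(f"diagonal must be {expected} for kind {self.kind!r}")
        if self.kind in ("similarity", "p_distance") and (self.values > 1 + 1e-12).any():
            raise ValueError(f"{self.kind} values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.labels)

    def loc(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def submatrix(self, labels: Iterable[str]) -> "DistanceMatrix":
        labels = list(labels)
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)], self.kind)

    def reorder(self, labels: Iterable[str]) -> "DistanceMatrix":
        return self.submatrix(labels)

    def to_dissimilarity(self) -> "DistanceMatrix":
        """1 - S companion matrix for a similarity matrix."""
        if self.kind != "similarity":
            raise ValueError("to_dissimilarity applies to similarity matrices")
        return DistanceMatrix(self.labels, 1.0 - self.values, "dissimilarity")

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in scipy ``pdist`` order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def pairs(self):
        """Yield (label_a, label_b, value) once per unordered pair."""
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                yield self.labels[i], self.labels[j], float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)

    def write_phylip(self, path: str | Path) -> None:
        """PHYLIP square distance format (used for p-distance export)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.values):
                fh.write(label + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, kind: str) -> "DistanceMatrix":
        return cls(list(df.index), df.to_numpy(dtype=float), kind)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def read_infection_csv(path: str | Path) -> InfectionTable:
    """Read a long-format infection CSV into a validated :class:`InfectionTable`.

    Required header: ``individual_id,host_species,site_id,parasite_taxon,count``
    with an optional ``taxon_group`` column. Rows sharing an (individual,
    taxon) pair are summed. Uninfected individuals may be declared with a
    single ``count=0`` row.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    _require_columns(df, _INFECTION_COLUMNS, path)

    counts = pd.to_numeric(df["count"], errors="coerce")
    if counts.isna().any():
        bad = df.loc[counts.isna(), "count"].iloc[0]
        raise ValueError(f"{path}: non-numeric count {bad!r}")
    if (counts != counts.round()).any():
        raise ValueError(f"{path}: counts must be integers")
    if (counts < 0).any():
        raise ValueError(f"{path}: counts must be >= 0")
    df = df.assign(count=counts.astype(np.int64))

    # one species and one site per individual
    for col in ("host_species", "site_id"):
        per_ind = df.groupby("individual_id")[col].nunique()
        conflicted = per_ind[per_ind > 1]
        if len(conflicted):
            raise ConsistencyError(
                f"{path}: individual(s) {list(conflicted.index)[:5]} mapped to multiple {col} values"
            )

    pivot = (
        df.groupby(["individual_id", "parasite_taxon"])["count"].sum().unstack(fill_value=0)
    )
    # drop taxa that never occur (zero-declaration placeholders)
    pivot = pivot.loc[:, pivot.sum(axis=0) > 0]
    meta = df.drop_duplicates("individual_id").set_index("individual_id")
    pivot = pivot.reindex(meta.index, fill_value=0)
    pivot.index.name = None
    pivot.columns.name = None
    meta.index.name = None

    group_of: dict[str, str] = {}
    if "taxon_group" in df.columns:
        for taxon, grp in df.groupby("parasite_taxon")["taxon_group"].agg(
            lambda s: next((g for g in s if g), "")
        ).items():
            if taxon in pivot.columns:
                group_of[taxon] = grp if grp in TAXON_GROUPS else "other"

    return InfectionTable(
        counts=pivot,
        host_species_of=meta["host_species"],
        site_of=meta["site_id"],
        group_of_taxon=group_of,
    )


def read_sites_csv(path: str | Path) -> SiteTable:
    """Read a ``site_id,latitude,longitude`` CSV into a :class:`SiteTable`."""
    df = pd.read_csv(path, dtype={"site_id": str})
    _require_columns(df, _SITE_COLUMNS, path)
    if df["site_id"].duplicated().any():
        dups = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
        raise ConsistencyError(f"{path}: duplicate site id(s) {dups}")
    coords = {
        str(row.site_id): (float(row.latitude), float(row.longitude))
        for row in df.itertuples()
    }
    return SiteTable(coords)


def read_fasta_alignment(path: str | Path) -> SequenceAlignment:
    """Read a pre-aligned FASTA; record ids are species codes.

    Sequences are uppercased and RNA ``U`` is mapped to ``T``; any other
    character outside {A,C,G,T,N,-} is an :class:`AlphabetError`.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ConsistencyError(f"{path}: duplicate species code {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper().replace("U", "T")
    if not seqs:
        raise SchemaError(f"{path}: no FASTA records found")
    return SequenceAlignment(seqs)


def read_hosts_csv(path: str | Path) -> HostMetadata:
    """Read per-individual ``individual_id,length_cm,sex`` metadata."""
    df = pd.read_csv(path, dtype={"individual_id": str, "sex": str})
    _require_columns(df, ("individual_id", "length_cm", "sex"), path)
    length = {
        str(r.individual_id): float(r.length_cm)
        for r in df.itertuples()
        if pd.notna(r.length_cm)
    }
    sex = {
        str(r.individual_id): str(r.sex)
        for r in df.itertuples()
        if isinstance(r.sex, str) and r.sex in {"F", "M"}
    }
    return HostMetadata(length_cm=length, sex=sex)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Report-only consistency check across the three dataset files."""

    species_missing_sequence: list[str]
    individuals_at_unknown_sites: list[str]
    uninfected_individuals: list[str]

    @property
    def issues(self) -> list[str]:
        out = [f"species {s!r} missing from alignment" for s in self.species_missing_sequence]
        out += [f"individual {i!r} at unknown site" for i in self.individuals_at_unknown_sites]
        return out

    @property
    def ok(self) -> bool:
        return not self.issues

    def to_json(self) -> str:
        return json.dumps(
            {
                "ok": self.ok,
                "species_missing_sequence": self.species_missing_sequence,
                "individuals_at_unknown_sites": self.individuals_at_unknown_sites,
                "uninfected_individuals": self.uninfected_individuals,
            },
            indent=2,
        )


def validate_dataset(
    infections: InfectionTable,
    sites: SiteTable,
    aln: SequenceAlignment,
) -> ValidationReport:
    """Cross-check a dataset; never raises, returns a report.

    Uninfected individuals are listed informationally (they are valid and
    only excluded by specific downstream analyses), while missing sequences
    or unknown sites are genuine issues.
    """
    missing_seq = sorted(set(infections.species) - set(aln.species))
    unknown_site = sorted(
        ind for ind in infections.individuals if infections.site_of[ind] not in sites
    )
    return ValidationReport(
        species_missing_sequence=missing_seq,
        individuals_at_unknown_sites=unknown_site,
        uninfected_individuals=infections.uninfected_individuals(),
    )
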