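"""Parasite community descriptors at two organisational levels.

*Infracommunity*: all parasites within one host individual — species
richness and total abundance per host.

*Component community*: all parasites in a host-species population —
presence/absence, prevalence (proportion of examined conspecific hosts
infected) and mean abundance (parasite individuals per examined host,
counting uninfected hosts in the denominator, sensu Bush et al.).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import InfectionTable
from .exceptions import DomainError


@dataclass(frozen=True)
class InfracommunityRecord:
    """Richness/abundance of the parasite infracommunity of one host."""

    individual: str
    richness: int
    total_abundance: int
    presence: pd.Series  # 0/1 over taxa


@dataclass(frozen=True)
class ComponentProfile:
    """Component-community descriptor vectors for one host species."""

    species: str
    n_hosts: int
    presence: pd.Series  # 0/1 per taxon
    prevalence: pd.Series  # proportion infected, in [0, 1]
    mean_abundance: pd.Series  # parasites per examined host

    def vector(self, metric: str) -> pd.Series:
        """Descriptor vector by name: presence | prevalence | mean_abundance."""
        try:
            return {"presence": self.presence,
                    "prevalence": self.prevalence,
                    "mean_abundance": self.mean_abundance}[metric]
        except KeyError:
            raise DomainError(f"unknown descriptor {metric!r}") from None


def infracommunity(table: InfectionTable) -> list[InfracommunityRecord]:
    """Per-individual richness and total abundance, uninfected hosts included."""
    presence = table.presence
    richness = presence.sum(axis=1)
    total = table.counts.sum(axis=1)
    return [
        InfracommunityRecord(
            individual=ind,
            richness=int(richness[ind]),
            total_abundance=int(total[ind]),
            presence=presence.loc[ind],
        )
        for ind in table.individuals
    ]


def infracommunity_frame(table: InfectionTable) -> pd.DataFrame:
    """Tabular form of :func:`infracommunity` with species/site attribution."""
    recs = infracommunity(table)
    return pd.DataFrame(
        {
            "individual_id": [r.individual for r in recs],
            "host_species": [table.host_species_of[r.individual] for r in recs],
            "site_id": [table.site_of[r.individual] for r in recs],
            "richness": [r.richness for r in recs],
            "total_abundance": [r.total_abundance for r in recs],
        }
    )


def component_profiles(table: InfectionTable) -> dict[str, ComponentProfile]:
    """Component-community descriptors per host species.

    Prevalence and mean abundance use the number of examined conspecific
    hosts (infected + uninfected) as denominator.
    """
    profiles: dict[str, ComponentProfile] = {}
    species_of = table.host_species_of
    for sp in table.species:
        inds = species_of.index[species_of == sp]
        n = len(inds)
        if n == 0:
            raise DomainError(f"species {sp!r} has no examined individuals")
        block = table.counts.loc[inds]
        infected = (block > 0).sum(axis=0)
        prevalence = infected / n
        mean_abundance = block.sum(axis=0) / n
        profiles[sp] = ComponentProfile(
            species=sp,
            n_hosts=n,
            presence=(infected > 0).astype(np.int64),
            prevalence=prevalence.astype(float),
            mean_abundance=mean_abundance.astype(float),
        )
    return profiles


def component_frame(profiles: dict[str, ComponentProfile]) -> pd.DataFrame:
    """Long export: one row per (species, taxon) with P and MA."""
    rows = []
    for sp, prof in profiles.items():
        for taxon in prof.presence.index:
            rows.append(
                (
                    sp,
                    taxon,
                    int(prof.presence[taxon]),
                    float(prof.prevalence[taxon]),
                    float(prof.mean_abundance[taxon]),
                )
            )
    return pd.DataFrame(
        rows, columns=["host_species", "parasite_taxon", "presence", "prevalence", "mean_abundance"]
    )
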