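"""Full-analysis orchestration.

Runs the complete chain on one dataset: validation, community descriptors,
similarity/phylogenetic/geographic matrices, PERMANOVA + PERMDISP +
pairwise tests at the infracommunity level, the three distance-decay
regressions, richness GLMs, and the species accumulation curve. Each stage
writes JSON/CSV into the output directory, and a run manifest records input
hashes, seeds and the package version so a rerun with identical inputs is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .accumulation import accumulation_curve
from .core_io import (
    HostMetadata,
    InfectionTable,
    read_fasta_alignment,
    read_hosts_csv,
    read_infection_csv,
    read_sites_csv,
    validate_dataset,
)
from .decay import DECAY_METRICS, build_decay_table, permutation_regression_test
from .descriptors import component_frame, component_profiles, infracommunity_frame
from .distances import (
    geographic_distance_matrix,
    individual_similarity_matrix,
    majority_site,
    p_distance_matrix,
)
from .exceptions import CommdecayError
from .multivariate import hac_average_linkage, pairwise_permanova, pcoa, permanova, permdisp
from .richness_models import richness_glms

log = logging.getLogger("commdecay")

STAGES = (
    "validate",
    "descriptors",
    "distances",
    "multivariate",
    "decay",
    "richness",
    "accumulation",
)

DEFAULT_CONFIG: dict[str, Any] = {
    "n_permutations": 999,  # multivariate tests and decay regressions
    "n_permutations_accumulation": 1000,
    # ln(S + epsilon): species pairs sharing no taxa have S = 0, so the
    # orchestrated run makes the offset decision explicitly, once, here
    "epsilon": 0.01,
    "seed": 0,
    "decay_scheme": "matrix_permute",
}


def _to_jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if hasattr(obj, "to_dict"):
        return _to_jsonable(obj.to_dict())
    return obj


def _write_json(path: Path, payload) -> None:
    with open(path, "w") as fh:
        json.dump(_to_jsonable(payload), fh, indent=2, sort_keys=True, default=str)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(CommdecayError):
    """Wraps a failure with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_full_analysis(
    infections_path: str | Path,
    sites_path: str | Path,
    alignment_path: str | Path,
    out_dir: str | Path,
    hosts_path: str | Path | None = None,
    config: dict[str, Any] | None = None,
) -> dict:
    """Execute every analysis stage and write results under ``out_dir``.

    Returns the manifest dict. Any stage error aborts with a
    :class:`StageError` naming the stage; results of completed stages are
    preserved on disk.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    n_perm = int(cfg["n_permutations"])
    rng = np.random.default_rng(seed)

    inputs = {
        "infections": Path(infections_path),
        "sites": Path(sites_path),
        "alignment": Path(alignment_path),
    }
    if hosts_path is not None:
        inputs["hosts"] = Path(hosts_path)

    manifest: dict[str, Any] = {
        "version": __version__,
        "config": cfg,
        "inputs": {},
        "stages": [],
    }
    for name, path in inputs.items():
        if not path.exists():
            raise StageError("validate", FileNotFoundError(f"missing input file: {path}"))
        manifest["inputs"][name] = {"path": str(path), "sha256": _hash_file(path)}

    def stage(name: str):
        log.info("stage %s", name)
        manifest["stages"].append(name)

    try:
        stage("validate")
        infections = read_infection_csv(inputs["infections"])
        sites = read_sites_csv(inputs["sites"])
        aln = read_fasta_alignment(inputs["alignment"])
        metadata: HostMetadata | None = (
            read_hosts_csv(inputs["hosts"]) if "hosts" in inputs else None
        )
        report = validate_dataset(infections, sites, aln)
        (out / "validation.json").write_text(report.to_json())
        if not report.ok:
            raise CommdecayError("dataset validation failed: " + "; ".join(report.issues))
    except StageError:
        raise
    except Exception as e:
        raise StageError("validate", e) from e

    try:
        stage("descriptors")
        infracommunity_frame(infections).to_csv(out / "infracommunity.csv", index=False)
        profiles = component_profiles(infections)
        component_frame(profiles).to_csv(out / "component_profiles.csv", index=False)
    except Exception as e:
        raise StageError("descriptors", e) from e

    try:
        stage("distances")
        dphylo = p_distance_matrix(aln).submatrix(sorted(profiles))
        dgeo = geographic_distance_matrix(sites, majority_site(infections))
        dgeo = dgeo.submatrix(sorted(profiles))
        dphylo.write_csv(out / "p_distance.csv")
        dgeo.write_csv(out / "geographic_km.csv")
    except Exception as e:
        raise StageError("distances", e) from e

    try:
        stage("multivariate")
        infected = infections.drop_uninfected()
        # species need >= 2 infected hosts to contribute to infracommunity
        # tests (dispersion is undefined for singleton groups)
        sizes = infected.host_species_of.value_counts()
        too_small = sorted(sizes.index[sizes < 2])
        if too_small:
            log.warning("excluding species with <2 infected hosts: %s", too_small)
            keep = ~infected.host_species_of.isin(too_small)
            infected = InfectionTable(
                counts=infected.counts.loc[keep].copy(),
                host_species_of=infected.host_species_of.loc[keep].copy(),
                site_of=infected.site_of.loc[keep].copy(),
                group_of_taxon=dict(infected.group_of_taxon),
            )
        groups = infected.host_species_of.to_dict()
        multivar: dict[str, Any] = {"excluded_species": too_small}
        for data, metric in (("presence", "jaccard"), ("abundance", "braycurtis")):
            sim = individual_similarity_matrix(infected, data=data, metric=metric)
            diss = sim.to_dissimilarity()
            res = permanova(diss, groups, n_perm=n_perm, seed=int(rng.integers(2**31)))
            disp = permdisp(diss, groups, n_perm=n_perm, seed=int(rng.integers(2**31)))
            pw = pairwise_permanova(diss, groups, n_perm=n_perm, seed=int(rng.integers(2**31)))
            ord_res = pcoa(diss, n_axes=2)
            ord_res.to_frame().to_csv(out / f"pcoa_{data}.csv")
            root, linkage = hac_average_linkage(diss)
            np.savetxt(
                out / f"hac_{data}.csv",
                linkage,
                delimiter=",",
                header="child_a,child_b,height,size",
                comments="",
            )
            multivar[data] = {
                "permanova": res.to_dict(),
                "permdisp": disp.to_dict(),
                "pairwise_permanova": [r.to_dict() for r in pw],
                "pcoa_goodness": ord_res.goodness,
                "pcoa_stress1": ord_res.stress1,
            }
        # component-community dendrograms (one per descriptor)
        for descriptor in ("presence", "prevalence", "mean_abundance"):
            from .distances import similarity_matrix

            metric = "jaccard" if descriptor == "presence" else "braycurtis"
            sim = similarity_matrix(
                {sp: profiles[sp].vector(descriptor).to_numpy() for sp in sorted(profiles)},
                metric=metric,
            )
            root, linkage = hac_average_linkage(sim.to_dissimilarity())
            np.savetxt(
                out / f"hac_component_{descriptor}.csv",
                linkage,
                delimiter=",",
                header="child_a,child_b,height,size",
                comments="",
            )
        _write_json(out / "multivariate.json", multivar)
    except Exception as e:
        raise StageError("multivariate", e) from e

    try:
        stage("decay")
        decay_out: dict[str, Any] = {}
        for metric in DECAY_METRICS:
            table = build_decay_table(
                profiles, metric, dphylo, dgeo, epsilon=float(cfg["epsilon"])
            )
            table.to_csv(out / f"decay_table_{metric}.csv", index=False)
            fit = permutation_regression_test(
                table,
                n_perm=n_perm,
                seed=int(rng.integers(2**31)),
                scheme=str(cfg["decay_scheme"]),
                metric=metric,
            )
            decay_out[metric] = fit.to_dict()
        _write_json(out / "decay.json", decay_out)
    except Exception as e:
        raise StageError("decay", e) from e

    try:
        stage("richness")
        glms = richness_glms(infections, metadata)
        payload = {
            pred: {
                "lrt": block["lrt"],
                "aic": block["aic"],
                "fits": {fam: fit.summary_dict() for fam, fit in block["fits"].items()},
                **({"n_with_length": block["n_with_length"]} if "n_with_length" in block else {}),
            }
            for pred, block in glms.items()
        }
        _write_json(out / "richness_glms.json", payload)
    except Exception as e:
        raise StageError("richness", e) from e

    try:
        stage("accumulation")
        curve = accumulation_curve(
            infections,
            n_perm=int(cfg["n_permutations_accumulation"]),
            seed=int(rng.integers(2**31)),
        )
        curve.to_csv(out / "accumulation.csv", index=False)
    except Exception as e:
        raise StageError("accumulation", e) from e

    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(_to_jsonable({k: manifest[k] for k in ("config", "inputs")}), sort_keys=True).encode()
    ).hexdigest()
    _write_json(out / "manifest.json", manifest)
    return manifest
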