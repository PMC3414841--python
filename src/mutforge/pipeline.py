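"""One-command orchestration of the full analysis over a catalog directory.

The pipeline runs spectrum -> NMF -> clustering -> kataegis -> doublets ->
transcription -> indels over a set of per-sample catalogs.  Stages are
isolated: a failed stage yields an error record and later independent
stages still run.  All parameters and seeds are echoed into the report for
provenance, and re-running an identical config reproduces every stochastic
output bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .catalog import MutationCatalog

logger = logging.getLogger(__name__)

_DEFAULTS = {
    "seed": 17,
    "nmf": {"k_min": 2, "k_max": 8, "n_runs": 100, "max_iter": 2000, "tol": 1e-6,
            "cophenetic_threshold": 0.95},
    "kataegis": {"min_cluster_size": 6, "imd_threshold": 1000, "macro_gap": 1_000_000},
    "doublets": {"n_sims": 1000},
    "transcription": {"n_bins": 8},
    "indels": {"mh_min": 2, "max_unit": 6},
}


class ConfigError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    reference: str | None = None
    substitutions: list[str] = field(default_factory=list)  # VCF paths
    indels: list[str] = field(default_factory=list)
    rearrangements: str | None = None
    genes: str | None = None
    islands: str | None = None
    expression: str | None = None
    output_dir: str = "mutforge_out"
    seed: int = 17
    nmf: dict = field(default_factory=lambda: dict(_DEFAULTS["nmf"]))
    kataegis: dict = field(default_factory=lambda: dict(_DEFAULTS["kataegis"]))
    doublets: dict = field(default_factory=lambda: dict(_DEFAULTS["doublets"]))
    transcription: dict = field(default_factory=lambda: dict(_DEFAULTS["transcription"]))
    indel_params: dict = field(default_factory=lambda: dict(_DEFAULTS["indels"]))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


_KNOWN_KEYS = {
    "reference", "substitutions", "indels", "rearrangements", "genes", "islands",
    "expression", "output_dir", "seed", "nmf", "kataegis", "doublets",
    "transcription", "indel_params",
}


def validate_config(path: str | os.PathLike | None = None, raw: dict | None = None) -> AnalysisConfig:
    """Load, default-fill, and range-check a YAML config.  Idempotent:
    validating an already-normalized config returns the same config."""
    if raw is None:
        raw = {}
        if path is not None:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = AnalysisConfig()
    for key, val in raw.items():
        if isinstance(getattr(cfg, key), dict) and isinstance(val, dict):
            merged = dict(getattr(cfg, key))
            bad = set(val) - set(merged)
            if bad:
                raise ConfigError(f"unknown keys in {key!r}: {sorted(bad)}")
            merged.update(val)
            setattr(cfg, key, merged)
        else:
            setattr(cfg, key, val)
    if cfg.kataegis["imd_threshold"] <= 0:
        raise ConfigError("kataegis.imd_threshold must be positive")
    if cfg.kataegis["min_cluster_size"] < 2:
        raise ConfigError("kataegis.min_cluster_size must be >= 2")
    if cfg.doublets["n_sims"] < 100:
        raise ConfigError("doublets.n_sims must be >= 100")
    if not 1 <= cfg.nmf["k_min"] <= cfg.nmf["k_max"]:
        raise ConfigError("nmf k range invalid")
    return cfg


@dataclass
class StageResult:
    name: str
    status: str  # ok | skipped | error
    detail: str = ""
    outputs: list[str] = field(default_factory=list)


@dataclass
class ReportBundle:
    config: AnalysisConfig
    stages: list[StageResult]
    chosen_k: int | None = None
    n_kataegis_clusters: int | None = None

    def write_log(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"mutforge {__version__}\n")
            fh.write(f"config_hash {self.config.config_hash()}\n")
            fh.write(f"seed {self.config.seed}\n")
            for s in self.stages:
                fh.write(f"stage {s.name}: {s.status} {s.detail}\n")


def run_pipeline(config: AnalysisConfig) -> ReportBundle:
    from . import io as mio
    from .doublets import monte_carlo_adjacency_test
    from .indels import classification_frame, classify_all
    from .kataegis import call_kataegis, clusters_to_frame, rainfall
    from .nmf import cluster_samples, extract_signatures, select_rank
    from .spectrum import build_spectrum_matrix
    from .transcription import assign_all, strand_bias_report

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[StageResult] = []
    bundle = ReportBundle(config, stages)

    if config.reference is None or not config.substitutions:
        raise ConfigError("pipeline requires 'reference' and 'substitutions'")
    genome = mio.read_reference(config.reference)
    catalogs: list[MutationCatalog] = []
    for vcf in config.substitutions:
        recs = mio.read_substitutions(vcf, genome=genome)
        by_sample: dict[str, list] = {}
        for r in recs:
            by_sample.setdefault(r.sample_id, []).append(r)
        for sid, rs in sorted(by_sample.items()):
            catalogs.append(MutationCatalog(sid, rs))

    spectrum = None
    try:
        spectrum = build_spectrum_matrix(catalogs, genome)
        spectrum.write(out / "spectrum.tsv")
        stages.append(StageResult("spectrum", "ok", outputs=["spectrum.tsv"]))
    except Exception as exc:  # noqa: BLE001 - stage isolation
        stages.append(StageResult("spectrum", "error", str(exc)))

    if spectrum is not None:
        try:
            nmf_cfg = config.nmf
            sel = select_rank(
                spectrum,
                range(nmf_cfg["k_min"], nmf_cfg["k_max"] + 1),
                n_runs=nmf_cfg["n_runs"],
                seed=config.seed,
                cophenetic_threshold=nmf_cfg["cophenetic_threshold"],
                max_iter=nmf_cfg["max_iter"],
                tol=nmf_cfg["tol"],
            )
            sel.to_frame().to_csv(out / "model_selection.tsv", sep="\t", index=False)
            bundle.chosen_k = sel.chosen_k
            sigset = extract_signatures(
                spectrum, sel.chosen_k, n_runs=nmf_cfg["n_runs"], seed=config.seed,
                max_iter=nmf_cfg["max_iter"], tol=nmf_cfg["tol"],
            )
            sigset.write(out / "signatures.tsv", out / "exposures.tsv")
            if len(catalogs) >= 2:
                cluster_samples(sigset)
            stages.append(
                StageResult("signatures", "ok", f"chosen_k={sel.chosen_k}",
                            ["model_selection.tsv", "signatures.tsv", "exposures.tsv"])
            )
        except Exception as exc:  # noqa: BLE001
            stages.append(StageResult("signatures", "error", str(exc)))

    try:
        kcfg = config.kataegis
        n_clusters = 0
        frames = []
        for cat in catalogs:
            clusters, _ = call_kataegis(
                rainfall(cat), kcfg["min_cluster_size"], kcfg["imd_threshold"],
                kcfg["macro_gap"],
            )
            n_clusters += len(clusters)
            df = clusters_to_frame(clusters)
            df.insert(0, "sample", cat.sample_id)
            frames.append(df)
        import pandas as pd

        pd.concat(frames, ignore_index=True).to_csv(
            out / "kataegis.tsv", sep="\t", index=False
        )
        bundle.n_kataegis_clusters = n_clusters
        stages.append(StageResult("kataegis", "ok", f"{n_clusters} clusters", ["kataegis.tsv"]))
    except Exception as exc:  # noqa: BLE001
        stages.append(StageResult("kataegis", "error", str(exc)))

    try:
        rows = []
        for cat in catalogs:
            res = monte_carlo_adjacency_test(
                cat, genome.chrom_lengths, config.doublets["n_sims"], config.seed
            )
            rows.append(
                {"sample": cat.sample_id, "observed": res.observed,
                 "sim_mean": res.sim_mean, "fold": res.fold_enrichment,
                 "p": res.empirical_p}
            )
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "doublets.tsv", sep="\t", index=False)
        stages.append(StageResult("doublets", "ok", outputs=["doublets.tsv"]))
    except Exception as exc:  # noqa: BLE001
        stages.append(StageResult("doublets", "error", str(exc)))

    if config.genes:
        try:
            genes = mio.read_genes(config.genes)
            assigned = [a for cat in catalogs for a in assign_all(cat, genes)]
            strand_bias_report(assigned, genome, genes).to_csv(
                out / "strand_bias.tsv", sep="\t", index=False
            )
            stages.append(StageResult("transcription", "ok", outputs=["strand_bias.tsv"]))
        except Exception as exc:  # noqa: BLE001
            stages.append(StageResult("transcription", "error", str(exc)))
    else:
        stages.append(StageResult("transcription", "skipped", "no gene annotation supplied"))

    if config.indels:
        try:
            all_cls = []
            for vcf in config.indels:
                recs = mio.read_indels(vcf, genome)
                all_cls.extend(
                    classify_all(recs, genome, config.indel_params["mh_min"],
                                 config.indel_params["max_unit"])
                )
            classification_frame(all_cls).to_csv(out / "indels.tsv", sep="\t", index=False)
            stages.append(StageResult("indels", "ok", outputs=["indels.tsv"]))
        except Exception as exc:  # noqa: BLE001
            stages.append(StageResult("indels", "error", str(exc)))
    else:
        stages.append(StageResult("indels", "skipped", "no indel input supplied"))

    bundle.write_log(out / "run_log.txt")
    return bundle
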