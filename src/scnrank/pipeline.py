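"""End-to-end run orchestration with a reproducibility manifest.

A run executes the four stages in order — over-expression selection on
tissue samples, paired network construction, spectral clustering of the
tissue network, Target Influence ranking on the cell-line network — and
writes each stage's TSV outputs plus a JSON manifest of parameters,
input checksums and stage counts. Replaying a config+seed reproduces the
manifest byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

from . import io as scio
from .diffexpr import results_to_frame, select_overexpressed
from .network import (build_cellline_network, build_tissue_network,
                      network_to_frames)
from .preprocess import (collapse_probes, essentiality_from_sgrna,
                         filter_probes, knn_impute, log2_transform,
                         quantile_normalize)
from .spectral import spectral_cluster
from .tiscore import rank_targets

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass
class RunConfig:
    """All inputs and tunables of a full run.

    Defaults follow the published procedure: alpha 0.05, Welch unpaired
    t-test, KNN K=10, probes dropped above 20% missing, Hartigan
    threshold 10, all PPI edges kept.
    """

    tissue_expr: str = ""
    tissue_labels: str = ""
    cellline_expr: str = ""
    cellline_labels: str = ""
    probe_map: str = ""          # optional probe->gene TSV ("" = gene-level input)
    ppi: str = ""
    sgrna: str = ""
    targets: str = ""
    out_dir: str = "scnrank_out"
    alpha: float = 0.05
    test_variant: str = "welch"
    knn_k: int = 10
    max_missing_frac: float = 0.20
    min_ppi_score: int = 0
    log2_offset: float = 0.0     # 0 = input already log2
    apply_log2: bool = False
    m_eigen: int | None = None
    k_clusters: int | None = None  # None = auto via Hartigan
    k_max: int = 10
    hartigan_threshold: float = 10.0
    path_mode: str = "logprod"
    seed: int = 0

    def validate(self) -> None:
        required = ["tissue_expr", "tissue_labels", "cellline_expr",
                    "cellline_labels", "ppi", "sgrna", "targets"]
        missing = [f for f in required if not getattr(self, f)]
        if missing:
            raise ConfigError(f"missing config fields: {missing}")
        for f in required + (["probe_map"] if self.probe_map else []):
            p = getattr(self, f)
            if not Path(p).exists():
                raise ConfigError(f"input file not found: {f} = {p}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _preprocess_matrix(cfg: RunConfig, expr_path: str, label_path: str):
    pm = scio.read_probe_matrix(expr_path, label_path,
                                cfg.probe_map if cfg.probe_map else None)
    pm = filter_probes(pm, cfg.max_missing_frac)
    pm = knn_impute(pm, k=cfg.knn_k)
    if pm.probe_to_gene is None:
        pm.probe_to_gene = {p: p for p in pm.probe_ids}  # gene-level input
    em = collapse_probes(pm)
    em = quantile_normalize(em)
    if cfg.apply_log2:
        em = log2_transform(em, offset=cfg.log2_offset)
    return em


def run_all(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": asdict(config),
        "inputs": {f: _sha256(getattr(config, f))
                   for f in ["tissue_expr", "tissue_labels", "cellline_expr",
                             "cellline_labels", "ppi", "sgrna", "targets"]
                   if getattr(config, f)},
        "counts": {},
        "stages": [],
    }

    def stage(name: str, fn):
        logger.info("stage %s ...", name)
        try:
            result = fn()
        except (ConfigError,) as exc:
            raise
        except Exception as exc:
            raise StageError(f"stage {name} failed: {exc}") from exc
        manifest["stages"].append(name)
        return result

    tissue = stage("preprocess.tissue",
                   lambda: _preprocess_matrix(config, config.tissue_expr,
                                              config.tissue_labels))
    cellline = stage("preprocess.cellline",
                     lambda: _preprocess_matrix(config, config.cellline_expr,
                                                config.cellline_labels))
    ppi = stage("read.ppi", lambda: scio.read_ppi(config.ppi, config.min_ppi_score))
    sgrna = stage("read.sgrna", lambda: scio.read_sgrna(config.sgrna))
    targets = stage("read.targets", lambda: scio.read_gene_list(config.targets))

    diff = stage("diffexpr", lambda: select_overexpressed(
        tissue, alpha=config.alpha, variant=config.test_variant))
    manifest["counts"]["genes_tested"] = len(tissue.gene_ids)
    manifest["counts"]["genes_selected"] = len(diff)
    results_to_frame(diff).to_csv(out / "diffexpr.tsv", sep="\t", index=False)

    tissue_net = stage("network.tissue",
                       lambda: build_tissue_network(tissue, diff, ppi))
    ess = stage("essentiality", lambda: essentiality_from_sgrna(sgrna))
    cl_net = stage("network.cellline",
                   lambda: build_cellline_network(cellline, tissue_net, ess))
    manifest["counts"]["genes_after_ppi_overlap"] = len(tissue_net.nodes)
    manifest["counts"]["network_edges"] = len(tissue_net.edges)
    for name, net in (("tissue", tissue_net), ("cellline", cl_net)):
        edges, nodes = network_to_frames(net)
        edges.to_csv(out / f"network_{name}_edges.tsv", sep="\t", index=False)
        nodes.to_csv(out / f"network_{name}_nodes.tsv", sep="\t", index=False)

    assignment = stage("spectral", lambda: spectral_cluster(
        tissue_net, m=config.m_eigen, k=config.k_clusters, seed=config.seed,
        k_max=config.k_max, hartigan_threshold=config.hartigan_threshold))
    manifest["counts"]["K"] = assignment.K
    scio.write_clusters(assignment.assignment, out / "clusters.tsv")
    if assignment.hartigan_trace is not None:
        assignment.hartigan_trace.to_frame().to_csv(
            out / "hartigan_trace.tsv", sep="\t", index=False)

    table = stage("rank", lambda: rank_targets(cl_net, assignment, targets,
                                               mode=config.path_mode))
    frame = table.to_frame()
    manifest["counts"]["targets_mapped"] = len(frame)
    scio.write_ranked_targets(frame, out / "ranked_targets.tsv")
    reps = sorted(table.representatives.items())
    with open(out / "cluster_representatives.tsv", "w") as fh:
        fh.write("cluster_id\tgene\n")
        for c, g in reps:
            fh.write(f"{c}\t{g}\n")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("run complete: %s", manifest["counts"])
    return manifest


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML (or JSON) run config; unknown keys are rejected."""
    import yaml
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    valid = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
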