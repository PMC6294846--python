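"""End-to-end orchestration: DEG screen -> network -> annotations -> GBA.

A :class:`PipelineConfig` fixes every input path (or a synthetic-mode
simulation config), every threshold and one master seed; ``run_pipeline``
executes the stages, writes each stage's outputs as inspectable text
files, and returns a manifest that makes the run reproducible (config
hash, seed substreams, per-stage row counts).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .annotations import (
    filter_terms,
    load_annotations,
    write_term_table,
)
from .degs import DifferentialExpression
from .errors import ConfigurationError, NetworkError
from .expression import ExpressionMatrix
from .gba import NeighborVoting
from .network import build_network, node_degrees, spearman_matrix, threshold_subnetwork
from .simulate import (
    STREAM_CV,
    SimulationConfig,
    generate_annotations,
    generate_expression,
    substream,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    Either the three input paths are set, or ``simulation`` provides a
    synthetic dataset. Threshold defaults are the published screen:
    p < 0.02, |log2FC| > 2, subnetwork weight > 0.8, term size > 20,
    optimal-function AUC > 0.7, 3-fold cross-validation.
    """

    matrix_path: str | None = None
    design_path: str | None = None
    annotations_path: str | None = None
    annotations_format: str = "two_column"
    simulation: SimulationConfig | None = None

    p_threshold: float = 0.02
    lfc_threshold: float = 2.0
    subnetwork_weight: float = 0.8
    min_term_genes: int = 20
    auc_threshold: float = 0.7
    n_folds: int = 3
    moderated: bool = True
    signed_threshold: bool = False
    vote_on_subnetwork: bool = False
    universe: str = "degs"            # "degs" or "matrix"
    top_k_hubs: int = 7

    seed: int = 0
    outdir: str = "netgba_out"

    _KNOWN = None  # populated below

    def __post_init__(self) -> None:
        if self.simulation is None and not (
            self.matrix_path and self.design_path and self.annotations_path
        ):
            raise ConfigurationError(
                "either simulation settings or all three input paths are required"
            )
        if not 0 < self.p_threshold <= 1:
            raise ConfigurationError("p_threshold must lie in (0, 1]")
        if self.lfc_threshold < 0:
            raise ConfigurationError("lfc_threshold must be non-negative")
        if not 0 <= self.subnetwork_weight <= 1:
            raise ConfigurationError("subnetwork_weight must lie in [0, 1]")
        if not 0 <= self.auc_threshold <= 1:
            raise ConfigurationError("auc_threshold must lie in [0, 1]")
        if self.min_term_genes < 0:
            raise ConfigurationError("min_term_genes must be non-negative")
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be at least 2")
        if self.universe not in ("degs", "matrix"):
            raise ConfigurationError("universe must be 'degs' or 'matrix'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("config file must be a mapping")
        known = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
            sim_unknown = set(sim) - sim_known
            if sim_unknown:
                raise ConfigurationError(
                    f"unknown simulation keys: {sorted(sim_unknown)}"
                )
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("_KNOWN", None)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write their outputs under ``config.outdir``.

    Returns the run manifest (also written as ``manifest.json``).
    Identical config + seed give identical outputs; any stage failure
    propagates with the stage name while earlier outputs stay on disk.
    """
    cfg = config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": cfg.to_dict(),
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "seed_substreams": {"cv": [cfg.seed, STREAM_CV]},
        "stages": {},
    }

    # stage: input / simulate ------------------------------------------
    truth = None
    if cfg.simulation is not None:
        sim = dataclasses.replace(cfg.simulation, seed=cfg.seed)
        matrix, truth = generate_expression(sim)
        ann_full, truth = generate_annotations(truth, sim)
        matrix.to_tsv(out / "expression.tsv", out / "design.tsv")
        from .annotations import write_gaf, write_two_column

        write_two_column(ann_full, out / "annotations.tsv")
        write_gaf(ann_full, out / "annotations.gaf")
        truth.to_json(out / "ground_truth.json")
        manifest["stages"]["simulate"] = {
            "n_genes": matrix.n_genes,
            "n_samples": matrix.n_samples,
            "n_terms": ann_full.n_terms,
        }
    else:
        matrix = ExpressionMatrix.from_tsv(cfg.matrix_path, cfg.design_path)
        ann_full = None
        manifest["stages"]["input"] = {
            "n_genes": matrix.n_genes,
            "n_samples": matrix.n_samples,
        }

    # stage: degs -------------------------------------------------------
    deg_res = DifferentialExpression(matrix, moderated=cfg.moderated).fit(
        p_threshold=cfg.p_threshold, lfc_threshold=cfg.lfc_threshold
    )
    deg_res.to_tsv(out / "degs.tsv")
    deg_ids = deg_res.deg_ids
    manifest["stages"]["degs"] = {
        "n_tested": len(deg_res.table),
        "n_degs": deg_res.n_degs,
        "d0": deg_res.d0,
        "s0_sq": deg_res.s0_sq,
    }
    if len(deg_ids) < 2:
        raise NetworkError(
            f"only {len(deg_ids)} DEGs selected; cannot build a co-expression network"
        )

    # stage: network ----------------------------------------------------
    srcc = spearman_matrix(matrix, deg_ids)
    srcc.to_csv(out / "srcc_matrix.tsv", sep="\t", float_format="%.6g")
    net = build_network(srcc)
    net.to_edge_tsv(out / "network_edges.tsv")
    net.to_graphml(out / "network.graphml")
    hubs = node_degrees(net, top_k=cfg.top_k_hubs)
    sub = threshold_subnetwork(
        net, min_weight=cfg.subnetwork_weight, signed=cfg.signed_threshold
    )
    sub.to_edge_tsv(out / "subnetwork_edges.tsv")
    if sub.n_nodes:
        sub.to_graphml(out / "subnetwork.graphml")
    sub_hubs = node_degrees(sub, top_k=cfg.top_k_hubs) if sub.n_nodes else []
    with open(out / "hubs.tsv", "w") as fh:
        fh.write("gene_id\tdegree\tnetwork\n")
        for g, dgr in hubs:
            fh.write(f"{g}\t{dgr}\tfull\n")
        for g, dgr in sub_hubs:
            fh.write(f"{g}\t{dgr}\tsubnetwork\n")
    manifest["stages"]["network"] = {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "subnetwork_nodes": sub.n_nodes,
        "subnetwork_edges": sub.n_edges,
        "top_hubs": [g for g, _ in hubs],
    }

    # stage: annotations ------------------------------------------------
    universe = deg_ids if cfg.universe == "degs" else matrix.gene_ids
    if cfg.simulation is not None:
        ann = ann_full.restrict(universe)
        ann = _drop_empty(ann)
    else:
        ann = load_annotations(
            cfg.annotations_path, cfg.annotations_format, universe
        )
    ann = filter_terms(ann, min_genes=cfg.min_term_genes)
    write_term_table(ann, out / "filtered_terms.tsv")
    manifest["stages"]["annotations"] = {
        "n_terms_retained": ann.n_terms,
        "universe_size": len(ann.universe),
    }

    # stage: gba --------------------------------------------------------
    model = NeighborVoting(
        build_network(srcc) if not cfg.vote_on_subnetwork else sub,
        ann,
        restrict_to_edges=cfg.vote_on_subnetwork,
    )
    res = model.fit(
        n_folds=cfg.n_folds,
        seed=int(np.abs(substream(cfg.seed, STREAM_CV).integers(2**31))),
        auc_threshold=cfg.auc_threshold,
    )
    res.to_tsv(out / "term_performance.tsv")
    res.mf_profile.to_csv(out / "mf_scores.tsv", sep="\t", index=False, float_format="%.6g")
    res.auc_histogram().to_csv(out / "auc_histogram.tsv", sep="\t", index=False)
    res.optimal.to_csv(out / "optimal_terms.tsv", sep="\t", index=False, float_format="%.6g")
    manifest["stages"]["gba"] = {
        "n_terms_evaluated": len(res.term_table),
        "mean_auc": res.mean_auc,
        "n_optimal": len(res.optimal),
    }
    if truth is not None:
        manifest["stages"]["gba"]["planted_coherent_terms"] = sorted(
            truth.coherent_terms
        )

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _drop_empty(ann):
    from .annotations import AnnotationSet

    kept = {t: g for t, g in ann.memberships.items() if g}
    return AnnotationSet(
        memberships=kept,
        universe=ann.universe,
        term_names=ann.term_names,
        term_namespaces=ann.term_namespaces,
    )
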