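"""Synthetic two-group expression data with planted signal.

Emulates the study design the pipeline was built for: a small case/control
placental expression experiment (8 samples per arm), a planted set of
differentially expressed genes with large log2 fold changes, correlated
gene modules driven by shared latent factors, and GO-style annotations
that are partially coherent with those modules. Every downstream stage is
therefore testable without any download, and planted ground truth is
available for recovery checks.

Expression model (log2 scale)
-----------------------------
For gene *g* in sample *s*::

    x[g, s] = mu_g + delta_g * 1[s is case]
              + noise_sd * (sqrt(rho) * f[m(g), s] + sqrt(1 - rho) * eps[g, s])

where ``mu_g ~ N(7, 1.5^2)`` is a baseline intensity, ``delta_g`` is the
planted effect (``+-de_lfc_mean`` for DE genes, 0 otherwise), ``f`` is a
standard-normal latent factor shared by all genes of module ``m(g)``
(non-module genes have the factor term replaced by ``eps`` alone), and
``rho = module_rho`` is the population within-module correlation.

Genes belonging to a module share the module's DE direction by default
(a co-regulated module responds to disease coherently); DE *status* is
still planted uniformly, independent of module membership.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import AnnotationSet
from .errors import ConfigurationError
from .expression import ExpressionMatrix

# substream ids hung off the master seed; recorded in run manifests
STREAM_EXPRESSION = 0
STREAM_DE = 1
STREAM_ANNOTATIONS = 2
STREAM_CV = 3


def substream(seed: int, stream: int) -> np.random.Generator:
    """Deterministic child generator for one stage of the simulation."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic dataset.

    Defaults mirror the target study design: two arms of 8 samples,
    planted DE effects beyond the |log2FC| > 2 screen, and GO terms
    large enough to survive the >20-member filter.
    """

    n_genes: int = 500
    n_per_group: int = 8
    n_de_genes: int = 50
    de_lfc_mean: float = 3.0          # log2 units; > 2 so planted DEGs pass the screen
    n_modules: int = 10
    module_size: int = 25
    module_rho: float = 0.7           # population within-module correlation
    noise_sd: float = 1.0             # log2-scale expression noise
    n_terms: int = 20
    n_coherent_terms: int | None = None   # None -> all terms coherent
    term_coherence: float = 0.5       # fraction of a coherent term drawn from one module
    min_term_size: int = 21
    max_term_size: int = 30
    de_sign_by_module: bool = True    # module genes share the module's DE direction
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de_genes > self.n_genes:
            raise ConfigurationError("n_de_genes exceeds n_genes")
        if self.n_modules * self.module_size > self.n_genes:
            raise ConfigurationError("n_modules * module_size exceeds n_genes")
        if not 0.0 <= self.module_rho <= 1.0:
            raise ConfigurationError("module_rho must lie in [0, 1]")
        if not 0.0 <= self.term_coherence <= 1.0:
            raise ConfigurationError("term_coherence must lie in [0, 1]")
        if self.n_per_group < 2:
            raise ConfigurationError("need at least 2 samples per group")
        if self.min_term_size > self.max_term_size:
            raise ConfigurationError("min_term_size exceeds max_term_size")
        if self.max_term_size > self.n_genes:
            raise ConfigurationError("term size exceeds n_genes")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.n_coherent_terms is not None and self.n_coherent_terms > self.n_terms:
            raise ConfigurationError("n_coherent_terms exceeds n_terms")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: DE genes, module structure, coherent terms."""

    de_gene_ids: frozenset[str]
    de_signs: dict[str, int]
    module_assignments: dict[str, int]   # gene -> module id; absent = no module
    coherent_terms: frozenset[str]
    term_modules: dict[str, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "de_gene_ids": sorted(self.de_gene_ids),
            "de_signs": dict(sorted(self.de_signs.items())),
            "module_assignments": dict(sorted(self.module_assignments.items())),
            "coherent_terms": sorted(self.coherent_terms),
            "term_modules": dict(sorted(self.term_modules.items())),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            de_gene_ids=frozenset(d["de_gene_ids"]),
            de_signs={g: int(s) for g, s in d["de_signs"].items()},
            module_assignments={g: int(m) for g, m in d["module_assignments"].items()},
            coherent_terms=frozenset(d["coherent_terms"]),
            term_modules={t: int(m) for t, m in d["term_modules"].items()},
        )


def generate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw an expression matrix and its ground truth from the model above.

    Deterministic: identical config (including seed) gives bit-identical
    output. Expression and DE assignment use separate substreams of the
    master seed, so e.g. changing n_terms does not perturb the matrix.
    """
    cfg = config
    rng_x = substream(cfg.seed, STREAM_EXPRESSION)
    rng_de = substream(cfg.seed, STREAM_DE)

    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    samples = [f"CTRL_{i + 1}" for i in range(cfg.n_per_group)] + [
        f"CASE_{i + 1}" for i in range(cfg.n_per_group)
    ]
    n_samples = 2 * cfg.n_per_group
    is_case = np.r_[np.zeros(cfg.n_per_group), np.ones(cfg.n_per_group)]

    # module membership: a random block of genes per module
    module_of = np.full(cfg.n_genes, -1)
    pool = rng_x.permutation(cfg.n_genes)
    for m in range(cfg.n_modules):
        module_of[pool[m * cfg.module_size:(m + 1) * cfg.module_size]] = m

    # planted DE genes, uniform over all genes (status independent of modules)
    de_idx = rng_de.choice(cfg.n_genes, size=cfg.n_de_genes, replace=False)
    module_signs = rng_de.choice([-1, 1], size=max(cfg.n_modules, 1))
    gene_signs = rng_de.choice([-1, 1], size=cfg.n_genes)
    delta = np.zeros(cfg.n_genes)
    signs = np.zeros(cfg.n_genes, dtype=int)
    for g in de_idx:
        if cfg.de_sign_by_module and module_of[g] >= 0:
            signs[g] = module_signs[module_of[g]]
        else:
            signs[g] = gene_signs[g]
        delta[g] = signs[g] * cfg.de_lfc_mean

    mu = rng_x.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    factors = rng_x.normal(size=(max(cfg.n_modules, 1), n_samples))
    eps = rng_x.normal(size=(cfg.n_genes, n_samples))

    rho = cfg.module_rho
    signal = np.where(
        (module_of >= 0)[:, None],
        np.sqrt(rho) * factors[np.clip(module_of, 0, None), :]
        + np.sqrt(1.0 - rho) * eps,
        eps,
    )
    x = mu[:, None] + np.outer(delta, is_case) + cfg.noise_sd * signal

    matrix = ExpressionMatrix(
        values=pd.DataFrame(x, index=genes, columns=samples),
        groups=pd.Series(
            np.where(is_case == 1, "case", "control"), index=samples
        ),
        control_group="control",
    )
    truth = GroundTruth(
        de_gene_ids=frozenset(genes[i] for i in de_idx),
        de_signs={genes[i]: int(signs[i]) for i in de_idx},
        module_assignments={
            genes[i]: int(module_of[i]) for i in range(cfg.n_genes) if module_of[i] >= 0
        },
        coherent_terms=frozenset(),
    )
    return matrix, truth


def generate_annotations(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[AnnotationSet, GroundTruth]:
    """Plant GO-style term memberships, partially coherent with modules.

    Each coherent term is tied to one module (round-robin over modules);
    a fraction ``term_coherence`` of its members is drawn from that module
    and the remainder uniformly from the other genes. Incoherent terms are
    drawn uniformly. Returns the annotation set together with an updated
    ground truth whose ``coherent_terms`` / ``term_modules`` are filled in.
    """
    cfg = config
    rng = substream(cfg.seed, STREAM_ANNOTATIONS)
    genes = sorted(
        set(truth.module_assignments) | truth.de_gene_ids
        | {f"G{i:04d}" for i in range(cfg.n_genes)}
    )
    by_module: dict[int, list[str]] = {}
    for g, m in truth.module_assignments.items():
        by_module.setdefault(m, []).append(g)
    for m in by_module:
        by_module[m].sort()

    n_coherent = cfg.n_terms if cfg.n_coherent_terms is None else cfg.n_coherent_terms
    memberships: dict[str, frozenset[str]] = {}
    term_modules: dict[str, int] = {}
    coherent: set[str] = set()
    for t in range(cfg.n_terms):
        term = f"GO:{t + 1:07d}"
        size = int(rng.integers(cfg.min_term_size, cfg.max_term_size + 1))
        members: list[str] = []
        if t < n_coherent and by_module:
            m = t % len(by_module)
            module_genes = by_module[m]
            k = min(int(round(cfg.term_coherence * size)), len(module_genes))
            members.extend(map(str, rng.choice(module_genes, size=k, replace=False)))
            coherent.add(term)
            term_modules[term] = m
        rest_pool = [g for g in genes if g not in set(members)]
        n_rest = size - len(members)
        if n_rest > 0:
            members.extend(map(str, rng.choice(rest_pool, size=n_rest, replace=False)))
        memberships[term] = frozenset(members)

    ann = AnnotationSet(
        memberships=memberships,
        universe=frozenset(genes),
        term_names={t: f"synthetic term {t[3:].lstrip('0')}" for t in memberships},
    )
    updated = dataclasses.replace(
        truth, coherent_terms=frozenset(coherent), term_modules=term_modules
    )
    return ann, updated


# -- dataset writer ------------------------------------------------------


def write_dataset(outdir, config: SimulationConfig) -> GroundTruth:
    """Generate and write a full synthetic dataset to ``outdir``.

    Emits the expression TSV, the two-line design file, annotations in
    both GAF 2.2 and two-column TSV form, and a ground-truth JSON.
    """
    from pathlib import Path

    from .annotations import write_gaf, write_two_column

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, truth = generate_expression(config)
    ann, truth = generate_annotations(truth, config)
    matrix.to_tsv(out / "expression.tsv", out / "design.tsv")
    write_gaf(ann, out / "annotations.gaf")
    write_two_column(ann, out / "annotations.tsv")
    truth.to_json(out / "ground_truth.json")
    return truth
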