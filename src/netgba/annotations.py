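"""Gene <-> GO-term annotations: loading, filtering, in/out counts.

Annotations are a bipartite membership structure between genes and GO
terms, restricted to a *universe* of genes. The universe matters because
the multifunctionality score and the neighbor-voting prior count genes
inside versus outside each term; by default downstream code uses the DEG
network's node set as the universe, since voting only ever sees network
neighbors.

Two text formats are supported: GAF 2.x (the standard Gene Association
File; lines whose qualifier contains ``NOT`` are dropped) and a minimal
two-column ``gene<TAB>term`` TSV.
"""

from __future__ import annotations

import logging
import operator
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import AnnotationError, ParseError

log = logging.getLogger(__name__)

_GAF_COLUMNS = 17  # GAF 2.x is 17 tab-separated columns


@dataclass(frozen=True)
class AnnotationSet:
    """Term -> gene memberships over a fixed gene universe.

    Invariant: memberships are subsets of the universe, so for every term
    ``in_count(K) + out_count(K) == len(universe)``.
    """

    memberships: dict[str, frozenset[str]]
    universe: frozenset[str]
    term_names: dict[str, str] = field(default_factory=dict)
    term_namespaces: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.memberships.items():
            extra = genes - self.universe
            if extra:
                raise AnnotationError(
                    f"term {term} annotates genes outside the universe: {sorted(extra)[:3]}"
                )

    @property
    def terms(self) -> list[str]:
        return sorted(self.memberships)

    @property
    def n_terms(self) -> int:
        return len(self.memberships)

    def genes_of(self, term: str) -> frozenset[str]:
        return self.memberships[term]

    def terms_of(self, gene: str) -> set[str]:
        return {t for t, genes in self.memberships.items() if gene in genes}

    def in_count(self, term: str) -> int:
        return len(self.memberships[term])

    def out_count(self, term: str) -> int:
        return len(self.universe) - len(self.memberships[term])

    def restrict(self, universe) -> "AnnotationSet":
        """Project memberships onto a new gene universe (terms may shrink)."""
        uni = frozenset(universe)
        return AnnotationSet(
            memberships={t: g & uni for t, g in self.memberships.items()},
            universe=uni,
            term_names=self.term_names,
            term_namespaces=self.term_namespaces,
        )

    def permuted(self, seed: int) -> "AnnotationSet":
        """Null model: relabel genes by a seeded permutation of the universe.

        Term sizes and the gene-term bipartite degree sequence are
        preserved; any relation between annotations and expression is
        destroyed.
        """
        rng = np.random.default_rng(seed)
        genes = sorted(self.universe)
        relabel = dict(zip(genes, rng.permutation(genes)))
        return AnnotationSet(
            memberships={
                t: frozenset(str(relabel[g]) for g in gs)
                for t, gs in self.memberships.items()
            },
            universe=self.universe,
            term_names=self.term_names,
            term_namespaces=self.term_namespaces,
        )


# -- loading -------------------------------------------------------------


def load_annotations(path, format: str, universe) -> AnnotationSet:
    """Read annotations and restrict them to ``universe``.

    Parameters
    ----------
    path : path-like
        Input file.
    format : {"gaf", "two_column"}
        ``gaf`` expects GAF 2.x (``!`` comment lines skipped, NOT
        qualifiers dropped); ``two_column`` expects ``gene<TAB>term``.
    universe : iterable of str
        Genes against which in/out counts are taken; memberships are
        intersected with it and duplicate pairs collapse.
    """
    uni = frozenset(map(str, universe))
    if not uni:
        raise AnnotationError("empty gene universe")
    if format == "gaf":
        pairs, names = _read_gaf(path)
    elif format == "two_column":
        pairs, names = _read_two_column(path), {}
    else:
        raise ValueError(f"unknown annotation format {format!r}")

    memberships: dict[str, set[str]] = {}
    for gene, term in pairs:
        if gene in uni:
            memberships.setdefault(term, set()).add(gene)
    memberships = {t: g for t, g in memberships.items() if g}
    if not memberships:
        raise AnnotationError(
            f"no annotated gene in {path} intersects the {len(uni)}-gene universe"
        )
    return AnnotationSet(
        memberships={t: frozenset(g) for t, g in memberships.items()},
        universe=uni,
        term_names=names,
    )


def _read_two_column(path) -> list[tuple[str, str]]:
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ParseError("expected gene<TAB>term", path, lineno)
            pairs.append((fields[0], fields[1]))
    return pairs


def _read_gaf(path):
    pairs: list[tuple[str, str]] = []
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(
                    f"GAF line has {len(fields)} columns, expected >= 5", path, lineno
                )
            qualifier, go_id, symbol = fields[3], fields[4], fields[2]
            if not go_id.startswith("GO:"):
                raise ParseError(f"column 5 is not a GO id: {go_id!r}", path, lineno)
            if "NOT" in qualifier.split("|"):
                continue
            pairs.append((symbol, go_id))
    return pairs, names


# -- writing (used by the synthetic generator and the pipeline) ----------


def write_two_column(ann: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        for term in ann.terms:
            for gene in sorted(ann.genes_of(term)):
                fh.write(f"{gene}\t{term}\n")


def write_gaf(ann: AnnotationSet, path) -> None:
    """Write GAF 2.2 with minimal but format-valid columns."""
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for term in ann.terms:
            for gene in sorted(ann.genes_of(term)):
                fields = [""] * _GAF_COLUMNS
                fields[0] = "SYNTH"          # DB
                fields[1] = gene             # DB Object ID
                fields[2] = gene             # DB Object Symbol
                fields[3] = "involved_in"    # Qualifier
                fields[4] = term             # GO ID
                fields[5] = "SYNTH:0"        # DB:Reference
                fields[6] = "IEA"            # Evidence Code
                fields[8] = "P"              # Aspect
                fields[11] = "gene"          # DB Object Type
                fields[12] = "taxon:9606"    # Taxon
                fields[13] = "20180101"      # Date
                fields[14] = "SYNTH"         # Assigned By
                fh.write("\t".join(fields) + "\n")


def write_term_table(ann: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("term\tname\tin_count\n")
        for term in ann.terms:
            fh.write(f"{term}\t{ann.term_names.get(term, '')}\t{ann.in_count(term)}\n")


# -- filtering -----------------------------------------------------------


def filter_terms(
    ann: AnnotationSet, min_genes: int = 20, comparator=operator.gt
) -> AnnotationSet:
    """Keep terms annotating strictly more than ``min_genes`` universe genes.

    The strict ``>`` comparator reflects the "more than 20 DEGs" screen;
    pass ``operator.ge`` for an inclusive cut. Idempotent. Raises
    :class:`AnnotationError` if nothing survives.
    """
    kept = {
        t: g for t, g in ann.memberships.items() if comparator(len(g), min_genes)
    }
    if not kept:
        raise AnnotationError(
            f"no term has {'>' if comparator is operator.gt else 'cmp'}"
            f"{min_genes} genes in the universe; lower min_genes"
        )
    dropped = ann.n_terms - len(kept)
    if dropped:
        log.info("filter_terms: dropped %d of %d terms", dropped, ann.n_terms)
    return AnnotationSet(
        memberships=kept,
        universe=ann.universe,
        term_names=ann.term_names,
        term_namespaces=ann.term_namespaces,
    )


# -- optional ontology propagation --------------------------------------


def propagate_annotations(ann: AnnotationSet, obo_path) -> AnnotationSet:
    """Up-propagate memberships along is_a / part_of edges of an ontology.

    Off the default path: only used when an OBO file is supplied. A gene
    annotated to a term becomes annotated to all its ancestors.
    """
    import networkx as nx
    import obonet

    graph = obonet.read_obo(Path(obo_path))
    keep = {
        (u, v, k) for u, v, k in graph.edges(keys=True) if k in ("is_a", "part_of")
    }
    slim = nx.MultiDiGraph()
    slim.add_nodes_from(graph.nodes)
    slim.add_edges_from(keep)

    memberships: dict[str, set[str]] = {
        t: set(g) for t, g in ann.memberships.items()
    }
    for term in list(ann.memberships):
        if term not in slim:
            continue
        for anc in nx.descendants(slim, term):  # edges point child -> parent
            memberships.setdefault(anc, set()).update(ann.memberships[term])
    names = dict(ann.term_names)
    for node, data in graph.nodes(data=True):
        if "name" in data and node not in names:
            names[node] = data["name"]
    return AnnotationSet(
        memberships={t: frozenset(g) for t, g in memberships.items() if g},
        universe=ann.universe,
        term_names=names,
        term_namespaces=ann.term_namespaces,
    )
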