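"""Guilt-by-association function prediction with multifunctionality control.

The predictor is weighted neighbor voting on the dense co-expression
network: a gene's score for GO term K is the |SRCC|-weighted fraction of
its (visible) network neighbors annotated to K,

    score(i, K) = sum_j |w_ij| 1[j in K] / sum_j |w_ij|,   j visible, j != i.

Because every gene pair carries a weight, voting aggregates both
nearest-neighbor and indirect co-expression evidence. Performance is
function-centric: genes are split into folds, each fold's annotations are
hidden in turn, held-out genes are scored from the visible folds only,
and each term receives the ROC AUC of its held-out members against
held-out non-members (Mann-Whitney form); the fold-averaged AUC is the
term's score and terms above a threshold (0.7) are the "optimal
functions".

Annotation bias is summarised per gene by the multifunctionality score

    MF_i = sum over terms K containing gene i of 1 / (Num_in_K * Num_out_K),

where Num_in_K / Num_out_K count universe genes inside/outside K. The
MF ranking — the same gene ordering for every term — is evaluated
alongside neighbor voting as a network-free baseline, so terms that are
predictable from annotation structure alone are visible as such.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import AnnotationSet
from .errors import ConfigurationError, EvaluationError
from .network import CoexpressionNetwork

log = logging.getLogger(__name__)


# -- primitives ----------------------------------------------------------


def multifunctionality_scores(ann: AnnotationSet) -> pd.DataFrame:
    """Per-gene multifunctionality score and rank.

    MF_i sums 1/(in_count * out_count) over the terms annotating gene i;
    unannotated genes score 0. A term annotating the entire universe
    (out_count = 0) carries no discriminating information and is excluded
    with a warning. Rank 1 is the most multifunctional gene; ties break
    by gene id.
    """
    genes = sorted(ann.universe)
    scores = dict.fromkeys(genes, 0.0)
    for term in ann.terms:
        n_in, n_out = ann.in_count(term), ann.out_count(term)
        if n_in == 0:
            continue
        if n_out == 0:
            log.warning("term %s annotates the whole universe; excluded from MF", term)
            continue
        contrib = 1.0 / (n_in * n_out)
        for g in ann.genes_of(term):
            scores[g] += contrib
    out = pd.DataFrame({"gene_id": genes, "mf_score": [scores[g] for g in genes]})
    out = out.sort_values(["mf_score", "gene_id"], ascending=[False, True], kind="mergesort")
    out["mf_rank"] = np.arange(1, len(out) + 1)
    return out.sort_values("gene_id", kind="mergesort").reset_index(drop=True)


def neighbor_voting_scores(
    net: CoexpressionNetwork,
    ann: AnnotationSet,
    labels_visible,
    restrict_to_edges: bool = False,
) -> pd.DataFrame:
    """Voting score matrix (genes x terms) using only visible labels.

    Every gene in the network is scored for every term from the
    annotations of the visible genes; a gene's own annotations never
    enter its row. When a gene has no weight to any visible gene the
    term prior in_count/|visible| is used. ``restrict_to_edges`` limits
    voting to the network's existing edges (relevant for thresholded
    subnetworks; the dense network already connects every pair).
    """
    nodes = net.nodes
    visible = set(labels_visible) & set(nodes)
    if not visible:
        raise EvaluationError("no visible labelled gene in the network")
    if not set(ann.universe) <= set(nodes):
        raise EvaluationError("annotation universe extends beyond the network nodes")
    terms = ann.terms
    idx = {g: i for i, g in enumerate(nodes)}

    w = net.weight_matrix(nodes, absolute=True).to_numpy(float)  # zero diagonal
    if restrict_to_edges:
        pass  # absent edges are already zero in the dense matrix
    vis = np.zeros(len(nodes))
    vis[[idx[g] for g in visible]] = 1.0
    a = np.zeros((len(nodes), len(terms)))
    for k, term in enumerate(terms):
        for g in ann.genes_of(term):
            if g in idx:
                a[idx[g], k] = 1.0

    num = w @ (a * vis[:, None])
    den = w @ vis
    prior = (a * vis[:, None]).sum(axis=0) / vis.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(den[:, None] > 0, num / den[:, None], prior[None, :])
    return pd.DataFrame(score, index=nodes, columns=terms)


def cv_split(genes, n_folds: int = 3, seed: int = 0) -> list[list[str]]:
    """Seeded partition of genes into near-equal folds.

    The genes are shuffled by a seeded permutation and split; fold sizes
    differ by at most one (larger folds first). Same seed, same partition.
    """
    genes = list(genes)
    if n_folds < 2:
        raise ConfigurationError("need at least 2 folds")
    if n_folds > len(genes):
        raise ConfigurationError(f"{n_folds} folds but only {len(genes)} genes")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(genes)
    return [list(map(str, fold)) for fold in np.array_split(perm, n_folds)]


def roc_auc(scores, positives, negatives) -> float:
    """ROC AUC by the Mann-Whitney rank statistic.

    Equals (#(pos, neg) pairs with score_pos > score_neg + 0.5 * ties)
    / (|pos| * |neg|); ties receive half credit via mid-ranks.
    """
    pos = list(positives)
    neg = list(negatives)
    if set(pos) & set(neg):
        raise EvaluationError("positives and negatives overlap")
    if not pos or not neg:
        raise EvaluationError("positives and negatives must both be nonempty")
    values = np.array([scores[g] for g in pos] + [scores[g] for g in neg], float)
    ranks = stats.rankdata(values)  # mid-ranks
    n_pos, n_neg = len(pos), len(neg)
    r_pos = ranks[:n_pos].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def select_optimal(perf: pd.DataFrame, auc_threshold: float = 0.7) -> pd.DataFrame:
    """Terms whose mean cross-validated AUC strictly exceeds the threshold.

    Sorted by descending mean AUC; may be empty.
    """
    sel = perf[perf["mean_auc"] > auc_threshold]
    return sel.sort_values(
        ["mean_auc", "term"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


# -- cross-validated evaluation -----------------------------------------


def evaluate_terms(
    net: CoexpressionNetwork,
    ann: AnnotationSet,
    n_folds: int = 3,
    seed: int = 0,
    restrict_to_edges: bool = False,
    combined: bool = False,
) -> pd.DataFrame:
    """Per-term cross-validated AUC for neighbor voting and the MF baseline.

    Folds partition *genes*; in each fold the held-out genes' annotations
    are hidden, all genes are rescored from the visible labels, and each
    term's AUC is computed over held-out genes only (held-out members =
    positives, held-out non-members = negatives). Terms with fewer
    positives than folds are skipped. A fold where a term has no held-out
    positive or negative is recorded as missing and excluded from that
    term's mean.

    Returns one row per evaluated term: in_count, auc_fold_1..n, mean_auc,
    n_folds_used, mf_auc (and combined_auc when requested).
    """
    nodes = net.nodes
    ann = ann.restrict(set(nodes) & set(ann.universe))
    folds = cv_split(nodes, n_folds=n_folds, seed=seed)

    terms = []
    for term in ann.terms:
        n_pos = ann.in_count(term)
        if n_pos < n_folds:
            log.warning(
                "term %s has %d positives (< %d folds); skipped", term, n_pos, n_folds
            )
            continue
        if ann.out_count(term) == 0:
            log.warning("term %s annotates every network gene; skipped", term)
            continue
        terms.append(term)
    if not terms:
        raise EvaluationError("no term has enough annotated genes to evaluate")

    # MF baseline: one gene ranking for every term, computed from the full
    # annotation set. It is a bias diagnostic (how far annotation structure
    # alone predicts membership), not a legitimate predictor, so it is not
    # subjected to the fold masking that the voting scores are.
    mf = multifunctionality_scores(ann)
    mf_score = dict(zip(mf["gene_id"], mf["mf_score"]))

    nv_aucs = {t: [] for t in terms}
    mf_aucs = {t: [] for t in terms}
    cb_aucs = {t: [] for t in terms}
    for fold in folds:
        held = set(fold)
        visible = [g for g in nodes if g not in held]
        scores = neighbor_voting_scores(
            net, ann, visible, restrict_to_edges=restrict_to_edges
        )
        for term in terms:
            members = ann.genes_of(term)
            pos = sorted(held & members)
            neg = sorted(held - members)
            if not pos or not neg:
                warnings.warn(
                    f"term {term}: fold without both classes; AUC undefined",
                    stacklevel=2,
                )
                nv_aucs[term].append(np.nan)
                mf_aucs[term].append(np.nan)
                cb_aucs[term].append(np.nan)
                continue
            col = scores[term]
            nv_aucs[term].append(roc_auc(col, pos, neg))
            mf_aucs[term].append(
                roc_auc({g: mf_score.get(g, 0.0) for g in held}, pos, neg)
            )
            if combined:
                held_list = sorted(held)
                nv_rank = stats.rankdata([col[g] for g in held_list])
                mf_rank = stats.rankdata([mf_score.get(g, 0.0) for g in held_list])
                comb = dict(zip(held_list, (nv_rank + mf_rank) / 2.0))
                cb_aucs[term].append(roc_auc(comb, pos, neg))

    rows = []
    for term in terms:
        fold_vals = nv_aucs[term]
        defined = [v for v in fold_vals if not np.isnan(v)]
        row = {
            "term": term,
            "name": ann.term_names.get(term, ""),
            "in_count": ann.in_count(term),
            **{f"auc_fold_{i + 1}": v for i, v in enumerate(fold_vals)},
            "mean_auc": float(np.mean(defined)) if defined else np.nan,
            "n_folds_used": len(defined),
            "mf_auc": float(np.nanmean(mf_aucs[term])) if defined else np.nan,
        }
        if combined:
            row["combined_auc"] = float(np.nanmean(cb_aucs[term])) if defined else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# -- model / results objects --------------------------------------------


@dataclass
class FunctionPredictionResults:
    """Cross-validated per-term performance of the GBA predictor.

    Attributes
    ----------
    term_table : pandas.DataFrame
        One row per evaluated term with fold AUCs, mean_auc, the
        multifunctionality-baseline AUC and the is_optimal flag.
    mf_profile : pandas.DataFrame
        Per-gene multifunctionality score and rank on the full
        annotation set.
    """

    term_table: pd.DataFrame
    mf_profile: pd.DataFrame
    n_folds: int
    seed: int
    auc_threshold: float
    n_genes: int

    @property
    def optimal(self) -> pd.DataFrame:
        """Terms selected as optimal functions (mean AUC > threshold)."""
        return select_optimal(self.term_table, self.auc_threshold)

    @property
    def mean_auc(self) -> float:
        """Average of per-term mean AUCs across all evaluated terms."""
        return float(self.term_table["mean_auc"].mean())

    def auc_histogram(self, bins: int = 10) -> pd.DataFrame:
        """Binned distribution of per-term mean AUCs (histogram data)."""
        counts, edges = np.histogram(
            self.term_table["mean_auc"].dropna(), bins=bins, range=(0.0, 1.0)
        )
        return pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
        )

    def plot_auc_histogram(self, ax=None, bins: int = 10):
        """Histogram of per-term mean AUCs (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        hist = self.auc_histogram(bins=bins)
        ax.bar(
            hist["bin_left"], hist["count"],
            width=hist["bin_right"] - hist["bin_left"],
            align="edge", edgecolor="white",
        )
        ax.axvline(self.auc_threshold, color="firebrick", linestyle="--")
        ax.set_xlabel("mean cross-validated AUC")
        ax.set_ylabel("GO terms")
        return ax

    def summary(self) -> str:
        t = self.term_table
        lines = [
            "Guilt-by-association function prediction",
            "=" * 48,
            f"network genes       {self.n_genes}",
            f"terms evaluated     {len(t)}",
            f"cross-validation    {self.n_folds}-fold, seed {self.seed}",
            f"mean AUC (voting)   {self.mean_auc:.3f}",
            f"mean AUC (MF only)  {t['mf_auc'].mean():.3f}",
            f"optimal functions   {len(self.optimal)} (mean AUC > {self.auc_threshold})",
            "",
            self.optimal[["term", "name", "in_count", "mean_auc", "mf_auc"]]
            .to_string(index=False)
            if len(self.optimal)
            else "(no term exceeds the AUC threshold)",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        out = self.term_table.copy()
        out["is_optimal"] = out["mean_auc"] > self.auc_threshold
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


class NeighborVoting:
    """GBA model: neighbor voting on a co-expression network + annotations.

    Parameters
    ----------
    network : CoexpressionNetwork
        Dense (or thresholded) weighted network over the genes of interest.
    annotations : AnnotationSet
        Term memberships; the universe is restricted to the network nodes.
    restrict_to_edges : bool
        Vote only along existing edges instead of the dense weight matrix.

    Examples
    --------
    >>> model = NeighborVoting(network, annotations)
    >>> res = model.fit(n_folds=3, seed=7)
    >>> print(res.summary())
    """

    def __init__(
        self,
        network: CoexpressionNetwork,
        annotations: AnnotationSet,
        restrict_to_edges: bool = False,
    ):
        self.network = network
        self.annotations = annotations.restrict(
            set(annotations.universe) & set(network.nodes)
        )
        self.restrict_to_edges = restrict_to_edges

    def fit(
        self,
        n_folds: int = 3,
        seed: int = 0,
        auc_threshold: float = 0.7,
        combined: bool = False,
    ) -> FunctionPredictionResults:
        """Run the cross-validated evaluation and package the results."""
        table = evaluate_terms(
            self.network,
            self.annotations,
            n_folds=n_folds,
            seed=seed,
            restrict_to_edges=self.restrict_to_edges,
            combined=combined,
        )
        table["is_optimal"] = table["mean_auc"] > auc_threshold
        return FunctionPredictionResults(
            term_table=table,
            mf_profile=multifunctionality_scores(self.annotations),
            n_folds=n_folds,
            seed=seed,
            auc_threshold=auc_threshold,
            n_genes=self.network.n_nodes,
        )

    def predict(self, labels_visible=None) -> pd.DataFrame:
        """Voting scores for every (gene, term) using the given visible labels.

        With no argument all labels are visible (resubstitution scores).
        """
        visible = (
            list(labels_visible)
            if labels_visible is not None
            else list(self.annotations.universe)
        )
        return neighbor_voting_scores(
            self.network,
            self.annotations,
            visible,
            restrict_to_edges=self.restrict_to_edges,
        )
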