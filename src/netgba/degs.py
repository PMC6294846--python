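"""Two-group differential expression with empirical-Bayes variance moderation.

The screen is a gene-wise two-sample linear model on log2 expression:
fold change is the case-minus-control mean difference, and the gene-wise
residual variances s_g^2 are shrunk toward a common prior. The prior is a
scaled inverse chi-square with d0 degrees of freedom and scale s0^2,
estimated by moment matching on log s_g^2 (the digamma/trigamma moment
equations of that model). The moderated statistic is

    t_g = lfc_g / (s~_g * sqrt(1/n1 + 1/n2)),
    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d),

referred to a t distribution on d + d0 degrees of freedom, where
d = n1 + n2 - 2. With moderation disabled (d0 = 0) this is exactly the
textbook pooled-variance two-sample t-test.

Genes are then flagged as differentially expressed when p < p_threshold
AND |lfc| > lfc_threshold, both strict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import DesignError, EstimationError
from .expression import ExpressionMatrix

log = logging.getLogger(__name__)

_COLUMNS = ["gene_id", "log2_fold_change", "t_stat", "p_value", "neg_log10_p", "is_deg"]


def _fit_variance_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Moment-matching estimate of (d0, s0^2) from gene-wise variances.

    Under s_g^2 ~ s0^2 * chi2_{d0}/... (scaled inverse chi-square prior,
    chi-square sampling), z_g = log s_g^2 has
        E[z] = log s0^2 + psi(d/2) - log(d/2) - psi(d0/2) + log(d0/2)
        Var[z] = psi'(d/2) + psi'(d0/2)
    so d0 solves psi'(d0/2) = var(z) - psi'(d/2) and s0^2 follows from the
    mean equation. Returns d0 = inf when the observed spread of log
    variances is no larger than sampling noise alone.
    """
    z = np.log(s2[s2 > 0])
    if z.size < 2:
        # nothing to estimate a spread from; fall back to no moderation
        return 0.0, float(np.exp(z.mean())) if z.size else 0.0
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    evar = float(np.var(e, ddof=1))
    # correction for the finite-sample variance of e itself
    target = evar - float(special.polygamma(1, d / 2.0))
    if target <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(e.mean()))
        return d0, s0_sq
    d0 = 2.0 * _trigamma_inverse(target)
    s0_sq = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_sq


def _trigamma_inverse(x: float) -> float:
    """Solve psi'(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse needs a positive argument")
    y = 0.5 + 1.0 / x  # starting value; psi'(y) ~ 1/y + 1/(2y^2)
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


@dataclass
class DEGResults:
    """Per-gene statistics and the selected DEG set.

    Attributes
    ----------
    table : pandas.DataFrame
        One row per gene, in input order: log2_fold_change, t_stat,
        p_value, neg_log10_p, is_deg (plus q_value when FDR was requested).
    d0, s0_sq : float
        Estimated prior degrees of freedom and prior variance (d0 = 0
        means moderation was disabled).
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float
    p_threshold: float
    lfc_threshold: float
    control_group: str
    case_group: str

    @property
    def degs(self) -> pd.DataFrame:
        """Selected DEGs sorted by ascending p-value."""
        return (
            self.table[self.table["is_deg"]]
            .sort_values(["p_value", "gene_id"], kind="mergesort")
            .reset_index(drop=True)
        )

    @property
    def deg_ids(self) -> list[str]:
        return list(self.degs["gene_id"])

    @property
    def n_degs(self) -> int:
        return int(self.table["is_deg"].sum())

    def summary(self) -> str:
        lines = [
            "Differential expression (moderated two-sample t)",
            "=" * 48,
            f"genes tested        {len(self.table)}",
            f"orientation         {self.case_group} - {self.control_group}",
            f"prior df (d0)       {self.d0:.4g}",
            f"prior variance s0^2 {self.s0_sq:.4g}",
            f"selection           p < {self.p_threshold} and |lfc| > {self.lfc_threshold}",
            f"selected DEGs       {self.n_degs}",
        ]
        top = self.degs.head(10)
        if len(top):
            lines.append("")
            lines.append(top.to_string(index=False))
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


class DifferentialExpression:
    """Two-group differential expression model for a log2 expression matrix.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Genes x samples, two groups of >= 2 samples each.
    moderated : bool
        Shrink gene-wise variances toward the empirical-Bayes prior
        (default). ``False`` gives the ordinary pooled-variance t-test.

    Examples
    --------
    >>> res = DifferentialExpression(matrix).fit()
    >>> res.degs.head()
    """

    def __init__(self, matrix: ExpressionMatrix, moderated: bool = True):
        self.matrix = matrix
        self.moderated = moderated

    def fit(
        self,
        p_threshold: float = 0.02,
        lfc_threshold: float = 2.0,
        fdr: bool = False,
    ) -> DEGResults:
        """Estimate per-gene statistics and flag DEGs.

        ``fdr=True`` adds a Benjamini-Hochberg q_value column and applies
        the p criterion to it instead of the raw p-value; the published
        screen uses raw p, so this is off by default.
        """
        m = self.matrix
        case_cols = m.group_columns(m.case_group)
        ctrl_cols = m.group_columns(m.control_group)
        n1, n2 = len(case_cols), len(ctrl_cols)
        if n1 < 2 or n2 < 2:
            raise DesignError("each group needs at least 2 samples")
        x1 = m.values[case_cols].to_numpy(float)
        x2 = m.values[ctrl_cols].to_numpy(float)

        lfc = x1.mean(axis=1) - x2.mean(axis=1)
        d = n1 + n2 - 2
        ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
            (x2 - x2.mean(axis=1, keepdims=True)) ** 2
        ).sum(axis=1)
        s2 = ss / d
        if not (s2 > 0).any():
            raise EstimationError("zero residual variance in every gene")

        if self.moderated:
            d0, s0_sq = _fit_variance_prior(s2, d)
            if np.isinf(d0):
                s2_tilde = np.full_like(s2, s0_sq)
                df = np.inf
            else:
                s2_tilde = (d0 * s0_sq + d * s2) / (d0 + d)
                df = d + d0
        else:
            d0, s0_sq = 0.0, 0.0
            s2_tilde = s2
            df = d

        se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, lfc / se, np.where(lfc == 0, 0.0, np.inf * np.sign(lfc)))
        if np.isinf(df):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df)
        # zero-variance, zero-effect genes carry no evidence at all
        p = np.where((se == 0) & (lfc == 0), 1.0, p)
        p = np.clip(p, np.finfo(float).tiny, 1.0)

        table = pd.DataFrame(
            {
                "gene_id": m.gene_ids,
                "log2_fold_change": lfc,
                "t_stat": t,
                "p_value": p,
                "neg_log10_p": -np.log10(p),
            }
        )
        p_for_selection = p
        if fdr:
            from statsmodels.stats.multitest import multipletests

            table["q_value"] = multipletests(p, method="fdr_bh")[1]
            p_for_selection = table["q_value"].to_numpy()
        table["is_deg"] = (p_for_selection < p_threshold) & (
            np.abs(lfc) > lfc_threshold
        )
        if not table["is_deg"].any():
            log.warning(
                "no gene passes p < %g and |lfc| > %g", p_threshold, lfc_threshold
            )
        log.info(
            "fold-change orientation: %s minus %s", m.case_group, m.control_group
        )
        return DEGResults(
            table=table,
            d0=float(d0),
            s0_sq=float(s0_sq),
            p_threshold=p_threshold,
            lfc_threshold=lfc_threshold,
            control_group=m.control_group,
            case_group=m.case_group,
        )


# -- functional surface --------------------------------------------------


def moderated_t_test(matrix: ExpressionMatrix, moderated: bool = True) -> pd.DataFrame:
    """Per-gene moderated t statistics without the selection step."""
    res = DifferentialExpression(matrix, moderated=moderated).fit()
    return res.table.drop(columns=["is_deg"])


def select_degs(
    records: pd.DataFrame, p_threshold: float = 0.02, lfc_threshold: float = 2.0
) -> pd.DataFrame:
    """Flag records with p < p_threshold and |lfc| > lfc_threshold (strict).

    Returns the selected rows sorted by ascending p-value.
    """
    out = records.copy()
    out["is_deg"] = (out["p_value"] < p_threshold) & (
        out["log2_fold_change"].abs() > lfc_threshold
    )
    if not out["is_deg"].any():
        log.warning("select_degs: empty selection")
    return (
        out[out["is_deg"]]
        .sort_values(["p_value", "gene_id"], kind="mergesort")
        .reset_index(drop=True)
    )
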