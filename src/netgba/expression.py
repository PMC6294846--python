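"""Gene x sample expression container and its on-disk text formats.

The pipeline's entry point is a log2-scale expression matrix over two
sample groups (case and control). On disk it is a plain TSV (first column
gene id, header row sample ids) plus a two-line design file, one line per
group::

    control<TAB>C1<TAB>C2<TAB>...
    case<TAB>P1<TAB>P2<TAB>...

The first line names the reference (control) group: fold changes are
reported as case minus control.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DesignError


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log2-scale expression values with a two-group sample design.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes in rows (index = gene ids), samples in columns.
    groups : pandas.Series
        Group label per sample, indexed by sample id, exactly two levels.
    control_group : str
        The label treated as the reference when computing fold changes.
    """

    values: pd.DataFrame
    groups: pd.Series
    control_group: str

    def __post_init__(self) -> None:
        if list(self.groups.index) != list(self.values.columns):
            raise DesignError("design samples do not match matrix columns")
        levels = self.groups.unique()
        if len(levels) != 2:
            raise DesignError(
                f"exactly two groups required, got {sorted(map(str, levels))}"
            )
        if self.control_group not in levels:
            raise DesignError(f"control group {self.control_group!r} not in design")
        counts = self.groups.value_counts()
        if (counts < 2).any():
            raise DesignError("each group needs at least 2 samples")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise DesignError("duplicate gene or sample ids")
        if not np.isfinite(self.values.to_numpy()).all():
            raise DesignError("expression values must be finite")

    # -- convenience ----------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def case_group(self) -> str:
        return next(g for g in self.groups.unique() if g != self.control_group)

    def group_columns(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset(self, gene_ids) -> "ExpressionMatrix":
        missing = set(gene_ids) - set(self.values.index)
        if missing:
            raise KeyError(f"genes not in matrix: {sorted(missing)[:5]}")
        return ExpressionMatrix(
            self.values.loc[list(gene_ids)], self.groups, self.control_group
        )

    # -- IO -------------------------------------------------------------

    def to_tsv(self, matrix_path, design_path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(matrix_path, sep="\t")
        case = self.case_group
        with open(design_path, "w") as fh:
            fh.write("\t".join([self.control_group, *self.group_columns(self.control_group)]) + "\n")
            fh.write("\t".join([case, *self.group_columns(case)]) + "\n")

    @classmethod
    def from_tsv(cls, matrix_path, design_path) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        lines = [
            ln.rstrip("\n").split("\t")
            for ln in Path(design_path).read_text().splitlines()
            if ln.strip()
        ]
        if len(lines) != 2:
            raise DesignError(f"design file must have 2 lines, found {len(lines)}")
        labels = {}
        for row in lines:
            group, *samples = row
            if not samples:
                raise DesignError(f"group {group!r} lists no samples")
            for s in samples:
                labels[s] = group
        missing = [s for s in values.columns if s not in labels]
        if missing:
            raise DesignError(f"samples missing from design: {missing}")
        groups = pd.Series([labels[s] for s in values.columns], index=values.columns)
        return cls(values=values, groups=groups, control_group=lines[0][0])
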