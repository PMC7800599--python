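"""Relative expression from qPCR Ct tables and response classification.

Quantification follows the standard delta-delta-Ct model: within each
(condition, replicate) the target Ct is normalized to a reference gene
(dCt = Ct_target - Ct_reference), conditions are differenced
(ddCt = mean dCt_knockdown - mean dCt_control), and the fold change is
efficiency**(-ddCt) with a configurable amplification efficiency (default
2.0, perfect doubling).  Responses are classified at a fractional threshold
(default 20%): down iff fold <= 1 - t, up iff fold >= 1 + t, both bounds
inclusive.  The SEM is computed over per-replicate fold-change estimates so
error bars live on the fold-change axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

KNOCKDOWN = "knockdown"
CONTROL = "control"


@dataclass
class CtTable:
    """Long-format Ct measurements with a designated reference gene.

    ``data`` columns: condition (knockdown/control), replicate, gene, ct.
    """

    data: pd.DataFrame
    reference_gene: str

    def __post_init__(self) -> None:
        required = {"condition", "replicate", "gene", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"CtTable missing columns {sorted(missing)}")
        bad = set(self.data["condition"]) - {KNOCKDOWN, CONTROL}
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        for cond, grp in self.data.groupby("condition"):
            for rep, sub in grp.groupby("replicate"):
                if self.reference_gene not in set(sub["gene"]):
                    raise ValueError(
                        f"reference gene {self.reference_gene!r} missing from "
                        f"{cond} replicate {rep}")

    @property
    def genes(self) -> list[str]:
        return [g for g in self.data["gene"].unique()
                if g != self.reference_gene]

    @classmethod
    def read_tsv(cls, path_or_stream, reference_gene: str) -> "CtTable":
        df = pd.read_csv(path_or_stream, sep="\t", comment="#")
        return cls(df, reference_gene)

    def write_tsv(self, stream) -> None:
        stream.write(f"# reference_gene={self.reference_gene}\n")
        self.data.to_csv(stream, sep="\t", index=False)


@dataclass
class ExpressionChange:
    gene: str
    fold_change: float
    sem: float
    classification: str
    n_replicates: tuple[int, int]  # (knockdown, control)
    paired: bool


def _delta_ct(ct: CtTable, gene: str, condition: str) -> pd.Series:
    sub = ct.data[ct.data["condition"] == condition]
    target = sub[sub["gene"] == gene].set_index("replicate")["ct"]
    ref = sub[sub["gene"] == ct.reference_gene].set_index("replicate")["ct"]
    if target.empty:
        raise ValueError(f"gene {gene!r} absent from condition {condition!r}")
    return (target - ref.reindex(target.index)).dropna()


def relative_expression(ct: CtTable, gene: str,
                        efficiency: float = 2.0,
                        threshold: float = 0.20) -> ExpressionChange:
    """Knockdown-vs-control fold change of one gene, reference-normalized.

    Replicates are paired by replicate id when the two conditions share ids;
    otherwise per-replicate knockdown estimates are taken against the mean
    control dCt.
    """
    if gene == ct.reference_gene:
        raise ValueError("reference gene cannot be its own target; "
                         "its fold change is 1 by construction")
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    d_kd = _delta_ct(ct, gene, KNOCKDOWN)
    d_ct = _delta_ct(ct, gene, CONTROL)
    ddct = d_kd.mean() - d_ct.mean()
    fold = float(efficiency ** (-ddct))

    paired = set(d_kd.index) == set(d_ct.index)
    if paired:
        per_rep = efficiency ** (-(d_kd - d_ct.reindex(d_kd.index)))
    else:
        per_rep = efficiency ** (-(d_kd - d_ct.mean()))
    sem = float(per_rep.std(ddof=1) / np.sqrt(len(per_rep))) \
        if len(per_rep) > 1 else float("nan")
    return ExpressionChange(gene, fold, sem,
                            classify_fold(fold, threshold),
                            (len(d_kd), len(d_ct)), paired)


def classify_fold(fold_change: float, threshold: float = 0.20) -> str:
    """down iff fold <= 1 - t; up iff fold >= 1 + t; else unchanged."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if fold_change <= 1 - threshold:
        return "down"
    if fold_change >= 1 + threshold:
        return "up"
    return "unchanged"


def classify_response(change: ExpressionChange,
                      threshold: float = 0.20) -> str:
    return classify_fold(change.fold_change, threshold)


@dataclass
class KnockdownEfficiency:
    gene: str
    fold_decrease: float
    effective: bool  # fold decrease >= 5, the usual adequacy bar


def knockdown_efficiency(ct: CtTable, target_gene: str,
                         efficiency: float = 2.0,
                         min_fold: float = 5.0) -> KnockdownEfficiency:
    """Fold decrease of the knocked-down target's own mRNA."""
    change = relative_expression(ct, target_gene, efficiency)
    fold_decrease = 1.0 / change.fold_change
    # inclusive boundary, robust to float round-off in the Ct arithmetic
    effective = fold_decrease >= min_fold * (1.0 - 1e-9)
    return KnockdownEfficiency(target_gene, float(fold_decrease), effective)


def expression_table(ct: CtTable, efficiency: float = 2.0,
                     threshold: float = 0.20,
                     genes: list[str] | None = None) -> pd.DataFrame:
    """Fold change, SEM and class for a panel of genes."""
    rows = []
    for gene in (genes if genes is not None else ct.genes):
        ch = relative_expression(ct, gene, efficiency, threshold)
        rows.append({"gene": gene, "fold_change": ch.fold_change,
                     "sem": ch.sem, "class": ch.classification,
                     "n_knockdown": ch.n_replicates[0],
                     "n_control": ch.n_replicates[1]})
    return pd.DataFrame(rows)
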