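"""Relative gene expression from triplicate Ct values (comparative ΔΔCt).

Each well's cycle threshold Ct is recorded; replicate wells of a sample are
averaged.  Expression of a target gene is normalized to a reference gene
(beta-actin here) within each sample,

    ΔCt = mean Ct(target) - mean Ct(reference),

and reported relative to the untreated control condition,

    relative expression = 2^-(sample ΔCt - control ΔCt),

where the control ΔCt of a gene is the mean ΔCt over control-condition
samples.  No outlier rejection and no amplification-efficiency correction
are applied; replicate standard deviations are carried along for QC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("tjquant")

__all__ = [
    "CtTable",
    "ExpressionResult",
    "read_ct_table",
    "delta_ct",
    "relative_expression",
    "expression_report",
    "REFERENCE_GENE",
]

REFERENCE_GENE = "Actin"

CT_COLUMNS = ["sample_id", "condition", "gene", "replicate", "ct"]


@dataclass
class CtTable:
    """Long-format qPCR records: one row per well.

    ``records`` has columns sample_id, condition, gene, replicate, ct.
    Every sample must include the reference gene; Ct values must be finite
    and positive.
    """

    records: pd.DataFrame
    reference_gene: str = REFERENCE_GENE

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in CT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"Ct table is missing columns: {missing}")
        ct = df["ct"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ct)) or np.any(ct <= 0):
            raise ValueError("Ct values must be finite and positive")
        for sample_id, group in df.groupby("sample_id"):
            if self.reference_gene not in set(group["gene"]):
                raise ValueError(
                    f"sample {sample_id!r} lacks reference gene "
                    f"{self.reference_gene!r}"
                )

    @property
    def genes(self) -> list[str]:
        """Genes in first-appearance order, reference gene included."""
        return list(dict.fromkeys(self.records["gene"]))

    def ct_stats(self, sample_id, gene) -> tuple[float, float]:
        """Replicate mean and standard deviation of Ct for one sample/gene."""
        sel = self.records[
            (self.records["sample_id"] == sample_id)
            & (self.records["gene"] == gene)
        ]["ct"].to_numpy(dtype=float)
        if sel.size == 0:
            raise ValueError(f"sample {sample_id!r} has no Ct for gene {gene!r}")
        return float(sel.mean()), float(sel.std(ddof=1)) if sel.size > 1 else 0.0


@dataclass
class ExpressionResult:
    """Fold change of one gene in one sample relative to the control."""

    gene: str
    sample_id: str
    condition: str
    delta_ct: float
    ct_sd: float
    relative_expression: float


def read_ct_table(path, reference_gene: str = REFERENCE_GENE) -> CtTable:
    """Read a Ct CSV with columns sample_id, condition, gene, replicate, ct."""
    return CtTable(records=pd.read_csv(path), reference_gene=reference_gene)


def delta_ct(table: CtTable, sample_id, gene) -> float:
    """Mean Ct of the target minus mean Ct of the reference gene."""
    target_mean, _ = table.ct_stats(sample_id, gene)
    reference_mean, _ = table.ct_stats(sample_id, table.reference_gene)
    return target_mean - reference_mean


def relative_expression(sample_dct: float, control_dct: float) -> float:
    """Comparative fold change: 2^-(sample ΔCt - control ΔCt)."""
    if not (np.isfinite(sample_dct) and np.isfinite(control_dct)):
        raise ValueError("ΔCt values must be finite")
    return float(2.0 ** (-(sample_dct - control_dct)))


def expression_report(
    table: CtTable, control_condition: str = "control"
) -> list[ExpressionResult]:
    """Per gene × sample fold changes versus the control condition.

    The control ΔCt of each gene is the mean of per-sample ΔCts over the
    control condition.  Genes appear in input order; the reference gene's
    own fold change is identically 1 in every sample.
    """
    df = table.records
    conditions = set(df["condition"])
    if control_condition not in conditions:
        raise ValueError(
            f"no rows with control condition {control_condition!r} "
            f"(found {sorted(conditions)})"
        )
    samples = list(dict.fromkeys(df["sample_id"]))
    sample_condition = {
        s: df.loc[df["sample_id"] == s, "condition"].iloc[0] for s in samples
    }
    control_samples = [
        s for s in samples if sample_condition[s] == control_condition
    ]

    results: list[ExpressionResult] = []
    for gene in table.genes:
        gene_samples = [
            s for s in samples
            if not df[(df["sample_id"] == s) & (df["gene"] == gene)].empty
        ]
        control_dcts = [
            delta_ct(table, s, gene)
            for s in control_samples
            if s in gene_samples
        ]
        if not control_dcts:
            raise ValueError(f"gene {gene!r} has no control-condition samples")
        control_dct = float(np.mean(control_dcts))
        for s in gene_samples:
            dct = delta_ct(table, s, gene)
            _, sd = table.ct_stats(s, gene)
            results.append(
                ExpressionResult(
                    gene=gene,
                    sample_id=s,
                    condition=sample_condition[s],
                    delta_ct=dct,
                    ct_sd=sd,
                    relative_expression=relative_expression(dct, control_dct),
                )
            )
    logger.info(
        "expression_report: %d gene(s) x %d sample(s), control=%r",
        len(table.genes), len(samples), control_condition,
    )
    return results


def report_frame(results: list[ExpressionResult]) -> pd.DataFrame:
    """Tabulate :class:`ExpressionResult` records for CSV output."""
    return pd.DataFrame([r.__dict__ for r in results])
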