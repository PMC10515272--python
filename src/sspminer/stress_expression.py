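"""Drought-stress expression analysis and qPCR relative expression.

Differential-expression calls use the published thresholds on a precomputed
FPKM matrix: a gene is up-regulated at a timepoint when
log2(FPKM_treated / FPKM_control) >= 1 and q <= 0.05, down-regulated with
log2 fold change <= -1 at the same q gate.  q-values are consumed as
provided by the upstream RNA-seq processing; :func:`bh_adjust` is offered as
a convenience for synthetic raw p-values only.

qPCR relative expression is the 2^-ddCt method: dCt = Ct_target - Ct_reference
per sample, ddCt = dCt_treated - dCt_control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionRecord",
    "CtRecord",
    "de_call",
    "de_call_values",
    "tally_de",
    "relative_expression",
    "read_expression_matrix",
    "read_ct_table",
    "bh_adjust",
]

DEFAULT_TIMEPOINTS = ("ds-d1", "ds-d2", "ds-d3", "ds-d4", "ds-d5")


@dataclass
class ExpressionRecord:
    """One gene's control FPKM plus per-timepoint treated FPKM and q-value."""

    gene_id: str
    fpkm_control: float
    fpkm_treated: dict[str, float] = field(default_factory=dict)
    qvalue: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.fpkm_control < 0 or any(v < 0 for v in self.fpkm_treated.values()):
            raise ValueError(f"{self.gene_id}: negative FPKM")
        if any(not (0 <= q <= 1) for q in self.qvalue.values()):
            raise ValueError(f"{self.gene_id}: q-value outside [0, 1]")


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement: target and reference-gene (Actin) Ct values."""

    sample_id: str
    condition: str
    target_ct: float
    reference_ct: float

    def __post_init__(self):
        for v in (self.target_ct, self.reference_ct):
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{self.sample_id}: Ct must be positive and finite")

    @property
    def delta_ct(self) -> float:
        return self.target_ct - self.reference_ct


def de_call_values(
    fpkm_control: float,
    fpkm_treated: float,
    q: float,
    lfc_threshold: float = 1.0,
    q_threshold: float = 0.05,
    pseudocount: float = 0.0,
) -> str:
    """'up' / 'down' / 'ns' for one (control, treated, q) triple.

    With pseudocount 0 a zero FPKM on either side is an explicit error
    (undefined fold change), never a silent infinity.
    """
    c = fpkm_control + pseudocount
    t = fpkm_treated + pseudocount
    if c <= 0 or t <= 0:
        raise ValueError(
            "fold change undefined for zero FPKM with pseudocount 0; "
            "set a pseudocount to proceed"
        )
    lfc = math.log2(t / c)
    if q <= q_threshold:
        if lfc >= lfc_threshold:
            return "up"
        if lfc <= -lfc_threshold:
            return "down"
    return "ns"


def de_call(
    record: ExpressionRecord,
    timepoint: str,
    lfc_threshold: float = 1.0,
    q_threshold: float = 0.05,
    pseudocount: float = 0.0,
) -> str:
    return de_call_values(
        record.fpkm_control,
        record.fpkm_treated[timepoint],
        record.qvalue[timepoint],
        lfc_threshold,
        q_threshold,
        pseudocount,
    )


def tally_de(
    records: Sequence[ExpressionRecord],
    timepoints: Sequence[str] = DEFAULT_TIMEPOINTS,
    lfc_threshold: float = 1.0,
    q_threshold: float = 0.05,
    pseudocount: float = 0.0,
) -> dict:
    """Up/down counts per timepoint plus union gene sets across timepoints."""
    per_tp: dict[str, tuple[int, int]] = {}
    union_up: set[str] = set()
    union_down: set[str] = set()
    for tp in timepoints:
        n_up = n_down = 0
        for rec in records:
            call = de_call(rec, tp, lfc_threshold, q_threshold, pseudocount)
            if call == "up":
                n_up += 1
                union_up.add(rec.gene_id)
            elif call == "down":
                n_down += 1
                union_down.add(rec.gene_id)
        per_tp[tp] = (n_up, n_down)
    return {
        "per_timepoint": per_tp,
        "union_up": sorted(union_up),
        "union_down": sorted(union_down),
        "n_union_up": len(union_up),
        "n_union_down": len(union_down),
    }


def relative_expression(ct_treated: CtRecord, ct_control: CtRecord) -> float:
    """2^-ddCt relative expression of treated vs control."""
    ddct = ct_treated.delta_ct - ct_control.delta_ct
    return 2.0 ** (-ddct)


def read_expression_matrix(
    path: str | Path,
    control_col: str = "ck",
    timepoints: Sequence[str] = DEFAULT_TIMEPOINTS,
    q_prefix: str = "q_",
) -> list[ExpressionRecord]:
    """Read a gene x condition TSV (columns: gene_id, ck, ds-d1..., q_ds-d1...)."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        records.append(
            ExpressionRecord(
                gene_id=str(row["gene_id"]),
                fpkm_control=float(row[control_col]),
                fpkm_treated={tp: float(row[tp]) for tp in timepoints},
                qvalue={tp: float(row[q_prefix + tp]) for tp in timepoints},
            )
        )
    return records


def read_ct_table(path: str | Path) -> list[CtRecord]:
    """CSV with columns sample_id, condition, target_ct, reference_ct."""
    df = pd.read_csv(path)
    return [
        CtRecord(
            sample_id=str(r["sample_id"]),
            condition=str(r["condition"]),
            target_ct=float(r["target_ct"]),
            reference_ct=float(r["reference_ct"]),
        )
        for _, r in df.iterrows()
    ]


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (convenience for synthetic data)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]
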