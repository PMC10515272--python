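"""CEP (C-terminally encoded peptide) domain analysis.

CEP precursors carry one or more ~15-aa mature peptides near the C-terminus,
each marked by the conserved SPGxG(H/N) box (e.g. the synthesized 15-mers
YLGIKNSGPSPGEGH and TLGGIKAGPSPGEGH).  This module scans precursors for the
box, reports a fixed-width candidate mature peptide per hit, and summarizes
single- versus multi-domain architecture.

The 15-residue mature window ending at the motif's last residue is an
operational convention (true in-vivo processing boundaries are variable),
exposed as a parameter.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .sequence_io import ProteinRecord

__all__ = ["CEP_MOTIF", "CEPDomainHit", "detect_cep_domains", "summarize_domain_architecture"]

#: The conserved CEP box: S-P-G, any residue, G, then H or N.
CEP_MOTIF = re.compile(r"SPG.G[HN]")

DEFAULT_MATURE_LEN = 15


@dataclass(frozen=True)
class CEPDomainHit:
    """One motif occurrence; coordinates 0-based half-open on the precursor."""

    protein_id: str
    start: int
    end: int
    mature_peptide: str
    motif_text: str
    left_truncated: bool = False  # precursor shorter than the mature window


def detect_cep_domains(
    record: ProteinRecord, mature_len: int = DEFAULT_MATURE_LEN
) -> list[CEPDomainHit]:
    """All non-overlapping SPGxG(H/N) occurrences, left to right.

    Each hit carries the ``mature_len``-residue window ending at the motif's
    last residue as its candidate mature peptide; windows running off the
    precursor's N-terminus are flagged ``left_truncated``.
    """
    hits = []
    for m in CEP_MOTIF.finditer(record.sequence):
        w0 = m.end() - mature_len
        hits.append(
            CEPDomainHit(
                protein_id=record.protein_id,
                start=m.start(),
                end=m.end(),
                mature_peptide=record.sequence[max(0, w0) : m.end()],
                motif_text=m.group(0),
                left_truncated=w0 < 0,
            )
        )
    return hits


def summarize_domain_architecture(
    assignments: Iterable[tuple[str, Sequence[CEPDomainHit]]],
) -> pd.DataFrame:
    """Table of (protein_id, n_domains, single_or_multi).

    Proteins with zero hits are excluded with a warning — they carry no CEP
    domain and do not belong in the architecture summary.
    """
    rows = []
    for pid, hits in assignments:
        if not hits:
            warnings.warn(f"{pid}: no CEP domain found; excluded from summary")
            continue
        n = len(hits)
        rows.append((pid, n, "single" if n == 1 else "multi"))
    return pd.DataFrame(rows, columns=["protein_id", "n_domains", "single_or_multi"])
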