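"""The four-stage small-secreted-peptide (SSP) identification cascade.

An SSP precursor is a small protein (25–250 aa) carrying an N-terminal
signal peptide, no transmembrane helix in its mature region, and no
C-terminal ER-retention signal (K/HDEL).  The cascade applies those four
gates in order — length → signal peptide → transmembrane → ER retention —
and tallies survivors after each stage.

Signal-peptide and transmembrane calls come from a pluggable predictor:
either precomputed SignalP-5.0 / TMHMM v2.0 short-format files, or the
built-in deterministic hydropathy heuristics (so the pipeline is testable
without the licensed external tools; the heuristics make no claim of
reproducing SignalP/TMHMM outputs).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence
import warnings

from .sequence_io import ProteinRecord

__all__ = [
    "PredictorVerdict",
    "SSPCandidate",
    "CascadeTally",
    "PredictorConfig",
    "KYTE_DOOLITTLE",
    "filter_length",
    "load_signalp_short",
    "load_tmhmm_short",
    "heuristic_signal_peptide",
    "heuristic_tm_count",
    "filter_signal_peptide",
    "filter_transmembrane",
    "filter_er_retention",
    "run_cascade",
]

#: Kyte–Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

# Heuristic signal-peptide parameters (deterministic stand-in predictor).
SP_SEARCH_LIMIT = 45          # signal peptides live in the first ~45 residues
SP_CORE_WINDOW = 8            # hydrophobic h-region window length
SP_CORE_MIN_KD = 1.6          # mean Kyte-Doolittle threshold for the core
SP_CLEAVAGE_OFFSETS = range(7, 2, -1)   # cleavage 3-7 residues after core, farthest first
SMALL_RESIDUES = frozenset("AGSCT")     # allowed at the -3/-1 cleavage positions

# Heuristic TM parameters.
TM_WINDOW = 19
TM_MIN_KD = 1.8


@dataclass
class PredictorVerdict:
    """Per-protein signal-peptide / transmembrane predictor output.

    ``sp_cleavage_site`` is the 1-based position of the last signal-peptide
    residue (0 when there is none).  Fields left ``None`` are unknown (e.g. a
    SignalP file carries no TM information); :func:`merge_verdicts` combines
    partial verdicts.
    """

    protein_id: str
    has_signal_peptide: bool | None = None
    sp_cleavage_site: int = 0
    tm_helix_count: int | None = None

    def __post_init__(self):
        if self.has_signal_peptide is not None:
            if bool(self.sp_cleavage_site > 0) != bool(self.has_signal_peptide):
                raise ValueError(
                    f"{self.protein_id}: cleavage site {self.sp_cleavage_site} "
                    f"inconsistent with has_signal_peptide={self.has_signal_peptide}"
                )


def merge_verdicts(
    sp: dict[str, PredictorVerdict] | None,
    tm: dict[str, PredictorVerdict] | None,
) -> dict[str, PredictorVerdict]:
    """Combine SP-only and TM-only verdict maps into full verdicts."""
    out: dict[str, PredictorVerdict] = {}
    for d in (sp or {}), (tm or {}):
        for pid, v in d.items():
            cur = out.setdefault(pid, PredictorVerdict(pid))
            if v.has_signal_peptide is not None:
                cur.has_signal_peptide = v.has_signal_peptide
                cur.sp_cleavage_site = v.sp_cleavage_site
            if v.tm_helix_count is not None:
                cur.tm_helix_count = v.tm_helix_count
    return out


@dataclass
class SSPCandidate:
    """A protein with per-gate verdicts from the cascade."""

    record: ProteinRecord
    passed_length: bool = False
    passed_sp: bool = False
    passed_tm: bool = False
    passed_er: bool = False
    sp_cleavage_site: int = 0
    mature_sequence: str = ""

    @property
    def is_ssp(self) -> bool:
        return (
            self.passed_length and self.passed_sp
            and self.passed_tm and self.passed_er
        )

    @property
    def protein_id(self) -> str:
        return self.record.protein_id


@dataclass
class CascadeTally:
    """Survivor counts after each sequential gate (Table-2-shaped)."""

    n_input: int = 0
    after_length: int = 0
    after_sp: int = 0
    after_tm: int = 0
    after_er: int = 0

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (
            self.n_input, self.after_length, self.after_sp,
            self.after_tm, self.after_er,
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "input": self.n_input,
            "25-250 aa": self.after_length,
            "N-terminal SP": self.after_sp,
            "Non-TM": self.after_tm,
            "Putative SSP": self.after_er,
        }


@dataclass
class PredictorConfig:
    """How SP/TM verdicts are obtained for the cascade.

    Either point at precomputed SignalP-5.0 / TMHMM v2.0 short-format files,
    or set ``heuristic=True`` to use the built-in hydropathy rules.
    """

    heuristic: bool = False
    signalp_path: str | Path | None = None
    tmhmm_path: str | Path | None = None

    def __post_init__(self):
        if not self.heuristic and self.signalp_path is None:
            raise ValueError(
                "predictor config needs --heuristic or SignalP/TMHMM files"
            )

    def verdicts(self, records: Sequence[ProteinRecord]) -> dict[str, PredictorVerdict]:
        if self.heuristic:
            out = {}
            for rec in records:
                v = heuristic_signal_peptide(rec)
                mature = (
                    rec.sequence[v.sp_cleavage_site:] if v.has_signal_peptide else rec.sequence
                )
                v.tm_helix_count = heuristic_tm_count(mature)
                out[rec.protein_id] = v
            return out
        sp = load_signalp_short(self.signalp_path)
        tm = load_tmhmm_short(self.tmhmm_path) if self.tmhmm_path else {}
        return merge_verdicts(sp, tm)


# --------------------------------------------------------------------------
# Gates
# --------------------------------------------------------------------------

def filter_length(
    records: Iterable[ProteinRecord], min_len: int = 25, max_len: int = 250
) -> list[ProteinRecord]:
    """Keep proteins with min_len <= length <= max_len (both inclusive)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [r for r in records if min_len <= len(r) <= max_len]


_CS_POS_RX = re.compile(r"CS pos:\s*(\d+)-(\d+)")


def load_signalp_short(path: str | Path) -> dict[str, PredictorVerdict]:
    """Parse SignalP-5.0 short tabular output.

    Columns: ID, Prediction, SP(Sec/SPI) prob, OTHER prob, CS position.  A
    protein is signal-peptide positive iff Prediction == "SP(Sec/SPI)"; the
    cleavage site is the X of "CS pos: X-Y".
    """
    out: dict[str, PredictorVerdict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                parts = line.split()
            pid, prediction = parts[0], parts[1]
            if prediction == "SP(Sec/SPI)":
                m = _CS_POS_RX.search(line)
                if not m:
                    raise ValueError(f"SignalP line for {pid!r} lacks 'CS pos: X-Y'")
                out[pid] = PredictorVerdict(
                    pid, has_signal_peptide=True, sp_cleavage_site=int(m.group(1))
                )
            else:
                if prediction != "OTHER":
                    warnings.warn(
                        f"SignalP: unknown prediction label {prediction!r} for "
                        f"{pid!r}; treated as no signal peptide"
                    )
                out[pid] = PredictorVerdict(pid, has_signal_peptide=False)
    return out


_PREDHEL_RX = re.compile(r"PredHel=(\d+)")


def load_tmhmm_short(path: str | Path) -> dict[str, PredictorVerdict]:
    """Parse TMHMM v2.0 short output; reads the PredHel=N field."""
    out: dict[str, PredictorVerdict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pid = line.split()[0]
            m = _PREDHEL_RX.search(line)
            if not m:
                raise ValueError(f"TMHMM line for {pid!r} lacks 'PredHel=N'")
            out[pid] = PredictorVerdict(pid, tm_helix_count=int(m.group(1)))
    return out


def _mean_kd(window: str) -> float:
    return sum(KYTE_DOOLITTLE.get(a, 0.0) for a in window) / len(window)


def heuristic_signal_peptide(record: ProteinRecord) -> PredictorVerdict:
    """Deterministic built-in signal-peptide rule.

    Declares a signal peptide iff, within the first 45 residues, there is an
    8-residue hydrophobic core (mean Kyte–Doolittle >= 1.6) preceded by at
    least one K/R, with a cleavage site 3–7 residues after the core whose
    −3/−1 positions are small residues (A/G/S/C/T).  Windows are scanned
    left-to-right and cleavage offsets farthest-first, so the call and the
    reported cleavage site are reproducible.
    """
    seq = record.sequence
    limit = min(len(seq), SP_SEARCH_LIMIT)
    for start in range(1, limit - SP_CORE_WINDOW + 1):  # >=1: room for a K/R before
        window = seq[start : start + SP_CORE_WINDOW]
        if _mean_kd(window) < SP_CORE_MIN_KD:
            continue
        if not any(a in "KR" for a in seq[:start]):
            continue
        core_end = start + SP_CORE_WINDOW  # 1-based position of last core residue
        for off in SP_CLEAVAGE_OFFSETS:
            cs = core_end + off  # 1-based last SP residue
            if cs > len(seq):
                continue
            # -1 is the residue at cs, -3 two before it (A-X-A rule)
            if seq[cs - 1] in SMALL_RESIDUES and seq[cs - 3] in SMALL_RESIDUES:
                return PredictorVerdict(
                    record.protein_id, has_signal_peptide=True, sp_cleavage_site=cs
                )
    return PredictorVerdict(record.protein_id, has_signal_peptide=False)


def heuristic_tm_count(mature_sequence: str) -> int:
    """Count TM-like windows: non-overlapping 19-mers with mean KD >= 1.8,
    greedy left-to-right."""
    n = 0
    i = 0
    while i + TM_WINDOW <= len(mature_sequence):
        if _mean_kd(mature_sequence[i : i + TM_WINDOW]) >= TM_MIN_KD:
            n += 1
            i += TM_WINDOW
        else:
            i += 1
    return n


def _require_verdicts(
    records: Iterable[ProteinRecord], verdicts: dict[str, PredictorVerdict]
) -> None:
    missing = [r.protein_id for r in records if r.protein_id not in verdicts]
    if missing:
        raise KeyError(
            "no predictor verdict for: " + ", ".join(sorted(missing))
        )


def filter_signal_peptide(
    records: Sequence[ProteinRecord], verdicts: dict[str, PredictorVerdict]
) -> list[SSPCandidate]:
    """Keep signal-peptide-positive proteins; set their mature sequences."""
    _require_verdicts(records, verdicts)
    out = []
    for rec in records:
        v = verdicts[rec.protein_id]
        if v.has_signal_peptide:
            cs = v.sp_cleavage_site
            if cs >= len(rec):
                warnings.warn(
                    f"{rec.protein_id}: cleavage site {cs} leaves no mature "
                    "sequence; dropped"
                )
                continue
            out.append(
                SSPCandidate(
                    record=rec,
                    passed_length=True,
                    passed_sp=True,
                    sp_cleavage_site=cs,
                    mature_sequence=rec.sequence[cs:],
                )
            )
    return out


def filter_transmembrane(
    candidates: Sequence[SSPCandidate],
    verdicts: dict[str, PredictorVerdict],
    heuristic_fallback: bool = False,
) -> list[SSPCandidate]:
    """Remove candidates with >= 1 predicted TM helix.

    With ``heuristic_fallback`` the built-in window count runs on the mature
    sequence of any candidate whose verdict lacks a TM count.
    """
    out = []
    missing = []
    for cand in candidates:
        v = verdicts.get(cand.protein_id)
        tm = v.tm_helix_count if v else None
        if tm is None:
            if heuristic_fallback:
                tm = heuristic_tm_count(cand.mature_sequence)
            else:
                missing.append(cand.protein_id)
                continue
        if tm == 0:
            cand.passed_tm = True
            out.append(cand)
    if missing:
        raise KeyError("no TM verdict for: " + ", ".join(sorted(missing)))
    return out


def filter_er_retention(candidates: Sequence[SSPCandidate]) -> list[SSPCandidate]:
    """Remove ER-retained proteins: full sequence ending in K/HDEL."""
    out = []
    for cand in candidates:
        if cand.record.sequence[-4:].upper() in {"KDEL", "HDEL"}:
            continue
        cand.passed_er = True
        out.append(cand)
    return out


def run_cascade(
    records: Sequence[ProteinRecord],
    predictor: PredictorConfig,
    min_len: int = 25,
    max_len: int = 250,
    skip_length_gate: bool = False,
) -> tuple[list[SSPCandidate], CascadeTally]:
    """Apply the four gates in order and tally survivors after each.

    Returns the final SSP candidates (all gates true) and the tally.  The
    length gate can be marked pre-satisfied (used by the sORF miner, whose
    ORF enumeration already enforces the size range).
    """
    tally = CascadeTally(n_input=len(records))
    kept = list(records) if skip_length_gate else filter_length(records, min_len, max_len)
    tally.after_length = len(kept)

    verdicts = predictor.verdicts(kept)
    cands = filter_signal_peptide(kept, verdicts)
    tally.after_sp = len(cands)

    cands = filter_transmembrane(cands, verdicts, heuristic_fallback=predictor.heuristic)
    tally.after_tm = len(cands)

    cands = filter_er_retention(cands)
    tally.after_er = len(cands)
    return cands, tally
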