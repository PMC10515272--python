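"""Unannotated small-ORF mining from non-coding genomic sequence.

Pipeline: take the genome minus its annotated CDS intervals (the non-coding
sequence, NCDS), six-frame translate each remaining segment, enumerate every
ATG→stop open reading frame encoding a 25–250 aa peptide, drop nested
in-frame ORFs sharing a stop codon (keeping the most upstream start), and
push the surviving peptides through the secreted-peptide filter cascade.

Conventions: internal intervals are 0-based half-open on the forward strand;
an ORF interval covers the start codon through the stop codon inclusive
(the peptide excludes the stop).  Single-exon ORFs only — spliced peptides
are out of scope.  Codons containing N are treated as unreadable and abort
the ORF under construction rather than translating to X.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import reverse_complement

from .sequence_io import GenomeAnnotation, ProteinRecord
from .ssp_filter import CascadeTally, PredictorConfig, SSPCandidate, run_cascade

__all__ = [
    "NonCodingSegment",
    "OpenReadingFrame",
    "extract_ncds",
    "find_sorfs",
    "eliminate_nested_orfs",
    "mine_secreted_sorfs",
]

CODON_TABLE = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)

#: shortest cassette that can hold a min_aa=25 ORF (25 codons + stop)
MIN_SEGMENT_NT = 78


@dataclass(frozen=True)
class NonCodingSegment:
    """A maximal genome interval free of masked (CDS) features."""

    chromosome: str
    start: int  # 0-based half-open, forward strand
    end: int
    sequence: str

    def __post_init__(self):
        if self.end - self.start != len(self.sequence) or self.end <= self.start:
            raise ValueError("segment bounds inconsistent with sequence length")


@dataclass(frozen=True)
class OpenReadingFrame:
    """One ATG→stop ORF; interval spans start codon through stop codon."""

    chromosome: str
    start: int   # 0-based half-open genomic, forward-strand coordinates
    end: int
    strand: str  # '+' or '-'
    frame: int   # 0-2 within the scanned segment (on its coding strand)
    peptide: str
    has_stop: bool = True

    def __post_init__(self):
        if self.has_stop and (self.end - self.start) != 3 * len(self.peptide) + 3:
            raise ValueError("ORF span inconsistent with peptide length")
        if not self.peptide.startswith("M"):
            raise ValueError("ORF peptide must start with M")

    @property
    def stop_key(self) -> tuple:
        """Identity of the stop codon: ORFs sharing it are nested in-frame."""
        stop_pos = self.end if self.strand == "+" else self.start
        return (self.chromosome, self.strand, self.frame, stop_pos)

    @property
    def orf_id(self) -> str:
        return f"ORF_{self.chromosome}_{self.start}_{self.end}_{self.strand}"


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivals:
        return []
    ivals = sorted(ivals)
    merged = [list(ivals[0])]
    for s, e in ivals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


def extract_ncds(
    annotation: GenomeAnnotation,
    mask_feature_types: set[str] = frozenset({"CDS"}),
    min_segment_nt: int = 1,
) -> list[NonCodingSegment]:
    """Complement of the masked feature union, per chromosome.

    The mask ignores strand (a CDS on either strand excludes the interval).
    GFF3 1-based inclusive coordinates are converted to 0-based half-open
    here, at the boundary.  ``min_segment_nt`` can drop segments too short to
    hold any ORF (e.g. 78 nt for a 25-aa minimum).
    """
    annotation.validate()
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in annotation.sequences}
    for chrom, start, end, _strand, ftype, _attrs in annotation.features:
        if ftype in mask_feature_types:
            by_chrom[chrom].append((start - 1, end))  # to 0-based half-open
    segments = []
    for chrom in annotation.sequences:
        seq = annotation.sequences[chrom]
        pos = 0
        for s, e in _merge_intervals(by_chrom[chrom]) + [(len(seq), len(seq))]:
            if s - pos >= min_segment_nt:
                segments.append(
                    NonCodingSegment(chrom, pos, s, seq[pos:s])
                )
            pos = max(pos, e)
    return segments


def _scan_frame(dna: str, frame: int) -> Iterable[tuple[int, int, str]]:
    """Yield (start_codon_index, stop_codon_index, peptide) in codon units.

    Translates the frame once ('*' = stop, '!' = N-containing codon); every
    ATG since the last stop/unreadable codon opens an ORF ending at the next
    stop.  Indices are codon offsets within the frame.
    """
    n_codons = (len(dna) - frame) // 3
    trans = []
    starts_at = []  # codon indices of ATGs
    for ci in range(n_codons):
        codon = dna[frame + 3 * ci : frame + 3 * ci + 3]
        if "N" in codon:
            trans.append("!")
        elif codon in STOP_CODONS:
            trans.append("*")
        else:
            trans.append(CODON_TABLE[codon])
    open_starts: list[int] = []
    for ci, aa in enumerate(trans):
        if aa == "!":
            open_starts.clear()
            continue
        if aa == "*":
            for st in open_starts:
                yield st, ci, "".join(trans[st:ci])
            open_starts.clear()
            continue
        if aa == "M":
            open_starts.append(ci)
    # ORFs still open at segment end lack a stop codon and are dropped
    # (require_stop semantics handled by the caller).


def find_sorfs(
    segment: NonCodingSegment,
    min_aa: int = 25,
    max_aa: int = 250,
    require_stop: bool = True,
) -> list[OpenReadingFrame]:
    """Every ATG→stop ORF with peptide length in [min_aa, max_aa], 6 frames.

    ``require_stop=False`` is not supported: ORF-finder semantics demand an
    in-frame stop, and segment-truncated ORFs are discarded.
    """
    if not require_stop:
        raise NotImplementedError("segment-truncated ORFs are not enumerated")
    out = []
    seq = segment.sequence.upper()
    rc = reverse_complement(seq)
    L = len(seq)
    for strand, dna in (("+", seq), ("-", rc)):
        for frame in range(3):
            for st, sp, pep in _scan_frame(dna, frame):
                if not (min_aa <= len(pep) <= max_aa):
                    continue
                a = frame + 3 * st           # ORF start on scanned strand
                b = frame + 3 * sp + 3       # past the stop codon
                if strand == "+":
                    g0, g1 = segment.start + a, segment.start + b
                else:
                    g0, g1 = segment.start + (L - b), segment.start + (L - a)
                out.append(
                    OpenReadingFrame(
                        chromosome=segment.chromosome,
                        start=g0,
                        end=g1,
                        strand=strand,
                        frame=frame,
                        peptide=pep,
                    )
                )
    return out


def eliminate_nested_orfs(
    orfs: Sequence[OpenReadingFrame],
) -> list[OpenReadingFrame]:
    """Keep one ORF per (chromosome, strand, frame, stop position): the
    longest, i.e. the most upstream ATG.  ORFs with distinct stops all stay."""
    best: dict[tuple, OpenReadingFrame] = {}
    order: list[tuple] = []
    for orf in orfs:
        key = orf.stop_key
        cur = best.get(key)
        if cur is None:
            best[key] = orf
            order.append(key)
        elif len(orf.peptide) > len(cur.peptide):
            best[key] = orf
    return [best[k] for k in order]


def orfs_to_records(orfs: Sequence[OpenReadingFrame]) -> list[ProteinRecord]:
    """Wrap ORF peptides as protein records (id encodes the locus)."""
    return [
        ProteinRecord(
            protein_id=orf.orf_id,
            sequence=orf.peptide,
            gene_id=orf.orf_id,
            description=f"frame={orf.frame} len={len(orf.peptide)}aa",
        )
        for orf in orfs
    ]


def mine_secreted_sorfs(
    annotation: GenomeAnnotation,
    predictor: PredictorConfig,
    min_aa: int = 25,
    max_aa: int = 250,
    mask_feature_types: set[str] = frozenset({"CDS"}),
) -> tuple[list[SSPCandidate], dict[str, CascadeTally], list[OpenReadingFrame]]:
    """Full miner: NCDS → six-frame sORFs → nested elimination → cascade.

    Returns the final secreted-sORF candidates, a per-chromosome tally
    (plus a "Total" row) shaped like the sequential-filter table, and the
    post-elimination ORF list.
    """
    segments = extract_ncds(
        annotation, mask_feature_types, min_segment_nt=3 * min_aa + 3
    )
    orfs: list[OpenReadingFrame] = []
    for seg in segments:
        orfs.extend(find_sorfs(seg, min_aa=min_aa, max_aa=max_aa))
    orfs = eliminate_nested_orfs(orfs)

    candidates: list[SSPCandidate] = []
    tallies: dict[str, CascadeTally] = {}
    total = CascadeTally()
    for chrom in annotation.sequences:
        chrom_orfs = [o for o in orfs if o.chromosome == chrom]
        records = orfs_to_records(chrom_orfs)
        cands, tally = run_cascade(
            records, predictor, min_aa, max_aa, skip_length_gate=True
        )
        candidates.extend(cands)
        tallies[chrom] = tally
        total.n_input += tally.n_input
        total.after_length += tally.after_length
        total.after_sp += tally.after_sp
        total.after_tm += tally.after_tm
        total.after_er += tally.after_er
    tallies["Total"] = total
    return candidates, tallies, orfs
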