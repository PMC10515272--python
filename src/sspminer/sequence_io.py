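"""Reading, writing and normalising proteome / genome inputs.

The pipeline consumes a predicted proteome (protein FASTA, possibly with
several transcripts per gene) and, for unannotated-peptide mining, a genome
FASTA plus its GFF3 annotation.  This module owns the record types, the
format I/O and the proteome normalisation steps (longest-transcript
selection, physicochemical properties).

Coordinate convention: GFF3 features are stored 1-based inclusive exactly as
read; all internal interval arithmetic elsewhere in the package is 0-based
half-open, and the conversion happens only in readers/writers.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProteinRecord",
    "GenomeAnnotation",
    "GeneIdRule",
    "read_protein_fasta",
    "write_protein_fasta",
    "select_longest_transcript",
    "compute_protein_properties",
    "ProteinProperties",
    "read_genome_fasta",
    "read_gff3",
    "load_genome",
]

#: Default isoform-suffix rule: Solyc-style ids such as ``Solyc02g092890.1``
#: (and Phytozome ``.1.1`` doubles) carry the gene id before a trailing
#: ``.<number>`` block.
DEFAULT_GENE_ID_PATTERN = r"\.\d+$"

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYXBZU")

# Average (isotope-weighted) residue masses in Da, i.e. amino-acid mass minus
# one water.  Unknown/ambiguous residues (X/B/Z/U) contribute the arithmetic
# mean residue mass and carry no ionisable group.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524
MEAN_RESIDUE_MASS = sum(AVERAGE_RESIDUE_MASS.values()) / len(AVERAGE_RESIDUE_MASS)

# EMBOSS-style pKa values used for the net-charge/pI bisection.
PKA_NTERM = 8.6
PKA_CTERM = 3.6
PKA_SIDECHAIN_ACIDIC = {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}
PKA_SIDECHAIN_BASIC = {"H": 6.5, "K": 10.8, "R": 12.5}


class GeneIdRule:
    """Configurable protein-id -> gene-id derivation (regex removal)."""

    def __init__(self, pattern: str = DEFAULT_GENE_ID_PATTERN):
        self.pattern = pattern
        self._rx = re.compile(pattern)

    def __call__(self, protein_id: str) -> str:
        return self._rx.sub("", protein_id)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneIdRule({self.pattern!r})"


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its identifiers.

    ``sequence`` is uppercase, non-empty and free of internal stop symbols;
    a trailing ``*`` is stripped by the reader.
    """

    protein_id: str
    sequence: str
    gene_id: str = ""
    description: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        if "*" in self.sequence:
            raise ValueError(f"{self.protein_id}: internal stop symbol in sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.protein_id}: non-amino-acid symbols {sorted(bad)}"
            )
        if not self.gene_id:
            object.__setattr__(self, "gene_id", GeneIdRule()(self.protein_id))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeAnnotation:
    """Genome sequences plus GFF3 features (1-based inclusive, as read)."""

    sequences: dict[str, str]
    #: (chromosome, start, end, strand, type, attributes)
    features: list[tuple[str, int, int, str, str, dict]] = field(default_factory=list)

    def validate(self) -> None:
        for chrom, start, end, strand, ftype, _ in self.features:
            if chrom not in self.sequences:
                raise ValueError(f"feature on unknown chromosome {chrom!r}")
            n = len(self.sequences[chrom])
            if not (1 <= start <= end <= n):
                raise ValueError(
                    f"feature {ftype} {chrom}:{start}-{end} outside [1, {n}]"
                )
            if strand not in {"+", "-"}:
                raise ValueError(f"feature strand {strand!r} not +/-")


def read_protein_fasta(
    path: str | Path,
    gene_id_rule: GeneIdRule | None = None,
) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Sequences are uppercased; one trailing stop symbol ``*`` is stripped with
    a warning.  Malformed entries raise ``ValueError`` naming the record.
    """
    rule = gene_id_rule or GeneIdRule()
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if seq.endswith("*"):
            warnings.warn(f"{entry.id}: trailing stop symbol stripped")
            seq = seq[:-1]
        if entry.id in seen:
            raise ValueError(f"duplicate protein id {entry.id!r}")
        seen.add(entry.id)
        try:
            records.append(
                ProteinRecord(
                    protein_id=entry.id,
                    sequence=seq,
                    gene_id=rule(entry.id),
                    description=entry.description,
                )
            )
        except ValueError as exc:
            raise ValueError(f"malformed FASTA record {entry.id!r}: {exc}") from exc
    if not records:
        warnings.warn(f"{path}: no FASTA records found")
    return records


def write_protein_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqs)


def select_longest_transcript(records: list[ProteinRecord]) -> list[ProteinRecord]:
    """Keep one record per gene: the longest transcript.

    Ties break to the lexicographically smallest protein id, so the result is
    deterministic.  Output order follows first appearance of each gene.
    """
    best: dict[str, ProteinRecord] = {}
    order: list[str] = []
    for rec in records:
        cur = best.get(rec.gene_id)
        if cur is None:
            best[rec.gene_id] = rec
            order.append(rec.gene_id)
        elif (len(rec), _neg_id_key(rec.protein_id)) > (
            len(cur),
            _neg_id_key(cur.protein_id),
        ):
            best[rec.gene_id] = rec
    return [best[g] for g in order]


class _neg_id_key:
    """Inverted string ordering so max() prefers the smallest id on ties."""

    __slots__ = ("s",)

    def __init__(self, s: str):
        self.s = s

    def __lt__(self, other: "_neg_id_key") -> bool:
        return self.s > other.s

    def __gt__(self, other: "_neg_id_key") -> bool:
        return self.s < other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _neg_id_key) and self.s == other.s


class ProteinProperties(NamedTuple):
    length: int
    mw_kda: float
    pi: float


def net_charge(sequence: str, ph: float) -> float:
    """Net charge (elementary charges) at a given pH, Henderson–Hasselbalch."""
    charge = 1.0 / (1.0 + 10 ** (ph - PKA_NTERM))
    charge -= 1.0 / (1.0 + 10 ** (PKA_CTERM - ph))
    for aa, pka in PKA_SIDECHAIN_BASIC.items():
        n = sequence.count(aa)
        if n:
            charge += n / (1.0 + 10 ** (ph - pka))
    for aa, pka in PKA_SIDECHAIN_ACIDIC.items():
        n = sequence.count(aa)
        if n:
            charge -= n / (1.0 + 10 ** (pka - ph))
    return charge


def isoelectric_point(sequence: str, tol: float = 1e-6) -> float:
    """pI by bisection on the net-charge curve (monotone decreasing in pH)."""
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def molecular_weight_kda(sequence: str) -> float:
    """Average molecular weight in kDa (sum of residue masses + one water)."""
    da = WATER_MASS + sum(
        AVERAGE_RESIDUE_MASS.get(aa, MEAN_RESIDUE_MASS) for aa in sequence
    )
    return da / 1000.0


def compute_protein_properties(record: ProteinRecord) -> ProteinProperties:
    """Length (aa), molecular weight (kDa) and isoelectric point."""
    return ProteinProperties(
        length=len(record),
        mw_kda=molecular_weight_kda(record.sequence),
        pi=isoelectric_point(record.sequence),
    )


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Chromosome id -> uppercase DNA string."""
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def read_gff3(path: str | Path) -> list[tuple[str, int, int, str, str, dict]]:
    """Parse GFF3 features via gffutils (in-memory DB), 1-based inclusive."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    feats = []
    for f in db.all_features():
        feats.append(
            (f.seqid, f.start, f.end, f.strand, f.featuretype, dict(f.attributes))
        )
    return feats


def load_genome(fasta_path: str | Path, gff_path: str | Path) -> GenomeAnnotation:
    ann = GenomeAnnotation(
        sequences=read_genome_fasta(fasta_path), features=read_gff3(gff_path)
    )
    ann.validate()
    return ann
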