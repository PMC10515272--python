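"""Synthetic fixtures with known ground truth.

Every pipeline stage is testable without downloads: this module generates

* proteomes with planted SSP-family positives (CEP, CLE, RALF, PNP and the
  two six-cysteine spacing archetypes) and per-gate decoys (no signal
  peptide, transmembrane, K/HDEL-terminal, undersize, oversize);
* genomes (FASTA + GFF3) with planted intergenic sORF cassettes, nested
  start-codon pairs and decoy CDS features;
* drought-expression matrices with planted up/down effects;
* physiology tables with separated treatment groups.

Ground truth must be provable, not probabilistic, so the constructions are
co-designed with the package's built-in heuristics:

* planted signal peptides use one fixed 17-residue template (cleaved after
  position 17 by the hydropathy heuristic) plus an enumerated set of
  detection-preserving point mutations;
* random "body" sequence is drawn from a hydrophilic alphabet that can never
  satisfy the signal-peptide or transmembrane hydropathy rules, never spells
  a shipped family motif, and never ends in K/HDEL;
* genome background and cassette codons are sampled so that the strings ATG
  and CAT occur nowhere except at planted start codons — on either strand,
  every open reading frame in the genome is a planted one.

All generators are pure functions of (config, seed): reruns are
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .sequence_io import ProteinRecord
from .stress_expression import DEFAULT_TIMEPOINTS, ExpressionRecord
from .physiology import PhysiologySample

__all__ = [
    "SP_TEMPLATE",
    "SP_VARIANTS",
    "GeneratorManifest",
    "default_proteome_config",
    "make_proteome",
    "make_genome",
    "make_expression",
    "make_physiology",
    "write_proteome_fasta",
    "write_genome_files",
    "write_expression_tsv",
]

#: Fixed signal-peptide template; the built-in heuristic reports cleavage
#: after position 17 (A|mature): hydrophobic core LFLVLLLA, K at position 2,
#: A-x-A small residues at the -3/-1 cleavage positions.
SP_TEMPLATE = "MKTNLFLVLLLAGSALA"

#: Detection-preserving single-point mutations of the template (1-based
#: position, replacement).  Each variant is unit-tested to still be detected
#: with cleavage at position 17.
SP_MUTATIONS = [
    (2, "R"),   # K->R keeps the basic n-region residue
    (4, "Q"),   # N->Q, hydrophilic n-region
    (6, "I"),   # F->I, core stays hydrophobic
    (8, "L"),   # V->L
    (14, "T"),  # S->T, c-region
    (16, "V"),  # L->V, between the -3/-1 anchors
]
SP_VARIANTS = [SP_TEMPLATE] + [
    SP_TEMPLATE[: p - 1] + aa + SP_TEMPLATE[p:] for p, aa in SP_MUTATIONS
]

#: Hydrophilic filler alphabet: every residue has negative Kyte-Doolittle
#: hydropathy, none is C/R/S/P/H/M/I, so filler can neither satisfy the
#: SP/TM hydropathy rules nor spell SPGxG[HN], the CLE box, RR or K[VI][VI]D.
FILLER = "DENQKGT"

CEP_DOMAIN = "SPGEGH"
CLE_BOX = "RTVPSGPDPLHH"
PNP_BOX1 = "KVVD"
PNP_BOX2 = "LSGGAFGGIA"

#: Synthetic archetype gap vectors for novel-CRP discovery.  Archetype I
#: varies the last gap widely (the variable position); archetype II varies
#: gap 2 widely and gap 4 within the discovery tolerance.
CRP6C_I_FIXED = (3, 5, 5, 2)
CRP6C_I_VARIABLE_CHOICES = (6, 8, 10, 12)
CRP6C_II_GAPS = ((5,), (8, 10, 12, 14), (6,), (5, 6), (1,))


@dataclass
class GeneratorManifest:
    """Ground-truth record of everything a generator planted."""

    seed: int
    config: dict
    records: list = dc_field(default_factory=list)

    def ids_in_category(self, *categories: str) -> list[str]:
        return [r["id"] for r in self.records if r["category"] in categories]

    @property
    def true_ssp_ids(self) -> list[str]:
        return [r["id"] for r in self.records if r.get("is_ssp", False)]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=str))


def _filler(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(FILLER), size=n))


def default_proteome_config() -> dict:
    """The stated-world proteome: 40 planted SSPs across the five family
    templates plus per-gate decoys (15 oversize, 20 no-SP, 10 TM, 5 K/HDEL)."""
    return {
        "cep": 8,
        "cle": 8,
        "ralf": 8,
        "pnp": 8,
        "crp6c_i": 4,
        "crp6c_ii": 4,
        "decoy_nosp": 20,
        "decoy_tm": 10,
        "decoy_er": 5,
        "decoy_long": 15,
        "decoy_short": 0,
    }


def _cys_block(rng: np.random.Generator, gaps: tuple[int, ...]) -> str:
    parts = ["C"]
    for g in gaps:
        parts.append(_filler(rng, g))
        parts.append("C")
    return "".join(parts)


def make_proteome(
    config: dict | None = None, seed: int = 7
) -> tuple[list[ProteinRecord], GeneratorManifest]:
    """Generate a proteome of planted positives and decoys.

    Planted positives carry a signal-peptide variant (cleavage 17) and a
    family-defining mature region; each decoy category provably violates
    exactly one cascade gate.  Deterministic for a fixed (config, seed).
    """
    cfg = dict(default_proteome_config() if config is None else config)
    rng = np.random.default_rng(seed)
    manifest = GeneratorManifest(seed=seed, config=dict(cfg))
    records: list[ProteinRecord] = []

    def sp(rng) -> str:
        return SP_VARIANTS[rng.integers(0, len(SP_VARIANTS))]

    def add(pid: str, seq: str, **truth) -> None:
        records.append(ProteinRecord(protein_id=pid, sequence=seq, gene_id=pid))
        manifest.records.append({"id": pid, **truth})

    for i in range(cfg.get("cep", 0)):
        n_domains = 1 if i % 2 == 0 else 2
        mature = _filler(rng, 30)
        for _ in range(n_domains):
            mature += _filler(rng, 9) + CEP_DOMAIN
        mature += "GG"
        add(
            f"syn_cep_{i:03d}", sp(rng) + mature,
            category="cep", family="CEP", n_domains=n_domains, is_ssp=True,
        )

    for i in range(cfg.get("cle", 0)):
        mature = _filler(rng, int(rng.integers(20, 31))) + CLE_BOX + "GG"
        add(
            f"syn_cle_{i:03d}", sp(rng) + mature,
            category="cle", family="CLE", is_ssp=True,
        )

    for i in range(cfg.get("ralf", 0)):
        gaps = (int(rng.integers(3, 7)), int(rng.integers(6, 10)), int(rng.integers(2, 5)))
        mature = "RR" + _filler(rng, 10) + _cys_block(rng, gaps) + _filler(rng, 2) + "GG"
        add(
            f"syn_ralf_{i:03d}", sp(rng) + mature,
            category="ralf", family="RALF", n_cys=4, is_ssp=True,
        )

    for i in range(cfg.get("pnp", 0)):
        mature = (
            _filler(rng, 8) + PNP_BOX1 + _filler(rng, 10) + PNP_BOX2
            + _filler(rng, 5) + "GG"
        )
        add(
            f"syn_pnp_{i:03d}", sp(rng) + mature,
            category="pnp", family="PNP", is_ssp=True,
        )

    for i in range(cfg.get("crp6c_i", 0)):
        var = int(rng.choice(CRP6C_I_VARIABLE_CHOICES))
        gaps = CRP6C_I_FIXED + (var,)
        mature = _filler(rng, 6) + _cys_block(rng, gaps) + _filler(rng, 3) + "GG"
        add(
            f"syn_crp6c_i_{i:03d}", sp(rng) + mature,
            category="crp6c_i", family="unknown", gap_vector=list(gaps), is_ssp=True,
        )

    for i in range(cfg.get("crp6c_ii", 0)):
        gaps = tuple(int(rng.choice(ch)) for ch in CRP6C_II_GAPS)
        mature = _filler(rng, 6) + _cys_block(rng, gaps) + _filler(rng, 3) + "GG"
        add(
            f"syn_crp6c_ii_{i:03d}", sp(rng) + mature,
            category="crp6c_ii", family="unknown", gap_vector=list(gaps), is_ssp=True,
        )

    for i in range(cfg.get("decoy_nosp", 0)):
        seq = "M" + _filler(rng, int(rng.integers(50, 81))) + "GG"
        add(f"syn_nosp_{i:03d}", seq, category="decoy_nosp", is_ssp=False,
            removed_at="sp")

    for i in range(cfg.get("decoy_tm", 0)):
        seq = sp(rng) + _filler(rng, 10) + "L" * 21 + _filler(rng, 10) + "GG"
        add(f"syn_tm_{i:03d}", seq, category="decoy_tm", is_ssp=False,
            removed_at="tm")

    for i in range(cfg.get("decoy_er", 0)):
        suffix = "KDEL" if i % 2 == 0 else "HDEL"
        seq = sp(rng) + _filler(rng, int(rng.integers(30, 51))) + suffix
        add(f"syn_er_{i:03d}", seq, category="decoy_er", is_ssp=False,
            removed_at="er")

    for i in range(cfg.get("decoy_long", 0)):
        seq = sp(rng) + _filler(rng, int(rng.integers(240, 301))) + "GG"
        add(f"syn_long_{i:03d}", seq, category="decoy_long", is_ssp=False,
            removed_at="length")

    for i in range(cfg.get("decoy_short", 0)):
        seq = "M" + _filler(rng, int(rng.integers(5, 20)))
        add(f"syn_short_{i:03d}", seq, category="decoy_short", is_ssp=False,
            removed_at="length")

    return records, manifest


# --------------------------------------------------------------------------
# Genome generation
# --------------------------------------------------------------------------

#: Back-translation codon table.  Codons are chosen so that no ATG or CAT
#: trigram can form inside a codon or across any junction: no codon starts
#: with AT or TG, none ends with AT or CA, and none contains ATG/CAT.
#: Consequently the only start codons (either strand) are the planted ATGs.
BACKTRANSLATE = {
    "K": "AAA", "T": "ACC", "N": "AAC", "L": "CTC", "F": "TTC",
    "V": "GTC", "A": "GCC", "G": "GGC", "S": "AGC", "D": "GAC",
    "E": "GAA", "Q": "CAA",
}
STOP = "TAA"
GUARD_LEFT = "CCGGGG"   # ends GG: no CAT ahead of the planted ATG
GUARD_RIGHT = "CCGGCC"

_BASES = np.array(list("ACGT"))
_BASE_P = np.array([0.31, 0.19, 0.19, 0.31])  # GC fraction 0.38


def _encode_orf(peptide: str) -> str:
    """Guarded cassette: guard + ATG + codons + stop + guard.

    The peptide's leading M becomes the ATG; any internal M (a planted
    nested start) is emitted as ATG with the preceding codon forced to end
    in A by the table (all non-M codons end in A or C; a C before ATG would
    spell CAT, so the generator places K/E/Q ahead of internal starts).
    """
    assert peptide[0] == "M"
    codons = ["ATG"]
    for j, aa in enumerate(peptide[1:], start=1):
        if aa == "M":
            prev = codons[-1]
            if prev[-1] == "C":
                raise ValueError(
                    "internal start codon must follow an A-ending codon "
                    f"(residue {j}: previous codon {prev})"
                )
            codons.append("ATG")
        else:
            codons.append(BACKTRANSLATE[aa])
    return GUARD_LEFT + "".join(codons) + STOP + GUARD_RIGHT


def _sample_background(rng: np.random.Generator, n: int, context: str) -> str:
    """n background bases that never complete ATG or CAT given the context."""
    out = []
    last2 = context[-2:]
    for _ in range(n):
        while True:
            b = str(rng.choice(_BASES, p=_BASE_P))
            tri = last2 + b
            if tri[-3:] not in ("ATG", "CAT"):
                break
        out.append(b)
        last2 = (last2 + b)[-2:]
    return "".join(out)


def make_genome(
    n_secreted: int = 12,
    n_nonsp: int = 8,
    n_nested_pairs: int = 2,
    n_decoy_cds: int = 3,
    n_chromosomes: int = 2,
    spacing: tuple[int, int] = (80, 200),
    seed: int = 11,
) -> tuple[dict[str, str], list[tuple], GeneratorManifest]:
    """Genome with planted intergenic sORF cassettes and decoy CDS features.

    Returns (sequences, GFF3-style feature tuples (1-based inclusive),
    manifest).  Secreted cassettes encode SP-template peptides, non-SP
    cassettes hydrophilic peptides, nested pairs share a stop codon between
    two in-frame starts, and each decoy CDS *contains* a secreted-style
    cassette that masking must exclude.  About half of all cassettes go on
    the minus strand.  Background carries no ATG/CAT on either strand.
    """
    rng = np.random.default_rng(seed)
    manifest = GeneratorManifest(
        seed=seed,
        config={
            "n_secreted": n_secreted, "n_nonsp": n_nonsp,
            "n_nested_pairs": n_nested_pairs, "n_decoy_cds": n_decoy_cds,
            "n_chromosomes": n_chromosomes,
        },
    )

    jobs = []
    for i in range(n_secreted):
        pep = SP_TEMPLATE + _filler(rng, int(rng.integers(20, 41))) + "GG"
        jobs.append(("secreted", f"sec_{i:03d}", pep))
    for i in range(n_nonsp):
        pep = "M" + _filler(rng, int(rng.integers(30, 51))) + "GG"
        jobs.append(("nonsp", f"nonsp_{i:03d}", pep))
    for i in range(n_nested_pairs):
        # outer 40 aa; inner start at residue 12 (K before it avoids CAT)
        pep = (
            "M" + _filler(rng, 9) + "K" + "M" + _filler(rng, 26) + "GG"
        )
        jobs.append(("nested", f"nested_{i:03d}", pep))
    for i in range(n_decoy_cds):
        pep = SP_TEMPLATE + _filler(rng, 25) + "GG"
        jobs.append(("cds", f"cds_{i:03d}", pep))
    order = rng.permutation(len(jobs))
    jobs = [jobs[k] for k in order]

    chroms = [f"chr{c + 1}" for c in range(n_chromosomes)]
    seqs = {c: "" for c in chroms}
    features: list[tuple] = []
    for j, (kind, name, pep) in enumerate(jobs):
        chrom = chroms[j % n_chromosomes]
        cassette = _encode_orf(pep)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        ins = cassette
        if strand == "-":
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            ins = "".join(comp[b] for b in reversed(cassette))
        gap = int(rng.integers(*spacing))
        seqs[chrom] += _sample_background(rng, gap, seqs[chrom]) + "CC"
        pos = len(seqs[chrom])
        seqs[chrom] += ins
        L = len(cassette)
        orf_start = pos + len(GUARD_LEFT)              # 0-based ATG..stop span
        orf_end = pos + L - len(GUARD_RIGHT)
        entry = {
            "id": name, "category": kind, "chromosome": chrom,
            "strand": strand, "start": orf_start, "end": orf_end,
            "peptide": pep, "is_ssp": kind == "secreted",
        }
        if kind == "cds":
            # mask the whole cassette (1-based inclusive GFF3 feature)
            features.append(
                (chrom, pos + 1, pos + L, strand, "CDS", {"ID": [name]})
            )
            entry["is_ssp"] = False
        if kind == "nested":
            inner_offset = 3 * 11  # inner ATG 11 codons downstream
            if strand == "+":
                entry["outer"] = (orf_start, orf_end)
                entry["inner"] = (orf_start + inner_offset, orf_end)
            else:
                entry["outer"] = (orf_start, orf_end)
                entry["inner"] = (orf_start, orf_end - inner_offset)
        manifest.records.append(entry)
    for chrom in chroms:
        seqs[chrom] += _sample_background(
            rng, int(rng.integers(*spacing)), seqs[chrom]
        )
    return seqs, features, manifest


# --------------------------------------------------------------------------
# Expression / physiology generation
# --------------------------------------------------------------------------

def make_expression(
    n_up: int = 30,
    n_down: int = 20,
    n_null: int = 50,
    timepoints=DEFAULT_TIMEPOINTS,
    effect_lfc: float = 2.0,
    seed: int = 23,
) -> tuple[list[ExpressionRecord], GeneratorManifest]:
    """Expression matrix with planted effects at every timepoint.

    Planted genes get |log2FC| = effect_lfc +/- 0.25 with q <= 0.005; null
    genes get mild log-normal wobble with q >= 0.2, so the published
    thresholds (|log2FC| >= 1, q <= 0.05) recover the planted sets exactly.
    """
    rng = np.random.default_rng(seed)
    manifest = GeneratorManifest(
        seed=seed,
        config={"n_up": n_up, "n_down": n_down, "n_null": n_null,
                "effect_lfc": effect_lfc, "timepoints": list(timepoints)},
    )
    records = []

    def base_fpkm() -> float:
        return float(rng.lognormal(mean=2.0, sigma=0.8))

    for kind, n, sign in (("up", n_up, 1.0), ("down", n_down, -1.0), ("null", n_null, 0.0)):
        for i in range(n):
            gid = f"gene_{kind}_{i:03d}"
            ck = base_fpkm()
            treated, qv = {}, {}
            for tp in timepoints:
                if sign == 0.0:
                    lfc = float(rng.uniform(-0.5, 0.5))
                    q = float(rng.uniform(0.2, 1.0))
                else:
                    lfc = sign * (effect_lfc + float(rng.uniform(-0.25, 0.25)))
                    q = float(rng.uniform(1e-4, 0.005))
                treated[tp] = ck * 2.0 ** lfc
                qv[tp] = q
            records.append(
                ExpressionRecord(
                    gene_id=gid, fpkm_control=ck, fpkm_treated=treated, qvalue=qv
                )
            )
            manifest.records.append({"id": gid, "category": kind})
    return records, manifest


def make_physiology(
    n_per_group: int = 15, seed: int = 31
) -> tuple[list[PhysiologySample], GeneratorManifest]:
    """Leaf physiology samples for control / drought / drought+peptide.

    Group separations mimic a strong drought response partially rescued by
    peptide treatment: RWC ~95/55/75 %, REC ~20/70/45 %, MDA differences via
    the A532-A600 signal.  Fifteen samples per group.
    """
    rng = np.random.default_rng(seed)
    groups = {
        "control": {"rwc": 0.95, "rec": 0.20, "dA": 0.05},
        "drought": {"rwc": 0.55, "rec": 0.70, "dA": 0.20},
        "drought_peptide": {"rwc": 0.75, "rec": 0.45, "dA": 0.12},
    }
    manifest = GeneratorManifest(
        seed=seed, config={"n_per_group": n_per_group, "groups": list(groups)}
    )
    samples = []
    for gname, p in groups.items():
        for i in range(n_per_group):
            dw = 0.5 + float(rng.normal(0, 0.02))
            sw = dw + 2.0 + float(rng.normal(0, 0.05))
            frac = min(1.0, max(0.0, p["rwc"] + float(rng.normal(0, 0.02))))
            k2 = 1.2 + float(rng.normal(0, 0.05))
            a600 = 0.05 + float(rng.normal(0, 0.005))
            samples.append(
                PhysiologySample(
                    sample_id=f"{gname}_{i:02d}",
                    treatment=gname,
                    FW=dw + frac * (sw - dw),
                    SW=sw,
                    DW=dw,
                    K1=max(0.0, p["rec"] * k2 + float(rng.normal(0, 0.02))),
                    K2=k2,
                    A532=a600 + max(0.0, p["dA"] + float(rng.normal(0, 0.01))),
                    A600=a600,
                    Vr=4.0, V=3.0, Vt=1.0, Wt=0.3,
                )
            )
            manifest.records.append({"id": samples[-1].sample_id, "category": gname})
    return samples, manifest


# --------------------------------------------------------------------------
# File writers (text formats only)
# --------------------------------------------------------------------------

def write_proteome_fasta(records, manifest: GeneratorManifest, outdir: str | Path):
    from .sequence_io import write_protein_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_protein_fasta(records, outdir / "proteome.fasta")
    manifest.to_json(outdir / "manifest.json")
    return outdir / "proteome.fasta"


def write_genome_files(seqs, features, manifest, outdir: str | Path):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "genome.fasta"
    with open(fasta, "w") as fh:
        for chrom, seq in seqs.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    gff = outdir / "annotation.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, seq in seqs.items():
            fh.write(f"##sequence-region {chrom} 1 {len(seq)}\n")
        for chrom, start, end, strand, ftype, attrs in features:
            attr = ";".join(f"{k}={v[0]}" for k, v in attrs.items())
            fh.write(
                f"{chrom}\tsspminer\t{ftype}\t{start}\t{end}\t.\t{strand}\t0\t{attr}\n"
            )
    manifest.to_json(outdir / "manifest.json")
    return fasta, gff


def write_expression_tsv(records, manifest, outdir: str | Path,
                         timepoints=DEFAULT_TIMEPOINTS):
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        row = {"gene_id": r.gene_id, "ck": r.fpkm_control}
        for tp in timepoints:
            row[tp] = r.fpkm_treated[tp]
            row["q_" + tp] = r.qvalue[tp]
        rows.append(row)
    path = outdir / "expression.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    manifest.to_json(outdir / "manifest.json")
    return path
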