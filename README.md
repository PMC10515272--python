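# sspminer

Genome-wide discovery and classification of plant **small secreted peptides
(SSPs)** — signalling peptides whose precursors are short (25–250 aa), carry
an N-terminal signal peptide, lack transmembrane helices, and are not
retained in the ER — plus the downstream drought-stress analyses that
typically accompany an SSP survey (differential expression, qPCR relative
expression, leaf physiology).

Written for plant genomicists who want a tested, scriptable version of the
standard multi-step SSP survey instead of a chain of web tools.

## What it computes

**Identification cascade.** Starting from a predicted proteome (longest
transcript per gene), four sequential gates:

1. length gate: 25 ≤ L ≤ 250 aa;
2. signal-peptide gate: keep proteins with an N-terminal signal peptide and
   record the cleavage site (parsed from SignalP-5.0 short output, or a
   built-in deterministic hydropathy heuristic);
3. transmembrane gate: drop proteins with ≥ 1 TM helix in the mature
   sequence (TMHMM v2.0 short output, or a Kyte–Doolittle window heuristic);
4. ER-retention gate: drop proteins ending in K/HDEL.

Survivor counts after each gate form the cascade tally.

**Family classification.** A mature sequence with an even number (2–16) of
cysteines is a putative cysteine-rich peptide (CRP). A priority-ordered
motif rule set assigns known families over a controlled 38-family
vocabulary (shipped defaults: CEP `SPGxG[HN]`, a conservative CLE-box
skeleton, PNP `K(V/I)(V/I)D` + `LSxxA(F/I)xxIA`, RALF `RR` + exactly four
cysteines). Unclassified CRPs feed a novel-family discovery step that
groups peptides by cysteine count and spacing, e.g. the six-cysteine
archetypes `C x3 C x5 C x5 C x2 C xn C` and `C x5 C xn C x6 C x4-6 C x1 C`
(`xn` = any number of non-cysteine residues).

**sORF mining.** Non-coding sequence (genome minus annotated CDS) is
six-frame translated; every ATG→stop ORF of 25–250 codons is enumerated,
nested in-frame ORFs sharing a stop are collapsed to the longest, and the
surviving peptides run through the same cascade.

**CEP domains.** All `SPGxG[HN]` box occurrences per precursor, a 15-aa
candidate mature peptide per hit, and a single- vs multi-domain summary.

**Stress calculators.** DE calls at |log2 FC| ≥ 1 and q ≤ 0.05 with per-
timepoint tallies; qPCR relative expression 2^−ΔΔCt; RWC, REC and MDA leaf
physiology with one-way ANOVA and Tukey-based letter display:

    RWC = (FW − DW)/(SW − DW) × 100 %
    REC = K1/K2 × 100 %
    MDA (nM/g) = [(A532 − A600) × Vr/ε × 10⁹] / (Wt × Vt/V),  ε = 1.55×10⁵ L/mol/cm

**Synthetic fixtures.** `sspminer simulate` generates proteomes, genomes,
expression matrices and physiology tables with planted ground truth
(manifest JSON), so the whole pipeline is testable offline.

## Worked example

```bash
sspminer simulate proteome --seed 7 --out demo
sspminer identify --proteome demo/proteome.fasta --heuristic -o demo/out
# cascade tally: 90 -> 75 -> 55 -> 45 -> 40
```

The simulated proteome contains 90 proteins: 40 planted SSPs (CEP, CLE,
RALF, PNP and two novel-CRP spacing archetypes) plus 15 oversize, 20
signal-peptide-free, 10 transmembrane and 5 K/HDEL-terminal decoys. The
tally shows each gate removing exactly its decoy class; `demo/out/`
contains the per-protein table (length, MW, pI, gate flags, mature
sequence), the mature-peptide FASTA and the tally JSON. Classification
then assigns the known families and discovers the planted spacings:

```bash
sspminer classify --ssp-table demo/out/ssp_table.tsv --discover-novel -o demo/fam
# 32 of 40 assigned to known families
# 2 novel spacing families
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates all synthetic inputs from the seed and re-runs the main
computations end to end — cascade, classification, novel-family discovery,
secreted-sORF mining, CEP architecture, DE tally and the physiology group
comparison — printing a summary of what each recovered.

## Layout

- `src/sspminer/sequence_io.py` — FASTA/GFF3 I/O, longest transcript, MW/pI
- `src/sspminer/ssp_filter.py` — the four-gate cascade and predictors
- `src/sspminer/family_classify.py` — CRP rule, motif engine, discovery
- `src/sspminer/sorf_miner.py` — NCDS extraction and six-frame ORF mining
- `src/sspminer/cep.py` — CEP domain detection and architecture
- `src/sspminer/stress_expression.py`, `physiology.py` — stress calculators
- `src/sspminer/synthetic.py` — ground-truth fixture generators
- `docs/methods.md` — models, assumptions, numerical choices

Heuristic signal-peptide/TM calls are deterministic stand-ins for the
licensed external predictors: they make the pipeline testable, but make no
claim of reproducing SignalP/TMHMM output on real proteomes (see
`docs/methods.md`).
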