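# Methods

## The SSP model

A small secreted peptide (SSP) precursor is operationally defined by four
properties: length 25–250 aa inclusive; an N-terminal signal peptide; no
transmembrane helix in the mature (post-cleavage) region; and no C-terminal
ER-retention tetrapeptide (KDEL/HDEL, last four residues only — internal
K/HDEL is biologically inert for retention and is kept). The cascade
applies the gates in that order and reports survivors after each stage;
because the gates test disjoint evidence, the TM and ER stages commute and
the final set is order-independent past the SP stage.

Both length bounds and the gate order are configuration, not constants.

## Predictors

Signal-peptide and TM calls are a pluggable contract with three
implementations:

1. **SignalP-5.0 short-format parser** — positive iff the Prediction column
   is `SP(Sec/SPI)`; cleavage site is X of `CS pos: X-Y`. Unknown labels
   warn and count as negative.
2. **TMHMM v2.0 short-format parser** — helix count from `PredHel=N`.
3. **Built-in heuristics** — used where the licensed tools are unavailable
   and by every synthetic test. Signal peptide: within the first 45
   residues, an 8-residue window with mean Kyte–Doolittle hydropathy ≥ 1.6
   (the h-region), at least one K/R before it (the n-region), and a
   cleavage site 3–7 residues after the window whose −3/−1 residues are
   small (A/G/S/C/T, the Ala-X-Ala rule). Windows are scanned left-to-right
   and cleavage offsets farthest-first; the first admissible combination
   wins, making the call and cleavage site deterministic. TM: greedy count
   of non-overlapping 19-mers with mean hydropathy ≥ 1.8 in the mature
   sequence (counting in the mature region only avoids re-counting the
   signal peptide's own hydrophobic core).

The heuristics are calibrated only against the synthetic generator (below);
green tests establish internal consistency of the pipeline, not agreement
with SignalP/TMHMM on real proteomes. Real surveys should supply
precomputed predictor files. Missing verdicts are a hard error naming the
proteins — silent drops would corrupt the tallies.

## Molecular weight and isoelectric point

MW is the sum of average residue masses plus one water, reported in kDa.
pI is found by bisection on the Henderson–Hasselbalch net-charge curve with
EMBOSS-style pKa values (N-term 8.6, C-term 3.6; D 3.9, E 4.1, C 8.5,
Y 10.1, H 6.5, K 10.8, R 12.5); the curve is monotone in pH so bisection
converges, and the returned pI satisfies |net charge| < 1e−4 e. Ambiguous
residues X/B/Z/U count toward length, contribute the mean residue mass, and
carry no charge — real proteomes contain them and rejecting whole records
for one X would bias the length gate.

## Family classification

The CRP rule counts cysteines over the *whole* mature sequence (not a
C-terminal window — the alternative reading; counts differ and the choice
is recorded here): even and within 2–16 ⇒ putative CRP.

Known families are assigned by a priority-ordered motif rule set over a
38-family controlled vocabulary (`data/family_vocabulary.yaml`); every rule
is linted against the vocabulary's class and mode-of-action. One family per
protein (first matching rule), PTM motifs ahead of cysteine-dependent
rules. Only families with plainly published defining motifs ship default
rules (CEP, CLE, PNP, RALF); the other 34 names exist in the vocabulary so
external assignments can be imported. The CLE default is a deliberately
conservative dodecapeptide skeleton (`R..P.GP.P.H[HN]`) and is expected to
be edited per survey; CLE A/B subtyping is not implemented (its criteria
live in an external reference).

Cysteine-spacing patterns (`C x3 C x5 … C`) treat gap residues as
non-cysteine, so a matched block contains exactly the pattern's cysteines
and pattern cysteines map onto consecutive C's of the sequence. The matcher
therefore walks the C-position list directly; `xn` means ≥ 0 residues.
Matches are leftmost, non-overlapping.

Novel-family discovery reduces each unclassified CRP to its gap vector and
agglomerates greedily in input order: a candidate joins a group when
cysteine counts agree and the combined per-position spread exceeds the gap
tolerance (default 1) at no more than one position — the designated
variable position. Consensus: exact gap where spread is 0, range where
within tolerance, variable otherwise. Greedy order makes the procedure
deterministic; for spacing archetypes separated by ≥ 2 positions the
membership is provably permutation-stable. This is one concrete
realization of what is in practice a manual comparison of cysteine
numbers and positions; `min_members` (default 3) and the tolerance are
exposed.

## sORF mining

Non-coding sequence is the per-chromosome complement of the union of CDS
intervals (strand-ignored; UTRs and introns stay searchable, configurable
to mask whole genes). GFF3 coordinates are converted to 0-based half-open
exactly once, in the reader. ORFs require both an ATG and an in-frame stop
(segment-truncated ORFs are dropped); codons containing N abort the ORF
rather than translating to X, so assembly gaps cannot yield phantom
peptides. Genomic intervals cover start through stop codon inclusive;
peptides exclude the stop. Nested elimination keeps one ORF per
(chromosome, strand, frame, stop position) — the most upstream start.
Single-exon ORFs only; spliced peptides require re-annotation and are out
of scope. Mined peptides enter the cascade with the length gate
pre-satisfied (the enumeration already enforces 25–250 aa), and the tally
is reported per chromosome.

## CEP domains

The CEP box is matched exactly as `SPG.G[HN]`, leftmost non-overlapping.
The candidate mature peptide is the 15-residue window ending at the box's
last residue — both published synthesized peptides are 15-mers ending in
`SPGEGH`, and no cleavage rule beyond that is published — so the window
length is a parameter, not a biochemical claim; windows clipped by the
N-terminus are flagged.

## Expression and physiology

DE calls: up iff log2((treated+pc)/(control+pc)) ≥ 1 and q ≤ 0.05, down
symmetric; thresholds and pseudocount (default 0) are parameters. With
pseudocount 0, a zero FPKM raises — never a silent infinity. q-values are
consumed as provided; Benjamini–Hochberg is available as a convenience for
synthetic raw p-values only. Tissue-expression grouping is not computed
(no published criteria); only matrix readers are provided.

The MDA expression is evaluated in the literal printed operator order,
`((A532−A600)·Vr/ε)·10⁹ / (Wt·Vt/V)`; its unit label (nM/g) is reproduced
as printed even though strict bookkeeping of these inputs gives nmol/g —
the numerical value is what the formula yields either way. RWC warns (but
still answers) when FW falls outside [DW, SW]; REC warns above 100 %.

Group comparison: scipy one-way ANOVA plus statsmodels Tukey HSD, compact
letter display by insert-and-absorb over the non-significant pairs (the
source convention says only "different lowercase letters"; letters denote
sets with no significant internal pair). Degenerate all-equal groups short-
circuit to a single letter with p = 1.

## Synthetic data: the stated world

The generators are pure functions of (config, seed) — reruns are
byte-identical — and every planted record is *provably* classified by
construction, not probabilistically:

- Planted signal peptides use the fixed template `MKTNLFLVLLLAGSALA`
  (heuristic cleavage after position 17) or one of six enumerated
  detection-preserving point mutations, each unit-tested against the
  heuristic.
- Random filler is drawn from `{D,E,N,Q,K,G,T}` — all hydropathy-negative,
  no C/R/S/P/H/M/I — so filler can never satisfy the SP/TM rules, spell a
  shipped motif, or end in K/HDEL.
- The default proteome is 90 proteins: 8 CEP (alternating 1/2 domains),
  8 CLE, 8 RALF, 8 PNP, 4+4 six-cysteine spacing archetypes, and 15
  oversize / 20 no-SP / 10 TM / 5 K/HDEL decoys, each decoy violating
  exactly its target gate. Archetype I varies its last gap over
  {6,8,10,12}; archetype II fixes gaps (5,·,6,·,1), varies gap 2 over
  {8,10,12,14} and gap 4 over {5,6} so discovery provably yields one
  variable position and one within-tolerance range.
- Genome cassettes back-translate peptides with a codon table chosen so the
  trigrams ATG and CAT occur nowhere except planted start codons — on
  either strand, every ORF in the genome is planted. Background base
  sampling (GC 0.38) rejects any draw completing ATG/CAT. Defaults: 12
  secreted cassettes, 8 non-SP, 2 nested start pairs (shared stop, inner
  start 11 codons in), 3 decoy CDS features each containing a secreted-style
  cassette that masking must exclude; ~half of all cassettes on the minus
  strand; ≥ 80 nt spacing.
- Expression: planted genes get |log2FC| = 2 ± 0.25 with q ∈ [1e−4, 0.005]
  at every timepoint; nulls get |log2FC| ≤ 0.5 with q ∈ [0.2, 1] — both
  sides clear the published thresholds with margin, so tallies recover
  planted counts exactly. Defaults (30 up, 20 down, 50 null; 5 timepoints)
  mirror a small drought time-course.
- Physiology: 15 samples/group (the published sample size) for control /
  drought / drought+peptide with RWC ≈ 95/55/75 %, REC ≈ 20/70/45 % — a
  strong drought response partially rescued by peptide treatment.

What the fixtures do **not** emulate: real signal-peptide diversity,
genome-scale ORF background (millions of sORFs), multi-exon genes,
correlated expression noise, or batch effects. A green suite therefore
establishes that the algorithms implement their stated rules exactly — not
that the heuristics match the external predictors on biological data.

## Known limitations

- Heuristic SP/TM calls are pipeline stand-ins; headline counts from real
  surveys depend on SignalP-5.0/TMHMM and are not reproduced here.
- Family assignment is motif-based; profile-HMM/BLAST-backed classification
  must be imported via the rule file or external tables.
- Discovery's greedy agglomeration can depend on input order for archetypes
  closer than the separation bound above.
- Six-frame mining is single-exon; coding-potential scoring and
  transcript/peptide-level validation are out of scope.
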