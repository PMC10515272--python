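# Default motif rules for known-family classification, in priority order
# (PTM motifs before cysteine-dependent rules; first match wins).  Only the
# families whose defining motifs are published in plain text ship defaults:
#
#   CEP  — the conserved SPGxG(H/N) box of the ~15-aa mature peptide, in the
#          C-terminal region of the precursor.
#   CLE  — a conservative CLE-box dodecapeptide skeleton (CLV3-style
#          R..P.GP.P.H[HN]); editable, since published alignments show
#          family-level variation the skeleton deliberately under-matches.
#   PNP  — co-occurrence of the K(V/I)(V/I)D and LSxxA(F/I)xxIA boxes.
#   RALF — the dibasic endoprotease site (RR) together with exactly four
#          mature-sequence cysteines.
#
# Motifs are restricted regular expressions over the amino-acid alphabet;
# every motif listed for a rule must match.  Edit or extend freely — the
# engine lints each rule's class/mode against family_vocabulary.yaml.

- family: CEP
  class: PTM
  mode_of_action: Signal
  motifs: ["SPG.G[HN]"]
  search_region: c_terminal_k
  c_terminal_k: 50

- family: CLE
  class: PTM
  mode_of_action: Signal
  motifs: ["R..P.GP.P.H[HN]"]
  search_region: c_terminal_k
  c_terminal_k: 30

- family: PNP
  class: NonCysNonPTM
  mode_of_action: Signal
  motifs: ["K[VI][VI]D", "LS..A[FI]..IA"]
  search_region: mature

- family: RALF
  class: CRP
  mode_of_action: Signal
  motifs: ["RR"]
  search_region: mature
  exact_cys: 4
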