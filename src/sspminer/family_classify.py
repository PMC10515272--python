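"""Family classification of SSP candidates.

Three layers:

* the cysteine-rich-peptide (CRP) rule — a mature sequence with an even
  number (2–16) of cysteines is a putative CRP;
* a rule/motif engine assigning candidates to known families from a
  controlled 38-family vocabulary (CEP, CLE, RALF, PNP carry shipped default
  motifs; the rule file is an editable YAML resource);
* novel-family discovery over the unclassified CRPs by comparing the number
  and spacing of their cysteine residues (the CRP_6C-style procedure).

Cysteine-spacing patterns are written ``C x3 C x5 C x5 C x2 C xn C``: gaps
between consecutive cysteines are exact (``x3``), ranged (``x4-6``) or
variable (``xn``, any number >= 0).  Gap residues are non-cysteine, so a
matched block contains exactly the pattern's cysteines.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .ssp_filter import SSPCandidate

__all__ = [
    "CysPattern",
    "FamilyRule",
    "FamilyAssignment",
    "CRP_6C_I",
    "CRP_6C_II",
    "is_crp",
    "parse_cys_pattern",
    "match_cys_pattern",
    "cys_gap_vector",
    "load_family_vocabulary",
    "load_family_rules",
    "lint_rules",
    "classify_known_families",
    "discover_novel_crp_families",
]

SSP_CLASSES = {"PTM", "CRP", "NonCysNonPTM", "FunctionalPrecursor"}
MODES_OF_ACTION = {"Signal", "Antimicrobial", "PeptidaseInhibitor", "Unknown"}

VARIABLE = "n"  # sentinel for an unbounded gap


@dataclass(frozen=True)
class CysPattern:
    """A cysteine-spacing pattern: n_cys cysteines and n_cys-1 gap specs.

    Each gap spec is an int (exact), a (lo, hi) tuple (range) or the string
    ``"n"`` (variable, >= 0 residues).
    """

    n_cys: int
    gaps: tuple
    label: str = ""

    def __post_init__(self):
        if len(self.gaps) != self.n_cys - 1:
            raise ValueError(
                f"pattern {self.label!r}: {self.n_cys} cysteines need "
                f"{self.n_cys - 1} gaps, got {len(self.gaps)}"
            )
        for g in self.gaps:
            if isinstance(g, int):
                if g < 0:
                    raise ValueError("exact gap must be >= 0")
            elif isinstance(g, tuple):
                lo, hi = g
                if not (0 <= lo <= hi):
                    raise ValueError(f"bad gap range {g}")
            elif g != VARIABLE:
                raise ValueError(f"bad gap spec {g!r}")

    def gap_matches(self, i: int, d: int) -> bool:
        g = self.gaps[i]
        if isinstance(g, int):
            return d == g
        if isinstance(g, tuple):
            return g[0] <= d <= g[1]
        return d >= 0

    def to_text(self) -> str:
        parts = ["C"]
        for g in self.gaps:
            if isinstance(g, int):
                parts.append(f"x{g}")
            elif isinstance(g, tuple):
                parts.append(f"x{g[0]}-{g[1]}")
            else:
                parts.append("xn")
            parts.append("C")
        return " ".join(parts)

    def to_regex(self) -> str:
        """Equivalent regular expression (gap residues are non-C)."""
        out = ["C"]
        for g in self.gaps:
            if isinstance(g, int):
                out.append("[^C]{%d}" % g)
            elif isinstance(g, tuple):
                out.append("[^C]{%d,%d}" % g)
            else:
                out.append("[^C]*")
            out.append("C")
        return "".join(out)


_GAP_TOKEN = re.compile(r"^x(?:(\d+)(?:-(\d+))?|n)$")


def parse_cys_pattern(text: str, label: str = "") -> CysPattern:
    """Parse ``C x3 C x5 ... C`` notation into a :class:`CysPattern`."""
    tokens = text.split()
    if not tokens:
        raise ValueError("empty cysteine pattern")
    gaps = []
    for i, tok in enumerate(tokens):
        if i % 2 == 0:
            if tok != "C":
                raise ValueError(
                    f"pattern {text!r}: expected 'C' at token {i + 1}, got {tok!r}"
                )
        else:
            m = _GAP_TOKEN.match(tok)
            if not m:
                raise ValueError(
                    f"pattern {text!r}: bad gap token {tok!r} at position {i + 1}"
                )
            if tok == "xn":
                gaps.append(VARIABLE)
            elif m.group(2) is not None:
                gaps.append((int(m.group(1)), int(m.group(2))))
            else:
                gaps.append(int(m.group(1)))
    if len(tokens) % 2 == 0:
        raise ValueError(f"pattern {text!r}: must end with 'C'")
    n_cys = (len(tokens) + 1) // 2
    if n_cys < 2:
        raise ValueError(f"pattern {text!r}: needs at least two cysteines")
    return CysPattern(n_cys=n_cys, gaps=tuple(gaps), label=label or text)


#: The two novel tomato-style six-cysteine family patterns.
CRP_6C_I = parse_cys_pattern("C x3 C x5 C x5 C x2 C xn C", label="CRP_6C I")
CRP_6C_II = parse_cys_pattern("C x5 C xn C x6 C x4-6 C x1 C", label="CRP_6C II")


@dataclass(frozen=True)
class CysMatch:
    start: int            # 0-based index of the first cysteine
    end: int              # exclusive index past the last cysteine
    cys_positions: tuple  # 0-based positions of the matched cysteines


def match_cys_pattern(pattern: CysPattern, sequence: str) -> list[CysMatch]:
    """All non-overlapping, leftmost-first occurrences of a spacing pattern.

    Because gap residues are non-cysteine, the pattern's cysteines must map
    onto consecutive C's of the sequence; the scan therefore walks the C
    position list directly (kept independent of any regex machinery — the
    regex form serves as a cross-check in the test-suite, not here).
    """
    cpos = [i for i, a in enumerate(sequence) if a == "C"]
    matches: list[CysMatch] = []
    i = 0
    need = pattern.n_cys
    while i + need <= len(cpos):
        ok = True
        for j in range(need - 1):
            d = cpos[i + j + 1] - cpos[i + j] - 1
            if not pattern.gap_matches(j, d):
                ok = False
                break
        if ok:
            block = tuple(cpos[i : i + need])
            matches.append(
                CysMatch(start=block[0], end=block[-1] + 1, cys_positions=block)
            )
            i += need  # non-overlapping: resume after the matched block
        else:
            i += 1
    return matches


def is_crp(mature_sequence: str) -> tuple[bool, int]:
    """CRP rule: even number (2–16) of cysteines in the mature sequence."""
    n = mature_sequence.count("C")
    return (n % 2 == 0 and 2 <= n <= 16, n)


def cys_gap_vector(mature_sequence: str) -> tuple[int, ...]:
    """Gaps between consecutive cysteines of the mature sequence."""
    cpos = [i for i, a in enumerate(mature_sequence) if a == "C"]
    return tuple(b - a - 1 for a, b in zip(cpos, cpos[1:]))


# --------------------------------------------------------------------------
# Known-family rule engine
# --------------------------------------------------------------------------

@dataclass
class FamilyRule:
    """A motif rule for one family.

    ``motifs`` are restricted regular expressions over the amino-acid
    alphabet (literals, ``.`` wildcards, ``[..]`` classes, ``{a,b}`` counts);
    all must match.  ``search_region`` selects where to look: the mature
    sequence, its last ``c_terminal_k`` residues, or the full precursor.
    ``exact_cys`` (optional) additionally requires that cysteine count in the
    mature sequence.
    """

    family: str
    ssp_class: str
    mode_of_action: str
    motifs: list[str]
    search_region: str = "mature"
    c_terminal_k: int = 50
    exact_cys: int | None = None
    _compiled: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        if self.ssp_class not in SSP_CLASSES:
            raise ValueError(f"{self.family}: unknown class {self.ssp_class!r}")
        if self.mode_of_action not in MODES_OF_ACTION:
            raise ValueError(
                f"{self.family}: unknown mode of action {self.mode_of_action!r}"
            )
        if self.search_region not in {"mature", "c_terminal_k", "full"}:
            raise ValueError(f"{self.family}: bad search region")
        if not self.motifs:
            raise ValueError(f"{self.family}: rule has no motifs")
        self._compiled = [re.compile(m) for m in self.motifs]

    def region_of(self, candidate: SSPCandidate) -> tuple[str, int]:
        """(searched text, offset of that text on its parent sequence)."""
        if self.search_region == "full":
            return candidate.record.sequence, 0
        mature = candidate.mature_sequence or candidate.record.sequence
        if self.search_region == "mature":
            return mature, 0
        k = min(self.c_terminal_k, len(mature))
        return mature[-k:], len(mature) - k

    def evaluate(self, candidate: SSPCandidate):
        """None if the rule does not apply, else (evidence, n_domains)."""
        if self.exact_cys is not None:
            mature = candidate.mature_sequence or candidate.record.sequence
            if mature.count("C") != self.exact_cys:
                return None
        region, offset = self.region_of(candidate)
        evidence = []
        for rx in self._compiled:
            hits = list(rx.finditer(region))
            if not hits:
                return None
            evidence.append(hits)
        # domain count from the first (defining) motif
        n_domains = len(evidence[0])
        spans = [
            (rx_hits[0].group(0), rx_hits[0].start() + offset, rx_hits[0].end() + offset)
            for rx_hits in evidence
        ]
        return spans, n_domains


@dataclass(frozen=True)
class FamilyAssignment:
    protein_id: str
    family: str
    ssp_class: str
    mode_of_action: str
    n_domains: int
    evidence: tuple  # (motif text, start, end) on the searched parent, 0-based half-open


def _data_text(name: str) -> str:
    return resources.files("sspminer.data").joinpath(name).read_text()


def load_family_vocabulary(path: str | Path | None = None) -> dict[str, dict]:
    """The controlled 38-family vocabulary: family -> class / mode / n_tomato."""
    text = Path(path).read_text() if path else _data_text("family_vocabulary.yaml")
    vocab = yaml.safe_load(text)
    for fam, info in vocab.items():
        if info["class"] not in SSP_CLASSES:
            raise ValueError(f"vocabulary: {fam} has unknown class {info['class']}")
        if info["mode_of_action"] not in MODES_OF_ACTION:
            raise ValueError(f"vocabulary: {fam} has unknown mode")
    return vocab


def load_family_rules(path: str | Path | None = None) -> list[FamilyRule]:
    """Load motif rules (shipped defaults: CEP, CLE, PNP, RALF, in priority order)."""
    text = Path(path).read_text() if path else _data_text("family_rules.yaml")
    raw = yaml.safe_load(text)
    rules = [
        FamilyRule(
            family=r["family"],
            ssp_class=r["class"],
            mode_of_action=r["mode_of_action"],
            motifs=list(r["motifs"]),
            search_region=r.get("search_region", "mature"),
            c_terminal_k=r.get("c_terminal_k", 50),
            exact_cys=r.get("exact_cys"),
        )
        for r in raw
    ]
    if not rules:
        raise ValueError("empty family rule set")
    seen = set()
    for r in rules:
        if r.family in seen:
            raise ValueError(f"duplicate rule for family {r.family}")
        seen.add(r.family)
    return rules


def lint_rules(
    rules: Sequence[FamilyRule], vocabulary: dict[str, dict] | None = None
) -> None:
    """Every rule's family/class/mode must agree with the vocabulary."""
    vocab = vocabulary or load_family_vocabulary()
    for r in rules:
        if r.family not in vocab:
            raise ValueError(f"rule family {r.family!r} not in vocabulary")
        v = vocab[r.family]
        if r.ssp_class != v["class"] or r.mode_of_action != v["mode_of_action"]:
            raise ValueError(
                f"rule {r.family}: class/mode {r.ssp_class}/{r.mode_of_action} "
                f"disagree with vocabulary {v['class']}/{v['mode_of_action']}"
            )


def classify_known_families(
    candidates: Sequence[SSPCandidate],
    rules: Sequence[FamilyRule] | None = None,
) -> list[FamilyAssignment]:
    """Assign each candidate its first matching rule's family (or 'unknown').

    Rules are evaluated in list order — shipped order puts the PTM motifs
    (CEP, CLE) before the generic cysteine-dependent rules — so each protein
    receives exactly one label.
    """
    if rules is None:
        rules = load_family_rules()
    if not rules:
        raise ValueError("empty family rule set")
    out = []
    for cand in candidates:
        assigned = None
        for rule in rules:
            res = rule.evaluate(cand)
            if res is not None:
                spans, n_domains = res
                assigned = FamilyAssignment(
                    protein_id=cand.protein_id,
                    family=rule.family,
                    ssp_class=rule.ssp_class,
                    mode_of_action=rule.mode_of_action,
                    n_domains=n_domains,
                    evidence=tuple(spans),
                )
                break
        if assigned is None:
            assigned = FamilyAssignment(
                protein_id=cand.protein_id,
                family="unknown",
                ssp_class="CRP" if is_crp(cand.mature_sequence or cand.record.sequence)[0] else "NonCysNonPTM",
                mode_of_action="Unknown",
                n_domains=0,
                evidence=(),
            )
        out.append(assigned)
    return out


# --------------------------------------------------------------------------
# Novel CRP family discovery
# --------------------------------------------------------------------------

def _spread(vectors: list[tuple[int, ...]]) -> list[int]:
    return [max(col) - min(col) for col in zip(*vectors)]


def discover_novel_crp_families(
    unknown_crps: Sequence[SSPCandidate],
    min_members: int = 3,
    gap_tolerance: int = 1,
) -> list[tuple[CysPattern, list[str]]]:
    """Group unclassified CRPs by shared cysteine count and spacing.

    Each candidate is reduced to its mature-sequence cysteine gap vector.
    Groups are grown greedily in input order: a candidate joins a group when
    both have the same cysteine count and the combined per-position spread
    exceeds ``gap_tolerance`` at no more than one position (the designated
    variable position).  Groups with >= ``min_members`` members are emitted
    as consensus patterns: exact gap where the spread is zero, a range where
    it is within tolerance, variable at the designated position.

    Greedy agglomeration in input order is deterministic; for well-separated
    spacing archetypes the resulting membership is permutation-stable.
    """
    entries = []
    for cand in unknown_crps:
        mature = cand.mature_sequence or cand.record.sequence
        crp, n = is_crp(mature)
        if not crp:
            continue
        entries.append((cand.protein_id, n, cys_gap_vector(mature)))

    groups: list[dict] = []
    for pid, n, gaps in entries:
        placed = False
        for grp in groups:
            if grp["n_cys"] != n:
                continue
            spread = _spread(grp["vectors"] + [gaps])
            if sum(1 for s in spread if s > gap_tolerance) <= 1:
                grp["vectors"].append(gaps)
                grp["members"].append(pid)
                placed = True
                break
        if not placed:
            groups.append({"n_cys": n, "vectors": [gaps], "members": [pid]})

    out = []
    for k, grp in enumerate(g for g in groups if len(g["members"]) >= min_members):
        spread = _spread(grp["vectors"])
        cols = list(zip(*grp["vectors"]))
        consensus = []
        for i, col in enumerate(cols):
            if spread[i] > gap_tolerance:
                consensus.append(VARIABLE)  # the designated variable position
            elif spread[i] == 0:
                consensus.append(col[0])
            else:
                consensus.append((min(col), max(col)))
        pattern = CysPattern(
            n_cys=grp["n_cys"],
            gaps=tuple(consensus),
            label=f"novel_CRP_{grp['n_cys']}C_{k + 1}",
        )
        out.append((pattern, list(grp["members"])))
    return out
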