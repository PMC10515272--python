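"""CRP rule, cysteine-spacing patterns, rule engine and novel-family discovery."""

import re

import numpy as np
import pytest

from sspminer.family_classify import (
    CRP_6C_I,
    CRP_6C_II,
    CysPattern,
    classify_known_families,
    cys_gap_vector,
    discover_novel_crp_families,
    is_crp,
    lint_rules,
    load_family_rules,
    load_family_vocabulary,
    match_cys_pattern,
    parse_cys_pattern,
)
from sspminer.ssp_filter import PredictorConfig, run_cascade
from sspminer.synthetic import make_proteome


class TestIsCrp:
    @pytest.mark.parametrize("n", range(21))
    def test_exhaustive_cys_count_sweep(self, n):
        """Even 2-16 cysteines in the mature sequence => putative CRP."""
        seq = "G".join(["C"] * n) if n else "GGG"
        crp, count = is_crp(seq)
        assert count == n
        assert crp is (n % 2 == 0 and 2 <= n <= 16)


class TestParseCysPattern:
    def test_six_cys_archetype_i(self):
        pat = parse_cys_pattern("C x3 C x5 C x5 C x2 C xn C")
        assert pat.n_cys == 6
        assert pat.gaps == (3, 5, 5, 2, "n")

    def test_six_cys_archetype_ii(self):
        pat = parse_cys_pattern("C x5 C xn C x6 C x4-6 C x1 C")
        assert pat.gaps == (5, "n", 6, (4, 6), 1)

    @pytest.mark.parametrize("bad", ["C C", "x3 C", "C x3", "C y3 C", "", "C x3-1 C"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_cys_pattern(bad)

    def test_roundtrip_text(self):
        text = "C x5 C xn C x6 C x4-6 C x1 C"
        assert parse_cys_pattern(text).to_text() == text


def _random_seq(rng, n):
    # cysteine-enriched alphabet so patterns actually fire
    return "".join(rng.choice(list("CAAGGTDE"), size=n))


class TestMatchCysPattern:
    def test_archetype_i_example(self):
        seq = "ACAAACAAAAACAAAAACAACAAAACG"
        matches = match_cys_pattern(CRP_6C_I, seq)
        assert len(matches) == 1
        m = matches[0]
        assert seq[m.start] == "C" and seq[m.end - 1] == "C"
        assert len(m.cys_positions) == 6

    def test_missing_final_cys_no_match(self):
        seq = "ACAAACAAAAACAAAAACAACAAAAG"
        assert match_cys_pattern(CRP_6C_I, seq) == []

    def test_zero_gap(self):
        pat = parse_cys_pattern("C x0 C")
        assert len(match_cys_pattern(pat, "CC")) == 1

    @pytest.mark.parametrize(
        "pattern,oracle_rx",
        [
            (CRP_6C_I, "C[^C]{3}C[^C]{5}C[^C]{5}C[^C]{2}C[^C]*C"),
            (CRP_6C_II, "C[^C]{5}C[^C]*C[^C]{6}C[^C]{4,6}C[^C]{1}C"),
            (parse_cys_pattern("C x0 C x2 C"), "C[^C]{0}C[^C]{2}C"),
        ],
    )
    def test_against_regex_oracle(self, pattern, oracle_rx):
        """The hand-written scanner agrees with an independent regex oracle
        on 1,000 random cysteine-rich sequences per pattern."""
        rx = re.compile(oracle_rx)
        rng = np.random.default_rng(42)
        for _ in range(1000):
            seq = _random_seq(rng, int(rng.integers(10, 120)))
            got = [(m.start, m.end) for m in match_cys_pattern(pattern, seq)]
            want = [(m.start(), m.end()) for m in rx.finditer(seq)]
            assert got == want, seq


class TestRuleEngine:
    def test_vocabulary_has_38_families(self):
        vocab = load_family_vocabulary()
        assert len(vocab) == 38
        assert sum(v["n_tomato"] for v in vocab.values()) == 557

    def test_rules_lint_against_vocabulary(self):
        lint_rules(load_family_rules())

    def test_planted_families_recovered(self, proteome_seed7, heuristic_predictor):
        records, manifest = proteome_seed7
        cands, _ = run_cascade(records, heuristic_predictor)
        truth = {r["id"]: r for r in manifest.records}
        for a in classify_known_families(cands):
            assert a.family == truth[a.protein_id].get("family", "unknown")
            if a.family == "CEP":
                assert a.ssp_class == "PTM"
                assert a.n_domains == truth[a.protein_id]["n_domains"]
            if a.family == "RALF":
                assert a.ssp_class == "CRP"

    def test_unmatched_is_unknown(self):
        from sspminer.sequence_io import ProteinRecord
        from sspminer.ssp_filter import SSPCandidate

        rec = ProteinRecord(protein_id="x", sequence="M" + "G" * 40)
        cand = SSPCandidate(record=rec, mature_sequence="G" * 30)
        (a,) = classify_known_families([cand])
        assert a.family == "unknown"

    def test_empty_rule_set_is_error(self):
        with pytest.raises(ValueError):
            classify_known_families([], rules=[])


@pytest.fixture(scope="module")
def archetype_candidates(heuristic_predictor):
    records, manifest = make_proteome(config={"crp6c_i": 7, "crp6c_ii": 10}, seed=3)
    cands, _ = run_cascade(records, heuristic_predictor)
    return cands, manifest


class TestNovelFamilyDiscovery:
    def test_two_groups_with_correct_consensus(self, archetype_candidates):
        cands, manifest = archetype_candidates
        groups = discover_novel_crp_families(cands)
        assert len(groups) == 2
        by_size = {len(members): pat for pat, members in groups}
        assert by_size[7].gaps == (3, 5, 5, 2, "n")
        assert by_size[10].gaps[0] == 5 and by_size[10].gaps[1] == "n"
        assert by_size[10].gaps[2] == 6 and by_size[10].gaps[4] == 1

    def test_no_cross_contamination(self, archetype_candidates):
        cands, manifest = archetype_candidates
        truth = {r["id"]: r["category"] for r in manifest.records}
        for _, members in discover_novel_crp_families(cands):
            assert len({truth[m] for m in members}) == 1

    def test_permutation_stable_membership(self, archetype_candidates):
        cands, _ = archetype_candidates
        base = {frozenset(m) for _, m in discover_novel_crp_families(cands)}
        rng = np.random.default_rng(9)
        for _ in range(5):
            shuffled = list(cands)
            rng.shuffle(shuffled)
            got = {frozenset(m) for _, m in discover_novel_crp_families(shuffled)}
            assert got == base

    def test_min_members_threshold(self, heuristic_predictor):
        records, _ = make_proteome(config={"crp6c_i": 2}, seed=4)
        cands, _ = run_cascade(records, heuristic_predictor)
        assert discover_novel_crp_families(cands, min_members=3) == []

    def test_gap_vector(self):
        assert cys_gap_vector("GCAAACGGCAA") == (3, 2)
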