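"""The four-gate identification cascade and its pluggable predictors."""

import numpy as np
import pytest

from sspminer.sequence_io import ProteinRecord
from sspminer.ssp_filter import (
    PredictorConfig,
    PredictorVerdict,
    filter_er_retention,
    filter_length,
    filter_signal_peptide,
    filter_transmembrane,
    heuristic_signal_peptide,
    heuristic_tm_count,
    load_signalp_short,
    load_tmhmm_short,
    run_cascade,
)
from sspminer.synthetic import SP_TEMPLATE, SP_VARIANTS, make_proteome


def _rec(pid, seq):
    return ProteinRecord(protein_id=pid, sequence=seq)


def _recs_of_lengths(lengths):
    return [
        _rec(f"p{n}", "M" + "A" * (n - 1)) for n in lengths
    ]


class TestLengthGate:
    def test_inclusive_bounds(self):
        out = filter_length(_recs_of_lengths([24, 25, 250, 251]))
        assert sorted(len(r) for r in out) == [25, 250]

    def test_empty_input(self):
        assert filter_length([]) == []

    def test_step10_sweep(self):
        out = filter_length(_recs_of_lengths(range(10, 301, 10)))
        assert len(out) == 23  # 30..250 inclusive, step 10

    def test_bad_config(self):
        with pytest.raises(ValueError):
            filter_length([], min_len=100, max_len=50)


class TestSignalPParser:
    def test_short_format(self, tmp_path):
        p = tmp_path / "signalp.txt"
        p.write_text(
            "# SignalP-5.0\n"
            "# ID\tPrediction\tSP(Sec/SPI)\tOTHER\tCS Position\n"
            "prot1\tSP(Sec/SPI)\t0.98\t0.02\tCS pos: 24-25. Pr: 0.93\n"
            "prot2\tOTHER\t0.01\t0.99\t\n"
        )
        v = load_signalp_short(p)
        assert v["prot1"].has_signal_peptide and v["prot1"].sp_cleavage_site == 24
        assert not v["prot2"].has_signal_peptide

    def test_unknown_label_warns_no_sp(self, tmp_path):
        p = tmp_path / "signalp.txt"
        p.write_text("prot3\tLIPO(Sec/SPII)\t0.5\t0.5\t\n")
        with pytest.warns(UserWarning, match="unknown prediction"):
            v = load_signalp_short(p)
        assert not v["prot3"].has_signal_peptide


class TestTMHMMParser:
    def test_predhel(self, tmp_path):
        p = tmp_path / "tmhmm.txt"
        p.write_text(
            "prot1\tlen=120\tExpAA=22.5\tFirst60=0.1\tPredHel=1\tTopology=i7-29o\n"
            "prot2\tlen=80\tExpAA=0.0\tFirst60=0.0\tPredHel=0\tTopology=o\n"
        )
        v = load_tmhmm_short(p)
        assert v["prot1"].tm_helix_count == 1
        assert v["prot2"].tm_helix_count == 0


class TestHeuristicSignalPeptide:
    @pytest.mark.parametrize("template", SP_VARIANTS)
    def test_planted_template_cleaved_at_17(self, template):
        rec = _rec("t", template + "DDEEGGNNQQKKTTDDEEGGNNQQ")
        v = heuristic_signal_peptide(rec)
        assert v.has_signal_peptide
        assert v.sp_cleavage_site == len(SP_TEMPLATE) == 17

    def test_poly_d_not_detected(self):
        v = heuristic_signal_peptide(_rec("d", "M" + "D" * 60))
        assert not v.has_signal_peptide

    def test_too_short_not_detected(self):
        v = heuristic_signal_peptide(_rec("s", "MKLLLLLLLAG"))  # 11 aa
        assert not v.has_signal_peptide


class TestTMGate:
    def test_poly_leucine_window_counts(self):
        assert heuristic_tm_count("L" * 19) == 1
        assert heuristic_tm_count("G" * 5 + "L" * 19 + "G" * 5) == 1
        assert heuristic_tm_count("G" * 30) == 0

    def test_tm_candidates_removed(self):
        recs = [_rec("tm", SP_TEMPLATE + "GG" + "L" * 21 + "GG"),
                _rec("ok", SP_TEMPLATE + "G" * 40)]
        cfg = PredictorConfig(heuristic=True)
        verdicts = cfg.verdicts(recs)
        cands = filter_signal_peptide(recs, verdicts)
        kept = filter_transmembrane(cands, verdicts)
        assert [c.protein_id for c in kept] == ["ok"]


class TestERGate:
    def _cand(self, pid, seq):
        cfg = PredictorConfig(heuristic=True)
        recs = [_rec(pid, seq)]
        return filter_signal_peptide(recs, cfg.verdicts(recs))

    @pytest.mark.parametrize(
        "suffix,removed",
        [("AHDEL", True), ("GKDEL", True), ("KDELS", False), ("GGGGG", False)],
    )
    def test_terminal_kdel_hdel(self, suffix, removed):
        cands = self._cand("x", SP_TEMPLATE + "G" * 20 + suffix)
        out = filter_er_retention(cands)
        assert (len(out) == 0) is removed


class TestMissingVerdicts:
    def test_sp_gate_names_missing_ids(self):
        recs = [_rec("a", SP_TEMPLATE + "G" * 20)]
        with pytest.raises(KeyError, match="a"):
            filter_signal_peptide(recs, {})

    def test_tm_gate_names_missing_ids(self):
        recs = [_rec("a", SP_TEMPLATE + "G" * 20)]
        cfg = PredictorConfig(heuristic=True)
        cands = filter_signal_peptide(recs, cfg.verdicts(recs))
        bare = {"a": PredictorVerdict("a", has_signal_peptide=True, sp_cleavage_site=17)}
        with pytest.raises(KeyError, match="a"):
            filter_transmembrane(cands, bare, heuristic_fallback=False)


class TestCascade:
    def test_empty_proteome(self, heuristic_predictor):
        cands, tally = run_cascade([], heuristic_predictor)
        assert cands == [] and tally.as_tuple() == (0, 0, 0, 0, 0)

    def test_all_passing_input_constant_tally(self, heuristic_predictor):
        recs = [_rec(f"p{i}", SP_TEMPLATE + "G" * 30) for i in range(5)]
        _, tally = run_cascade(recs, heuristic_predictor)
        assert tally.as_tuple() == (5, 5, 5, 5, 5)

    def test_monotone_and_summing(self, heuristic_predictor):
        for seed in (1, 2, 3):
            records, _ = make_proteome(seed=seed)
            _, tally = run_cascade(records, heuristic_predictor)
            t = tally.as_tuple()
            assert all(a >= b for a, b in zip(t, t[1:]))

    def test_tm_er_gates_commute(self, heuristic_predictor):
        """The TM and ER exclusions act on disjoint evidence, so applying
        them in either order yields the same final set."""
        rng = np.random.default_rng(5)
        records, _ = make_proteome(seed=int(rng.integers(100)))
        verdicts = heuristic_predictor.verdicts(records)
        cands = filter_signal_peptide(records, verdicts)
        ab = {c.protein_id for c in filter_er_retention(
            filter_transmembrane(list(cands), verdicts, True))}
        cands2 = filter_signal_peptide(records, verdicts)
        ba = {c.protein_id for c in filter_transmembrane(
            filter_er_retention(list(cands2)), verdicts, True)}
        assert ab == ba

    def test_planted_truth_recovered(self, proteome_seed7, heuristic_predictor):
        records, manifest = proteome_seed7
        cands, tally = run_cascade(records, heuristic_predictor)
        assert sorted(c.protein_id for c in cands) == sorted(manifest.true_ssp_ids)
        removed = {"length": 0, "sp": 0, "tm": 0, "er": 0}
        for r in manifest.records:
            if not r["is_ssp"]:
                removed[r["removed_at"]] += 1
        t = tally.as_tuple()
        assert t[0] - t[1] == removed["length"]
        assert t[1] - t[2] == removed["sp"]
        assert t[2] - t[3] == removed["tm"]
        assert t[3] - t[4] == removed["er"]
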