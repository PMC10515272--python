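"""Non-coding segment extraction, six-frame ORF enumeration, nested
elimination and the full secreted-sORF miner."""

import numpy as np
import pytest
from Bio.Seq import Seq

from sspminer.sequence_io import GenomeAnnotation
from sspminer.sorf_miner import (
    NonCodingSegment,
    eliminate_nested_orfs,
    extract_ncds,
    find_sorfs,
    mine_secreted_sorfs,
)


def brute_force_orfs(seq, min_aa, max_aa):
    """Independent oracle: test every (position, frame, strand) start
    separately, translating codon by codon with Biopython."""
    results = set()
    L = len(seq)
    for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        for i in range(L - 2):
            if s[i : i + 3] != "ATG":
                continue
            pep = []
            j = i
            stopped = False
            while j + 3 <= L:
                codon = s[j : j + 3]
                if "N" in codon:
                    break
                aa = str(Seq(codon).translate())
                if aa == "*":
                    stopped = True
                    break
                pep.append(aa)
                j += 3
            if stopped and min_aa <= len(pep) <= max_aa:
                if strand == "+":
                    g0, g1 = i, j + 3
                else:
                    g0, g1 = L - (j + 3), L - i
                results.add((g0, g1, strand, i % 3, "".join(pep)))
    return results


def _segment(seq, chrom="c", start=0):
    return NonCodingSegment(chrom, start, start + len(seq), seq)


def _orf_key(o):
    return (o.start, o.end, o.strand, o.frame, o.peptide)


def _random_dna(rng, n, with_n=False):
    alphabet = "ACGTN" if with_n else "ACGT"
    p = [0.24, 0.24, 0.24, 0.24, 0.04] if with_n else None
    return "".join(rng.choice(list(alphabet), size=n, p=p))


class TestExtractNcds:
    def _ann(self, length, cds):
        seq = "A" * length
        feats = [("c", s, e, "+", "CDS", {}) for s, e in cds]
        return GenomeAnnotation(sequences={"c": seq}, features=feats)

    def test_interval_complement(self):
        segs = extract_ncds(self._ann(1000, [(101, 200)]))
        assert [(s.start, s.end) for s in segs] == [(0, 100), (200, 1000)]

    def test_no_features_full_segment(self):
        segs = extract_ncds(self._ann(500, []))
        assert [(s.start, s.end) for s in segs] == [(0, 500)]

    def test_adjacent_cds_merged(self):
        segs = extract_ncds(self._ann(300, [(51, 100), (101, 150)]))
        assert [(s.start, s.end) for s in segs] == [(0, 50), (150, 300)]

    def test_feature_beyond_bounds_errors(self):
        with pytest.raises(ValueError):
            extract_ncds(self._ann(100, [(50, 200)]))


class TestFindSorfs:
    def test_boundary_min_aa(self):
        dna = "ATG" + "GCT" * 24 + "TAA"
        orfs = find_sorfs(_segment(dna), min_aa=25, max_aa=250)
        assert len(orfs) == 1 and len(orfs[0].peptide) == 25
        assert find_sorfs(_segment(dna), min_aa=26, max_aa=250) == []

    def test_n_codon_aborts_orf(self):
        dna = "ATG" + "GCT" * 10 + "GNT" + "GCT" * 20 + "TAA"
        assert find_sorfs(_segment(dna), min_aa=5, max_aa=250) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dna = _random_dna(rng, 2000, with_n=(seed % 3 == 0))
        got = {_orf_key(o) for o in find_sorfs(_segment(dna), min_aa=5, max_aa=250)}
        assert got == brute_force_orfs(dna, 5, 250)

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(77)
        dna = _random_dna(rng, 1500)
        rc = str(Seq(dna).reverse_complement())
        fwd = {( o.start, o.end, o.strand, o.peptide)
               for o in find_sorfs(_segment(dna), min_aa=5, max_aa=250)}
        L = len(dna)
        flip = {"+": "-", "-": "+"}
        mirrored = {(L - e, L - s, flip[st], p)
                    for o in find_sorfs(_segment(rc), min_aa=5, max_aa=250)
                    for s, e, st, p in [(o.start, o.end, o.strand, o.peptide)]}
        assert fwd == mirrored

    def test_coordinates_reproduce_peptide(self, genome_seed11, heuristic_predictor):
        ann, _ = genome_seed11
        _, _, orfs = mine_secreted_sorfs(ann, heuristic_predictor)
        assert orfs
        for o in orfs:
            nt = ann.sequences[o.chromosome][o.start : o.end]
            if o.strand == "-":
                nt = str(Seq(nt).reverse_complement())
            assert str(Seq(nt[:-3]).translate()) == o.peptide
            assert str(Seq(nt[-3:]).translate()) == "*"


class TestEliminateNested:
    def test_two_starts_one_stop_keeps_longer(self):
        dna = "ATG" + "GCT" * 5 + "ATG" + "GCT" * 24 + "TAA"
        orfs = find_sorfs(_segment(dna), min_aa=5, max_aa=250)
        assert len(orfs) == 2
        kept = eliminate_nested_orfs(orfs)
        assert len(kept) == 1 and len(kept[0].peptide) == 31

    def test_distinct_stops_all_kept(self):
        dna = "ATG" + "GCT" * 6 + "TAA" + "ATG" + "GCT" * 6 + "TAA"
        orfs = find_sorfs(_segment(dna), min_aa=5, max_aa=250)
        assert len(eliminate_nested_orfs(orfs)) == len(orfs) == 2

    def test_unique_stop_keys(self):
        rng = np.random.default_rng(13)
        dna = "".join(rng.choice(list("ACGT"), size=4000))
        kept = eliminate_nested_orfs(find_sorfs(_segment(dna), min_aa=5, max_aa=250))
        keys = [o.stop_key for o in kept]
        assert len(keys) == len(set(keys))


class TestMineSecretedSorfs:
    def test_planted_recovery(self, genome_seed11, heuristic_predictor):
        ann, manifest = genome_seed11
        cands, tallies, _ = mine_secreted_sorfs(ann, heuristic_predictor)
        want = sorted(
            f"ORF_{r['chromosome']}_{r['start']}_{r['end']}_{r['strand']}"
            for r in manifest.records if r["is_ssp"]
        )
        assert sorted(c.protein_id for c in cands) == want
        assert tallies["Total"].after_er == len(want)

    def test_nested_pairs_resolve_to_longer(self, genome_seed11, heuristic_predictor):
        ann, manifest = genome_seed11
        _, _, orfs = mine_secreted_sorfs(ann, heuristic_predictor)
        ids = {o.orf_id for o in orfs}
        for r in manifest.records:
            if r["category"] != "nested":
                continue
            outer = f"ORF_{r['chromosome']}_{r['outer'][0]}_{r['outer'][1]}_{r['strand']}"
            inner = f"ORF_{r['chromosome']}_{r['inner'][0]}_{r['inner'][1]}_{r['strand']}"
            assert outer in ids and inner not in ids

    def test_cds_masked_cassettes_not_reported(self, genome_seed11, heuristic_predictor):
        ann, manifest = genome_seed11
        cands, _, orfs = mine_secreted_sorfs(ann, heuristic_predictor)
        cds_spans = {
            (r["chromosome"], r["start"], r["end"])
            for r in manifest.records if r["category"] == "cds"
        }
        assert cds_spans
        for o in orfs:
            assert (o.chromosome, o.start, o.end) not in cds_spans

    def test_fully_coding_genome_yields_nothing(self, heuristic_predictor):
        seq = "ATGGCTGCTTAA" * 20
        ann = GenomeAnnotation(
            sequences={"c": seq}, features=[("c", 1, len(seq), "+", "CDS", {})]
        )
        cands, tallies, orfs = mine_secreted_sorfs(ann, heuristic_predictor)
        assert cands == [] and orfs == []
        assert tallies["Total"].n_input == 0
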