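"""Zipcode scan, folding filter, search composition and synonymization."""

import numpy as np
import pytest

from budmrna.codons import codon_usage_frequency
from budmrna.transcript import Transcript, translate
from budmrna.zipcode import (
    FoldResult,
    ScanRules,
    SearchConfig,
    Stem,
    ZipCodeCandidate,
    filter_candidate,
    fold_window,
    scan_candidates,
    search_zipcodes,
    synonymize_zipcode,
)

from _oracles import brute_force_candidates

HAIRPIN = "GGGGCCCCAAAAGGGGCCCC"  # not a zipcode; used for folding checks only
PERFECT_HAIRPIN = "GCGCGCGCGCAAAAGCGCGCGCGC"  # 10 bp stem, 4 nt loop


def _signature(cand: ZipCodeCandidate):
    """0-based signature matching the brute-force oracle's output."""
    o, i = cand.outer, cand.inner
    return (
        (o.left_start - 1, o.left_end - 1),
        (o.right_start - 1, o.right_end - 1),
        (i.left_start - 1, i.left_end - 1),
        (i.right_start - 1, i.right_end - 1),
        (cand.cga_pos - 1, cand.lone_c_pos - 1),
    )


class TestScan:
    def test_minimal_element_has_exactly_one_candidate(self, minimal_zip):
        cands = scan_candidates(minimal_zip)
        assert len(cands) == 1
        cand = cands[0]
        # the element's extent is the 35-nt core of the printed 37-mer
        assert cand.span == (2, 36)
        assert abs(cand.bulge_left - cand.bulge_right) >= 1
        assert abs(cand.lone_c_pos - cand.cga_pos) == 6

    def test_homopolymer_yields_nothing(self):
        assert scan_candidates("A" * 80) == []

    def test_empty_sequence(self):
        assert scan_candidates("") == []

    def test_non_alphabet_characters_rejected(self):
        with pytest.raises(ValueError):
            Transcript("bad", "ACGTX" * 3, 1, 15)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_enumeration(self, seed, minimal_zip):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGU"), size=55))
        if seed == 0:
            seq = minimal_zip  # include the known positive
        got = {_signature(c) for c in scan_candidates(seq)}
        want = brute_force_candidates(seq)
        assert got == want

    def test_watson_crick_only_misses_wobble_stems(self, minimal_zip):
        # the minimal element's outer stem contains a G.U pair
        assert scan_candidates(minimal_zip, ScanRules(allow_gu=False)) == []

    def test_deterministic_order(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGU"), size=200))
        a = scan_candidates(seq)
        b = scan_candidates(seq)
        assert a == b
        spans = [c.span for c in a]
        assert spans == sorted(spans)


class TestFold:
    def test_homopolymer_folds_open(self):
        res = fold_window("A" * 100, center=50)
        assert set(res.structure) == {"."}
        assert res.dG == 0.0

    def test_agrees_with_engine_on_same_fragment(self):
        import RNA

        res = fold_window(PERFECT_HAIRPIN, center=12, width=len(PERFECT_HAIRPIN), temperature=28.0)
        md = RNA.md()
        md.temperature = 28.0
        ss, dg = RNA.fold_compound(PERFECT_HAIRPIN, md).mfe()
        assert res.structure == ss
        assert res.dG == pytest.approx(dg, abs=1e-6)
        # all ten stem pairs present
        assert res.structure.count("(") >= 10

    def test_constraint_already_in_mfe_costs_nothing(self):
        free = fold_window(PERFECT_HAIRPIN, center=12, width=30)
        stem_pairs = [(i, 25 - i) for i in range(1, 11)]  # 1-based hairpin pairs
        cons = fold_window(PERFECT_HAIRPIN, center=12, width=30, constraint=stem_pairs)
        assert cons.ok
        assert cons.dG == pytest.approx(free.dG, abs=1e-6)

    def test_window_clipped_not_shifted(self):
        res = fold_window("A" * 50, center=5, width=80)
        assert res.window == (1, 45)  # clipped at the left end only

    def test_temperature_changes_energy(self):
        cold = fold_window(PERFECT_HAIRPIN, center=12, width=30, temperature=10.0)
        hot = fold_window(PERFECT_HAIRPIN, center=12, width=30, temperature=60.0)
        assert cold.dG < hot.dG


class TestFilter:
    def _cand(self):
        return ZipCodeCandidate(
            outer=Stem(1, 4, 17, 20), inner=Stem(6, 9, 12, 15),
            bulge_left=1, bulge_right=0, cga_pos=5, lone_c_pos=11, span=(1, 20),
        )

    def _fold(self, dG, structure=None, constrained=False):
        return FoldResult((1, 20), structure or "." * 20, dG, constrained, 28.0)

    @pytest.mark.parametrize(
        "dg_free,dg_cons,expected",
        [(-10.0, -8.5, True), (-10.0, -7.9, False), (0.0, 0.0, True), (0.0, -1.0, False)],
    )
    def test_energy_tolerance(self, dg_free, dg_cons, expected):
        _, dg_ok = filter_candidate(self._cand(), self._fold(dg_free), self._fold(dg_cons, constrained=True))
        assert dg_ok is expected

    def test_one_stem_in_mfe_suffices(self):
        # structure containing the inner stem's pairs only
        structure = list("." * 20)
        for (i, j) in Stem(6, 9, 12, 15).base_pairs():
            structure[i - 1] = "("
            structure[j - 1] = ")"
        stem_ok, _ = filter_candidate(
            self._cand(), self._fold(-5.0, "".join(structure)), self._fold(-5.0, constrained=True)
        )
        assert stem_ok

    def test_no_stem_in_mfe_fails(self):
        stem_ok, _ = filter_candidate(
            self._cand(), self._fold(-5.0), self._fold(-5.0, constrained=True)
        )
        assert not stem_ok


class TestSearch:
    def test_single_hit_on_minimal_element(self, mini_transcript):
        hits = search_zipcodes(mini_transcript)
        assert len(hits) == 1
        hit = hits[0]
        assert hit.frame == "cds"
        assert hit.cds_span == (2, 36)
        assert hit.stem_in_mfe and hit.dG_ratio_ok

    def test_translation_equivariance(self, mini_transcript):
        offset = 9
        shifted = Transcript(
            "shifted", "N" * offset + mini_transcript.seq,
            mini_transcript.cds_start + offset, mini_transcript.cds_end + offset,
        )
        base = search_zipcodes(mini_transcript)
        moved = search_zipcodes(shifted)
        assert [(h.span[0] + offset, h.span[1] + offset) for h in base] == [h.span for h in moved]
        assert [h.cds_span for h in base] == [h.cds_span for h in moved]

    def test_spans_within_transcript_and_coords_consistent(self, mini_transcript):
        for hit in search_zipcodes(mini_transcript):
            s, e = hit.span
            assert 1 <= s <= e <= len(mini_transcript)
            if hit.cds_span:
                assert mini_transcript.from_cds_coords(hit.cds_span[0]) == s
                assert mini_transcript.from_cds_coords(hit.cds_span[1]) == e


class TestSynonymize:
    def test_no_hit_returns_unchanged(self):
        t = Transcript("plain", "ATG" + "GAA" * 20 + "TAA", 1, 66)
        res = synonymize_zipcode(t, None)
        assert res.n_changes == 0 and res.success
        assert res.mutant.seq == t.seq

    def test_round_trip_destroys_element(self, mini_transcript):
        hits = search_zipcodes(mini_transcript)
        res = synonymize_zipcode(mini_transcript, hits[0])
        assert res.success
        assert res.protein_identical
        assert res.residual_hits == 0
        assert res.n_changes >= 1
        s, e = hits[0].span
        after = [h for h in search_zipcodes(res.mutant) if h.span[0] <= e and h.span[1] >= s]
        assert after == []

    def test_changes_confined_to_element_codons(self, mini_transcript):
        hits = search_zipcodes(mini_transcript)
        res = synonymize_zipcode(mini_transcript, hits[0])
        s, e = hits[0].span
        cds0 = mini_transcript.cds_start
        lo = cds0 + 3 * ((s - cds0) // 3)
        hi = cds0 + 3 * ((e - cds0) // 3) + 2
        assert all(lo <= p <= hi for p in res.changed_positions)

    def test_protein_preserved_under_all_substitutions(self, mini_transcript):
        hits = search_zipcodes(mini_transcript)
        res = synonymize_zipcode(mini_transcript, hits[0])
        assert translate(res.mutant.cds) == translate(mini_transcript.cds)


class TestCodonUsage:
    def test_optimal_codons_score_one(self):
        # most-used yeast codons for M, K, E
        assert codon_usage_frequency("ATGAAAGAA") == pytest.approx(1.0)

    def test_single_codon_equals_its_weight(self):
        assert codon_usage_frequency("ATG") == pytest.approx(1.0)  # only Met codon

    def test_hand_built_table(self):
        # two-codon alphabet: GAA weight 1.0, GAG weight 20/40 = 0.5
        table = {"GAA": 40.0, "GAG": 20.0}
        cds = "GAA" * 6 + "GAG" * 4  # mean = (6*1.0 + 4*0.5) / 10 = 0.8
        assert codon_usage_frequency(cds, table) == pytest.approx(0.8)

    def test_internal_stop_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            val = codon_usage_frequency("ATGTAAATG")
        assert val == pytest.approx(1.0)
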