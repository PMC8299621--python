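import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cleavefeat.cleavage_scoring import OccupancyTable
from cleavefeat.feature_extraction import (
    FeatureConfig,
    FeatureSpec,
    build_feature_matrix,
    codon_aa_frequency,
    enumerate_feature_specs,
    enumerate_site_windows,
    evaluate_specs,
    fold_mfe,
    kmer_frequency,
    offset_to_slot,
    region_features,
    required_context,
    slot_to_offset,
    window_length,
    window_ro,
    window_transcript_span,
)
from cleavefeat.cleavage_scoring import CleavageSiteTable
from cleavefeat.transcript_io import Transcript

from conftest import make_transcript, sites_frame
from oracles import brute_force_fold, brute_force_window_slots


def to_slots(windows, max_offset):
    return {
        (offset_to_slot(a, max_offset), offset_to_slot(b, max_offset))
        for a, b in windows
    }


class TestWindows:
    def test_full_enumeration_count(self):
        wins = enumerate_site_windows(30, 1, 60, 1)
        assert len(wins) == 1830
        assert to_slots(wins, 30) == brute_force_window_slots(30, 1, 60, 1)

    def test_structure_mode_count(self):
        wins = enumerate_site_windows(30, 5, 60, 5)
        assert len(wins) == 78
        assert to_slots(wins, 30) == brute_force_window_slots(30, 5, 60, 5)

    def test_single_full_width_window(self):
        assert enumerate_site_windows(30, 60, 60, 1) == [(-30, 30)]

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            enumerate_site_windows(30, 0, 60, 1)
        with pytest.raises(ValueError):
            enumerate_site_windows(30, 61, 61, 1)
        with pytest.raises(ValueError):
            enumerate_site_windows(30, 10, 5, 1)

    def test_no_offset_zero(self):
        for a, b in enumerate_site_windows(5, 1, 10, 1):
            assert a != 0 and b != 0

    @given(st.integers(1, 50))
    def test_slot_offset_round_trip(self, m):
        for slot in range(2 * m):
            assert offset_to_slot(slot_to_offset(slot, m), m) == slot

    def test_window_length_skips_zero(self):
        assert window_length((-4, 2)) == 6
        assert window_length((1, 3)) == 3
        assert window_length((-3, -1)) == 3

    def test_transcript_span(self):
        # +1 nucleotide is the site position itself
        assert window_transcript_span((1, 1), 100) == (100, 101)
        assert window_transcript_span((-4, 2), 100) == (96, 102)
        assert window_transcript_span((-2, -1), 100) == (98, 100)


class TestFolding:
    def test_no_pairs_possible(self):
        assert fold_mfe("AAAA") == 0.0

    def test_hairpin(self):
        assert fold_mfe("GGGAAACCC") == -9.0
        assert brute_force_fold("GGGAAACCC") == -9.0

    def test_matches_brute_force_on_short_sequences(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 13))
            seq = "".join(rng.choice(list("ACGU"), size=n))
            assert fold_mfe(seq) == pytest.approx(brute_force_fold(seq))

    def test_numpy_and_jit_paths_agree(self, rng):
        from cleavefeat.feature_extraction.folding import (
            _NUMBA_MIN_LEN,
            _nussinov_numba,
        )

        if _nussinov_numba is None:
            pytest.skip("numba unavailable")
        seq = "".join(rng.choice(list("ACGU"), size=_NUMBA_MIN_LEN + 20))
        long_result = fold_mfe(seq)
        # force the numpy path via a distinct weights dict (cache-busting
        # values identical to the defaults)
        from cleavefeat.feature_extraction.folding import _nussinov_numpy, _pair_weight_matrix, _NT_INDEX
        W = _pair_weight_matrix({frozenset("GC"): -3.0, frozenset("AU"): -2.0, frozenset("GU"): -1.0})
        idx = np.fromiter((_NT_INDEX[c] for c in seq), dtype=np.intp)
        pw = W[idx[:, None], idx[None, :]]
        assert long_result == pytest.approx(_nussinov_numpy(idx, pw, 3))

    def test_never_positive(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGU"), size=int(rng.integers(1, 40))))
            assert fold_mfe(seq) <= 0.0

    def test_invalid_letters(self):
        with pytest.raises(ValueError):
            fold_mfe("ACGT")
        with pytest.raises(ValueError):
            fold_mfe("")

    def test_custom_backend_takes_precedence(self):
        assert fold_mfe("GGGAAACCC", backend=lambda s: -42.0) == -42.0


class TestKmerFrequency:
    def test_examples(self):
        assert kmer_frequency("GGAU", "G") == 0.5
        assert kmer_frequency("GGG", "GG") == 1.0
        assert kmer_frequency("AUGC", "GG") == 0.0

    def test_window_shorter_than_token(self):
        assert kmer_frequency("G", "GG") == 0.0

    def test_invalid_token(self):
        with pytest.raises(ValueError):
            kmer_frequency("ACGU", "GT")
        with pytest.raises(ValueError):
            kmer_frequency("ACGU", "")

    @given(st.text(alphabet="ACGU", min_size=1, max_size=30))
    def test_mononucleotide_frequencies_sum_to_one(self, seq):
        total = sum(kmer_frequency(seq, t) for t in "ACGU")
        assert total == pytest.approx(1.0)

    @given(
        st.text(alphabet="ACGU", min_size=1, max_size=30),
        st.sampled_from(["A", "G", "GG", "AU", "GCU"]),
    )
    def test_frequency_in_unit_interval(self, seq, token):
        assert 0.0 <= kmer_frequency(seq, token) <= 1.0


class TestCodonAaFrequency:
    def test_region_codon(self, toy_transcript):
        assert codon_aa_frequency(toy_transcript, "AUG", region="cds") == pytest.approx(1 / 3)

    def test_region_aa_excludes_stops(self, toy_transcript):
        # codons AUG GCU UAA -> aa M A * ; denominator excludes the stop
        assert codon_aa_frequency(toy_transcript, "M", region="cds") == pytest.approx(0.5)

    def test_stop_codon_counted_as_codon(self, toy_transcript):
        assert codon_aa_frequency(toy_transcript, "UAA", region="cds") == pytest.approx(1 / 3)

    def test_utr_site_has_no_codons(self, toy_transcript):
        # site at position 1 (5'UTR); window (-1, 1) spans [0, 2) < CDS start
        assert codon_aa_frequency(toy_transcript, "AUG", window=(-1, 1), site=1) == 0.0

    def test_around_site_in_frame_only(self, toy_transcript):
        # site at CDS start+3 = position 5; window (+1,+3) covers [5, 8) ->
        # codons GCU only (codon 1)
        assert codon_aa_frequency(toy_transcript, "GCU", window=(1, 3), site=5) == 1.0
        assert codon_aa_frequency(toy_transcript, "AUG", window=(1, 3), site=5) == 0.0

    def test_start_block_truncated(self, toy_transcript):
        # 3-codon CDS, 10-codon block -> all codons
        assert codon_aa_frequency(
            toy_transcript, "AUG", region="cds_start_codons", n_block=10
        ) == pytest.approx(1 / 3)


def occupancy_for(gene_id, ro, transcript):
    sites = pd.DataFrame(
        {
            "gene_id": gene_id,
            "position": list(ro),
            "ro_site": list(ro.values()),
        }
    )
    region_sums = pd.DataFrame(
        {
            "gene_id": [gene_id],
            "ro_5utr": [0.0],
            "ro_cds": [sum(ro.values())],
            "ro_3utr": [0.0],
            "ro_whole": [sum(ro.values())],
        }
    )
    return OccupancyTable(sites, region_sums)


class TestWindowRo:
    def test_mean_over_window(self, toy_transcript):
        # offsets +1, +2 at site 4 are transcript positions 4 and 5
        occ = occupancy_for("g1", {4: 0.1, 5: 0.3}, toy_transcript)
        assert window_ro(occ, "g1", 4, (1, 2), 13) == pytest.approx(0.2)

    def test_truncated_at_bounds(self, toy_transcript):
        occ = occupancy_for("g1", {12: 0.4}, toy_transcript)
        # window (+1,+5) at site 12 extends past length 13 -> only position 12
        assert window_ro(occ, "g1", 12, (1, 5), 13) == pytest.approx(0.4)

    def test_empty_occupancy_gives_zero(self, toy_transcript):
        occ = occupancy_for("g1", {}, toy_transcript)
        assert window_ro(occ, "g1", 5, (1, 3), 13) == 0.0


class TestRegionFeatures:
    def test_whole_kmer_frequency(self):
        t = make_transcript("g1", "GG", "AUGUAA", "CC")
        cfg = FeatureConfig.toy()
        vals = region_features(t, None, cfg)
        spec = FeatureSpec("nucleotide", "whole_rna", region="whole", token="G")
        assert vals[spec] == pytest.approx(kmer_frequency("GGAUGUAACC", "G"))

    def test_region_ro_sum_matches_occupancy_table(self, toy_transcript):
        occ = occupancy_for("g1", {4: 0.2, 7: 0.3}, toy_transcript)
        cfg = FeatureConfig.toy()
        vals = region_features(toy_transcript, occ, cfg)
        spec = FeatureSpec("occupancy", "whole_rna", region="whole")
        assert vals[spec] == pytest.approx(0.5)

    def test_empty_region_is_zero(self):
        t = Transcript("g1", "AUGUAAGG", 0, 6)  # no 5'UTR
        cfg = FeatureConfig.toy()
        vals = region_features(t, None, cfg)
        spec = FeatureSpec("nucleotide", "whole_rna", region="5utr", token="G")
        assert vals[spec] == 0.0


def toy_sites(gene_ids, position):
    rows = [(g, position, 5, 0.5) for g in gene_ids]
    return CleavageSiteTable(sites_frame(rows))


class TestBuildFeatureMatrix:
    def _transcript(self, gid="g1"):
        cds = "AUG" + "GCUGAAGGUCCAUUC" * 6 + "UAA"
        return make_transcript(gid, "AUCG" * 10, cds, "GCAU" * 10)

    def test_site_without_context_excluded(self):
        t = self._transcript()
        cfg = FeatureConfig.toy(seq_max_offset=30, seq_max_len=8, sequence_only=True)
        cs = toy_sites(["g1"], 10)  # needs 30 nt upstream
        fm = build_feature_matrix(cs, {"g1": t}, None, cfg)
        assert fm.n_sites == 0

    def test_identical_transcripts_identical_rows(self):
        t1, t2 = self._transcript("g1"), self._transcript("g2")
        cfg = FeatureConfig.toy(sequence_only=True)
        cs = toy_sites(["g1", "g2"], 50)
        fm = build_feature_matrix(cs, {"g1": t1, "g2": t2}, None, cfg)
        np.testing.assert_array_equal(fm.X[0], fm.X[1])

    def test_column_count_matches_hand_enumeration(self):
        cfg = FeatureConfig(
            seq_max_offset=3,
            seq_min_len=1,
            seq_max_len=6,
            seq_step=1,
            nt_k=(1,),
            include_codon_around=False,
            include_aa_around=False,
            include_structure=False,
            include_occupancy=False,
            region_nt_k=(1,),
            include_region_structure=False,
            include_region_occupancy=False,
            include_region_codon=False,
        )
        specs = enumerate_feature_specs(cfg)
        # windows in +/-3, lengths 1..6: sum_{L=1..6}(7-L) = 6+5+4+3+2+1 = 21
        # nucleotide tokens: 4 -> 84 around-site
        # regions: 4 base regions x 3 (full/end5/end3) x 4 tokens = 48
        assert len(specs) == 84 + 48

    def test_values_match_scalar_operations(self):
        t = self._transcript()
        occ = occupancy_for("g1", {50: 0.2, 52: 0.4, 60: 0.1}, t)
        cfg = FeatureConfig.toy()
        cs = toy_sites(["g1"], 50)
        fm = build_feature_matrix(cs, {"g1": t}, occ, cfg)
        row = fm.X[0]
        for j, spec in enumerate(fm.specs):
            if spec.scope != "around_site":
                continue
            a, b = window_transcript_span(spec.window, 50)
            if spec.category == "nucleotide":
                assert row[j] == pytest.approx(kmer_frequency(t.seq[a:b], spec.token))
            elif spec.category == "structure":
                assert row[j] == pytest.approx(fold_mfe(t.seq[a:b]))
            elif spec.category == "occupancy":
                assert row[j] == pytest.approx(
                    window_ro(occ, "g1", 50, spec.window, t.length)
                )

    def test_pure_function_of_inputs(self):
        t = self._transcript()
        cfg = FeatureConfig.toy(sequence_only=True)
        cs = toy_sites(["g1"], 50)
        a = build_feature_matrix(cs, {"g1": t}, None, cfg)
        b = build_feature_matrix(cs, {"g1": t}, None, cfg)
        np.testing.assert_array_equal(a.X, b.X)

    def test_all_frequencies_in_unit_interval(self):
        t = self._transcript()
        cfg = FeatureConfig.toy(sequence_only=True)
        cs = toy_sites(["g1"], 50)
        fm = build_feature_matrix(cs, {"g1": t}, None, cfg)
        for j, spec in enumerate(fm.specs):
            if spec.category in ("nucleotide", "codon", "amino_acid"):
                assert 0.0 <= fm.X[0, j] <= 1.0

    def test_required_context(self):
        specs = [
            FeatureSpec("nucleotide", "around_site", window=(-7, -5), token="A"),
            FeatureSpec("occupancy", "around_site", window=(-200, 200)),
            FeatureSpec("structure", "whole_rna", region="cds"),
        ]
        # occupancy windows are truncated, not dropped: they impose no context
        assert required_context(specs) == 7


class TestFeatureSpec:
    def test_name_format(self):
        s = FeatureSpec("nucleotide", "around_site", window=(-4, 2), token="G")
        assert s.name == "nucleotide|around_site|-4..+2|G"

    def test_header_round_trip(self):
        for s in [
            FeatureSpec("nucleotide", "around_site", window=(-4, 2), token="GG"),
            FeatureSpec("amino_acid", "whole_rna", region="cds_start_codons", token="M"),
            FeatureSpec("structure", "whole_rna", region="3utr"),
        ]:
            assert FeatureSpec.from_header_line(s.to_header_line()) == s

    def test_token_alphabet_enforced(self):
        with pytest.raises(ValueError):
            FeatureSpec("nucleotide", "around_site", window=(1, 1), token="T")
        with pytest.raises(ValueError):
            FeatureSpec("codon", "whole_rna", region="cds", token="AU")
        with pytest.raises(ValueError):
            FeatureSpec("structure", "whole_rna", region="cds", token="G")

    def test_deterministic_spec_order(self):
        cfg = FeatureConfig.toy()
        a = [s.name for s in enumerate_feature_specs(cfg)]
        b = [s.name for s in enumerate_feature_specs(cfg)]
        assert a == b
        assert len(set(a)) == len(a)
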