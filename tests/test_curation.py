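"""Quality filtering, clustering, epitope annotation and ID scoring."""

import itertools

import numpy as np
import pytest

from bidkit import curation
from bidkit.curation import (
    AntigenCluster,
    ClusterAlignment,
    QualityFilterConfig,
    annotate_epitopes,
    build_cluster_alignment,
    center_star_msa,
    cluster_antigens,
    compute_id_profile,
    quality_filter,
    sequence_identity,
    split_dataset,
)
from bidkit.errors import AnnotationError, ConsistencyError, SplitError
from bidkit.io_formats import AlignedSequence, IDProfile

from conftest import make_two_chain_complex


def far_apart_complex(**kw):
    ag = [[i * 4.0, 0, 0] for i in range(60)]
    ab = [[0, 100.0, 0]]
    return make_two_chain_complex(ag, ab, **kw)


class TestQualityFilter:
    def test_resolution_above_cutoff_excluded(self):
        rec = far_apart_complex(resolution=3.2, complex_id="bad_res")
        assert quality_filter([rec]) == []

    def test_all_thresholds_satisfied_retained(self):
        rec = far_apart_complex(resolution=2.0, r_factor=0.20, complex_id="good")
        ag = [[i * 4.0, 0, 0] for i in range(120)]
        rec = make_two_chain_complex(ag, [[0, 100.0, 0]], resolution=2.0,
                                     r_factor=0.20, complex_id="good")
        assert [r.complex_id for r in quality_filter([rec])] == ["good"]

    def test_identical_antibodies_keep_exactly_one(self):
        a = far_apart_complex(resolution=2.5, complex_id="dup_a")
        b = far_apart_complex(resolution=2.0, complex_id="dup_b")
        kept = quality_filter([a, b])
        assert len(kept) == 1
        assert kept[0].complex_id == "dup_b"  # better resolution wins

    def test_r_factor_and_short_antigen_excluded(self):
        high_r = far_apart_complex(r_factor=0.30, complex_id="r")
        short = make_two_chain_complex([[i * 4.0, 0, 0] for i in range(10)],
                                       [[0, 100.0, 0]], complex_id="s")
        missing = far_apart_complex(resolution=None, complex_id="m")
        assert quality_filter([high_r, short, missing]) == []

    def test_config_validation(self):
        with pytest.raises(ValueError):
            QualityFilterConfig(max_resolution=-1.0)
        with pytest.raises(ValueError):
            QualityFilterConfig(max_antibody_identity=1.5)


class TestClustering:
    def test_identity_of_identical_sequences(self):
        assert sequence_identity("ACDEFGHIKL", "ACDEFGHIKL") == 1.0

    def test_four_identical_sequences_form_one_cluster(self):
        seqs = [(f"s{i}", "ACDEFGHIKLMNPQRSTVWY" * 3) for i in range(4)]
        clusters = cluster_antigens(seqs)
        assert len(clusters) == 1
        assert sorted(clusters[0].member_ids) == ["s0", "s1", "s2", "s3"]

    def test_three_members_discarded_by_minimum_size(self):
        seqs = [(f"s{i}", "ACDEFGHIKLMNPQRSTVWY" * 3) for i in range(3)]
        assert cluster_antigens(seqs) == []

    def test_two_unrelated_families_split_into_two_clusters(self):
        rng = np.random.default_rng(3)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        seq_a = "".join(rng.choice(list(aa), 60))
        seq_b = "".join(rng.choice(list(aa), 60))
        assert sequence_identity(seq_a, seq_b) < 0.70
        seqs = [(f"a{i}", seq_a) for i in range(4)] + [(f"b{i}", seq_b) for i in range(4)]
        clusters = cluster_antigens(seqs)
        assert len(clusters) == 2
        # brute-force all-pairs identity confirms the partition
        for cl in clusters:
            for x, y in itertools.combinations(cl.member_ids, 2):
                sx = seq_a if x.startswith("a") else seq_b
                sy = seq_a if y.startswith("a") else seq_b
                assert sequence_identity(sx, sy) >= 0.70

    def test_empty_input_gives_empty_result(self):
        assert cluster_antigens([]) == []

    def test_representative_must_be_member(self):
        with pytest.raises(ConsistencyError):
            AntigenCluster(cluster_id="c", member_ids=["a"], representative_id="z")


class TestAnnotateEpitopes:
    @pytest.mark.parametrize("dist,expected", [(5.9, True), (6.0, True), (6.1, False)])
    def test_cutoff_boundary_is_closed(self, dist, expected):
        ag = [[0.0, 0, 0], [50.0, 0, 0]]
        ab = [[dist, 0.0, 0.0]]
        rec = make_two_chain_complex(ag, ab)
        mask = annotate_epitopes(rec)["A"]
        assert mask[0] == expected
        assert not mask[1]

    def test_chain_without_coordinates_rejected(self):
        rec = make_two_chain_complex([[0, 0, 0]], [[3, 0, 0]])
        object.__setattr__(rec.chains[1], "atom_coords", np.zeros((0, 3)))
        with pytest.raises(AnnotationError):
            annotate_epitopes(rec)

    def test_matches_brute_force_on_random_fixtures(self):
        from bidkit.benchmarks import _random_complex, brute_force_epitopes

        rng = np.random.default_rng(7)
        for _ in range(25):
            rec = _random_complex(rng)
            fast = annotate_epitopes(rec)
            slow = brute_force_epitopes(rec)
            for cid in fast:
                np.testing.assert_array_equal(fast[cid], slow[cid])


class TestCenterStar:
    def test_equal_length_mutants_align_gapless(self):
        rows = center_star_msa(("r", "ACDEFG"), [("m1", "ACDEFG"), ("m2", "ACDKFG")])
        assert [r.gapped_sequence for r in rows] == ["ACDEFG", "ACDEFG", "ACDKFG"]

    def test_insertion_in_member_creates_gap_in_center(self):
        rows = center_star_msa(("r", "ACDEFGHIKLMNP"), [("m", "ACDEFGWWHIKLMNP")])
        by_id = {r.seq_id: r for r in rows}
        assert by_id["r"].ungapped == "ACDEFGHIKLMNP"
        assert by_id["m"].ungapped == "ACDEFGWWHIKLMNP"
        assert len(by_id["r"].gapped_sequence) == len(by_id["m"].gapped_sequence)
        assert "-" in by_id["r"].gapped_sequence

    def test_deletion_in_member_creates_gap_in_member(self):
        rows = center_star_msa(("r", "ACDEFGHIKLMNP"), [("m", "ACDEFGKLMNP")])
        by_id = {r.seq_id: r for r in rows}
        assert "-" in by_id["m"].gapped_sequence
        assert by_id["m"].ungapped == "ACDEFGKLMNP"


class TestBuildClusterAlignment:
    def _cluster(self, members):
        return AntigenCluster(cluster_id="c", member_ids=members,
                              representative_id=members[0], min_members=1)

    def test_masks_attached_by_nongap_walk(self):
        rows = [AlignedSequence("a", "AC-DE"), AlignedSequence("b", "ACFDE")]
        masks = {"a": np.array([1, 0, 1, 0], bool), "b": np.zeros(5, bool)}
        aln = build_cluster_alignment(self._cluster(["a", "b"]), rows, masks)
        np.testing.assert_array_equal(aln.rows[0].column_flags(),
                                      [True, False, False, True, False])

    def test_all_zero_masks_valid(self):
        rows = [AlignedSequence(f"s{i}", "ACDE") for i in range(4)]
        masks = {f"s{i}": np.zeros(4, bool) for i in range(4)}
        aln = build_cluster_alignment(self._cluster([f"s{i}" for i in range(4)]),
                                      rows, masks)
        assert compute_id_profile(aln).scores.max() == 0.0

    def test_mask_length_mismatch_rejected(self):
        rows = [AlignedSequence("a", "ACDE")]
        with pytest.raises(ConsistencyError):
            build_cluster_alignment(self._cluster(["a"]), rows,
                                    {"a": np.zeros(3, bool)})

    def test_missing_member_row_rejected(self):
        rows = [AlignedSequence("a", "ACDE")]
        with pytest.raises(ConsistencyError):
            build_cluster_alignment(self._cluster(["a", "zz"]), rows,
                                    {"a": np.zeros(4, bool), "zz": np.zeros(4, bool)})


def alignment_from_flags(flag_matrix, rep_row=0):
    """Rows of identical sequence 'AAAA...' with given epitope flags."""
    n_rows, n_cols = flag_matrix.shape
    rows = [AlignedSequence(f"s{i}", "A" * n_cols,
                            epitope_mask=flag_matrix[i].astype(bool))
            for i in range(n_rows)]
    return ClusterAlignment(cluster_id="c", rows=rows, representative_row=rep_row)


class TestComputeIDProfile:
    def test_printed_formula_fraction(self):
        flags = np.zeros((10, 5), dtype=bool)
        flags[:4, 2] = True  # 4 of 10 rows flag column 2
        profile = compute_id_profile(alignment_from_flags(flags))
        assert profile.scores[2] == pytest.approx(0.4)
        assert profile.msa_depth == 10

    def test_score_bounds(self):
        flags = np.zeros((5, 3), dtype=bool)
        flags[:, 1] = True
        profile = compute_id_profile(alignment_from_flags(flags))
        assert profile.scores[0] == 0.0
        assert profile.scores[1] == 1.0

    def test_representative_gap_columns_dropped(self):
        rows = [AlignedSequence("rep", "A-CD", epitope_mask=np.array([0, 1, 1], bool)),
                AlignedSequence("m", "ABCD", epitope_mask=np.array([0, 1, 1, 0], bool))]
        aln = ClusterAlignment(cluster_id="c", rows=rows, representative_row=0)
        profile = compute_id_profile(aln)
        assert len(profile) == 3
        np.testing.assert_allclose(profile.scores, [0.0, 1.0, 0.5])

    def test_denominator_mode_nongap(self):
        rows = [AlignedSequence("rep", "AC", epitope_mask=np.array([1, 0], bool)),
                AlignedSequence("m1", "A-", epitope_mask=np.array([1], bool)),
                AlignedSequence("m2", "-C", epitope_mask=np.array([0], bool))]
        aln = ClusterAlignment(cluster_id="c", rows=rows, representative_row=0)
        total = compute_id_profile(aln, denominator="total_rows")
        nongap = compute_id_profile(aln, denominator="nongap_rows")
        np.testing.assert_allclose(total.scores, [2 / 3, 0.0])
        np.testing.assert_allclose(nongap.scores, [1.0, 0.0])

    def test_conservation_identity_counts_times_depth(self):
        rng = np.random.default_rng(1)
        flags = rng.random((8, 20)) < 0.3
        profile = compute_id_profile(alignment_from_flags(flags))
        total_from_scores = profile.scores.sum() * profile.msa_depth
        assert total_from_scores == pytest.approx(flags.sum())
        assert profile.epitope_counts.sum() == flags.sum()

    def test_invariant_under_row_permutation(self):
        rng = np.random.default_rng(2)
        flags = rng.random((6, 12)) < 0.4
        base = compute_id_profile(alignment_from_flags(flags, rep_row=0))
        perm = rng.permutation(6)
        rep_new = int(np.flatnonzero(perm == 0)[0])
        permuted = compute_id_profile(alignment_from_flags(flags[perm], rep_row=rep_new))
        np.testing.assert_array_equal(base.scores, permuted.scores)

    def test_adding_a_flag_is_monotone_and_local(self):
        rng = np.random.default_rng(3)
        flags = rng.random((6, 12)) < 0.3
        i, j = 4, 7
        flags[i, j] = False
        before = compute_id_profile(alignment_from_flags(flags))
        flags[i, j] = True
        after = compute_id_profile(alignment_from_flags(flags))
        assert after.scores[j] > before.scores[j]
        others = np.arange(12) != j
        np.testing.assert_array_equal(after.scores[others], before.scores[others])


class TestSplitDataset:
    def _profile(self, depth, name="p"):
        return IDProfile(antigen_id=f"{name}{depth}", scores=np.array([0.1]),
                         msa_depth=depth)

    def test_depth_rule(self):
        profiles = [self._profile(12), self._profile(9), self._profile(4)]
        split = split_dataset(profiles)
        assert split.test_ids == {"p12"}
        assert split.train_ids == {"p9", "p4"}

    def test_depth_exactly_ten_is_test(self):
        split = split_dataset([self._profile(10)])
        assert split.test_ids == {"p10"}

    def test_depth_below_cluster_minimum_rejected(self):
        with pytest.raises(SplitError):
            split_dataset([self._profile(3)])
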