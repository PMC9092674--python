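import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from scdnasim.cnv import (
    assign_clusters,
    build_matrix,
    draw_clone_profiles,
    draw_segments,
    inject_noise,
    make_bins,
    write_cnv_outputs,
)


def rng(seed=0):
    return np.random.default_rng(seed)


class TestBins:
    def test_exact_division(self):
        bs = make_bins({"c1": 2_000_000}, 500_000)
        assert len(bs) == 4
        assert bs.bins[-1].end == 2_000_000

    def test_remainder_bin_is_shorter(self):
        bs = make_bins({"c1": 2_300_000}, 500_000)
        assert len(bs) == 5
        last = bs.bins[-1]
        assert last.end - last.start + 1 == 300_000

    def test_chr22_at_500kb_gives_103_bins(self):
        bs = make_bins({"chr22": 51_304_566}, 500_000)
        assert len(bs) == 103

    def test_bins_tile_contig_without_gaps(self):
        bs = make_bins({"c1": 1_234_567}, 100_000)
        prev_end = 0
        for b in bs.bins:
            assert b.start == prev_end + 1
            prev_end = b.end
        assert prev_end == 1_234_567

    def test_labels_and_contig_slice(self):
        bs = make_bins({"c1": 1_000_000, "c2": 600_000}, 500_000)
        assert bs.labels[0] == "c1:1-500000"
        assert bs.contig_slice("c2") == slice(2, 4)


class TestSegments:
    @pytest.mark.parametrize("seg_no, n_bp", [(5, 4), (10, 9), (7, 6), (1, 0)])
    def test_breakpoint_count_is_seg_no_minus_one(self, seg_no, n_bp):
        bs = make_bins({"chr22": 51_304_566}, 500_000)
        seg = draw_segments(bs, seg_no, rng(1))
        assert len(seg.breakpoints()) == n_bp
        assert seg.n_segments == seg_no

    def test_breakpoint_coordinates_are_bin_len_multiples(self):
        bs = make_bins({"chr22": 51_304_566}, 500_000)
        seg = draw_segments(bs, 10, rng(2))
        for _, pos in seg.breakpoints():
            assert pos % 500_000 == 0

    def test_terminal_short_bin_end_is_never_a_breakpoint(self):
        bs = make_bins({"c1": 2_300_000}, 500_000)
        for s in range(20):
            seg = draw_segments(bs, 5, rng(s))
            assert all(pos != 2_300_000 for _, pos in seg.breakpoints())

    def test_segments_partition_the_bin_range(self):
        bs = make_bins({"c1": 5_000_000}, 500_000)
        seg = draw_segments(bs, 4, rng(3))
        covered = []
        for _, lo, hi in seg.segments():
            covered.extend(range(lo, hi + 1))
        assert covered == list(range(10))

    def test_seg_no_exceeding_bins_raises(self):
        bs = make_bins({"c1": 1_000_000}, 500_000)
        with pytest.raises(ValueError, match="seg_no"):
            draw_segments(bs, 3, rng(0))

    def test_per_contig_independent_draws(self):
        bs = make_bins({"c1": 5_000_000, "c2": 5_000_000}, 500_000)
        seg = draw_segments(bs, 3, rng(4))
        assert len(seg.boundaries["c1"]) == 2
        assert len(seg.boundaries["c2"]) == 2
        assert len(seg.breakpoints()) == 4


class TestClusters:
    def test_twenty_normal_cells_and_seven_nonempty_clones(self):
        labels = assign_clusters(100, 7, 0.2, rng(5))
        counts = Counter(labels)
        assert counts["normal"] == 20
        assert all(counts[f"clone{k}"] >= 1 for k in range(1, 8))
        assert sum(counts.values()) == 100

    def test_four_clones_give_five_distinct_subpopulations(self):
        labels = assign_clusters(100, 4, 0.2, rng(6))
        assert len(set(labels)) == 5

    def test_single_clone_no_normals(self):
        assert assign_clusters(10, 1, 0.0, rng(7)) == ["clone1"] * 10

    def test_zero_clusters_means_all_normal(self):
        assert assign_clusters(10, 0, 0.2, rng(8)) == ["normal"] * 10

    def test_normal_cells_are_the_first_indices(self):
        labels = assign_clusters(10, 2, 0.3, rng(9))
        assert labels[:3] == ["normal"] * 3
        assert "normal" not in labels[3:]

    def test_infeasible_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            assign_clusters(10, 8, 0.4, rng(0))


class TestCloneProfiles:
    def test_no_neutral_states_when_p_neutral_zero(self):
        bs = make_bins({"c1": 500_000}, 500_000)
        seg = draw_segments(bs, 1, rng(1))
        for s in range(30):
            profs = draw_clone_profiles(seg, 1, 8, 0.0, rng(s))
            assert profs["clone1"][0] in {0, 1, 3, 4, 5, 6, 7, 8}

    def test_profiles_distinct_and_each_has_an_aberration(self):
        bs = make_bins({"c1": 5_000_000}, 500_000)
        seg = draw_segments(bs, 7, rng(2))
        profs = draw_clone_profiles(seg, 2, 8, 0.5, rng(3))
        a, b = profs["clone1"], profs["clone2"]
        assert len(a) == 7 and len(b) == 7
        assert (a != 2).any() and (b != 2).any()
        assert not np.array_equal(a, b)

    def test_aberrant_states_uniform(self):
        bs = make_bins({"c1": 10_000}, 1)
        seg = draw_segments(bs, 10_000, rng(4))
        profs = draw_clone_profiles(seg, 1, 8, 0.0, rng(5))
        values = profs["clone1"]
        n = len(values)
        tol = 3 * math.sqrt((1 / 8) * (7 / 8) / n)
        for state in (0, 1, 3, 4, 5, 6, 7, 8):
            assert abs((values == state).mean() - 1 / 8) <= tol

    def test_impossible_distinct_profiles_raise(self):
        bs = make_bins({"c1": 500_000}, 500_000)
        seg = draw_segments(bs, 1, rng(6))
        with pytest.raises(RuntimeError):
            # only 8 aberrant single-segment profiles exist
            draw_clone_profiles(seg, 9, 8, 0.0, rng(7))


class TestMatrix:
    @pytest.fixture()
    def setup(self):
        bs = make_bins({"chr22": 51_304_566}, 500_000)
        seg = draw_segments(bs, 5, rng(10))
        labels = assign_clusters(100, 7, 0.2, rng(11))
        profs = draw_clone_profiles(seg, 7, 8, 0.5, rng(12))
        matrix = build_matrix(labels, profs, seg, bs)
        return bs, seg, labels, profs, matrix

    def test_shape_is_cells_by_bins(self, setup):
        _, _, _, _, matrix = setup
        assert matrix.clean.shape == (100, 103)

    def test_normal_rows_are_all_two(self, setup):
        _, _, labels, _, matrix = setup
        for i, label in enumerate(labels):
            if label == "normal":
                assert (matrix.clean[i] == 2).all()
            else:
                assert (matrix.clean[i] != 2).any()

    def test_same_subpopulation_rows_identical_and_distinct_across(self, setup):
        _, _, labels, _, matrix = setup
        rows_by_label = {}
        for i, label in enumerate(labels):
            rows_by_label.setdefault(label, []).append(matrix.clean[i])
        reps = {k: v[0] for k, v in rows_by_label.items()}
        for label, vecs in rows_by_label.items():
            for v in vecs:
                assert np.array_equal(v, reps[label])
        labels_list = list(reps)
        for i in range(len(labels_list)):
            for j in range(i + 1, len(labels_list)):
                assert not np.array_equal(reps[labels_list[i]], reps[labels_list[j]])

    def test_clean_entries_constant_within_segment_blocks(self, setup):
        bs, seg, labels, profs, matrix = setup
        for chrom, lo, hi in seg.segments():
            sl = bs.contig_slice(chrom)
            block = matrix.clean[:, sl.start + lo : sl.start + hi + 1]
            assert (block == block[:, [0]]).all()

    def test_all_normal_assignment_gives_all_two_matrix(self):
        bs = make_bins({"c1": 2_000_000}, 500_000)
        seg = draw_segments(bs, 2, rng(13))
        matrix = build_matrix(["normal"] * 5, {}, seg, bs)
        assert (matrix.clean == 2).all()


class TestNoise:
    def test_zero_noise_leaves_matrix_unchanged(self):
        bs = make_bins({"c1": 2_000_000}, 500_000)
        seg = draw_segments(bs, 2, rng(1))
        m = build_matrix(["normal"] * 5, {}, seg, bs)
        inject_noise(m, 0.0, 8, rng(2))
        assert np.array_equal(m.noisy, m.clean)

    def test_full_noise_on_diploid_matrix_forces_one_or_three(self):
        bs = make_bins({"c1": 2_000_000}, 500_000)
        seg = draw_segments(bs, 2, rng(3))
        m = build_matrix(["normal"] * 5, {}, seg, bs)
        inject_noise(m, 1.0, 8, rng(4))
        assert set(np.unique(m.noisy)) == {1, 3}
        assert (m.clean == 2).all()  # clean untouched

    def test_boundary_values_stay_in_range(self):
        bs = make_bins({"c1": 500_000}, 500_000)
        seg = draw_segments(bs, 1, rng(5))
        m = build_matrix(
            ["clone1"] * 50 + ["clone2"] * 50,
            {"clone1": np.array([0]), "clone2": np.array([8])},
            seg,
            bs,
        )
        inject_noise(m, 1.0, 8, rng(6))
        assert (m.noisy[:50] == 1).all()  # 0 can only move up
        assert (m.noisy[50:] == 7).all()  # max_cn can only move down

    @pytest.mark.parametrize("rate", [0.10, 0.12])
    def test_perturbed_fraction_within_binomial_band(self, rate):
        bs = make_bins({"chr22": 51_304_566}, 500_000)
        seg = draw_segments(bs, 5, rng(7))
        m = build_matrix(["normal"] * 100, {}, seg, bs)
        inject_noise(m, rate, 8, rng(int(rate * 100)))
        n = m.clean.size
        changed = int((m.noisy != m.clean).sum())
        assert abs(changed - n * rate) <= 3 * math.sqrt(n * rate * (1 - rate))


class TestOutputs:
    def test_file_contents_and_round_trip(self, tmp_path):
        bs = make_bins({"chr22": 51_304_566}, 500_000)
        seg = draw_segments(bs, 7, rng(20))
        labels = assign_clusters(20, 3, 0.2, rng(21))
        profs = draw_clone_profiles(seg, 3, 8, 0.5, rng(22))
        m = build_matrix(labels, profs, seg, bs)
        inject_noise(m, 0.1, 8, rng(23))
        paths = write_cnv_outputs(m, labels, seg, bs, tmp_path)
        assert len(paths["breakpoints.tsv"].read_text().splitlines()) == 7  # header + 6
        assert len(paths["segments.bed"].read_text().splitlines()) == 7
        back = pd.read_csv(paths["cnv_matrix_clean.csv"], index_col=0)
        assert np.array_equal(back.to_numpy(), m.clean)
        assert list(back.columns) == m.bin_labels
        clusters = pd.read_csv(paths["clusters.csv"])
        assert list(clusters["label"]) == labels

    def test_breakpoint_coordinate_is_end_of_upstream_segment(self, tmp_path):
        bs = make_bins({"chr22": 51_304_566}, 500_000)
        seg = draw_segments(bs, 2, rng(0))
        # force the boundary after the 59th bin: segment bins 0..58
        seg.boundaries["chr22"] = (59,)
        m = build_matrix(["normal"] * 2, {}, seg, bs)
        inject_noise(m, 0.0, 8, rng(1))
        paths = write_cnv_outputs(m, ["normal"] * 2, seg, bs, tmp_path)
        bp_lines = paths["breakpoints.tsv"].read_text().splitlines()
        assert bp_lines[1] == "chr22\t29500000"
        bed_lines = paths["segments.bed"].read_text().splitlines()
        assert bed_lines[0] == "chr22\t0\t29500000\tchr22:seg1"

    def test_breakpoints_reconstructible_from_bed(self, tmp_path):
        bs = make_bins({"c1": 5_000_000}, 500_000)
        seg = draw_segments(bs, 4, rng(2))
        m = build_matrix(["normal"] * 2, {}, seg, bs)
        inject_noise(m, 0.0, 8, rng(3))
        paths = write_cnv_outputs(m, ["normal"] * 2, seg, bs, tmp_path)
        bed_rows = [
            line.split("\t")
            for line in paths["segments.bed"].read_text().splitlines()
        ]
        interior_ends = [int(r[2]) for r in bed_rows[:-1]]
        assert interior_ends == [pos for _, pos in seg.breakpoints()]
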