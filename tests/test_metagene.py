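"""Profile matrices: strand orientation, averaging oracles, quintiles."""
import numpy as np
import pytest

from nucdyn.genomic_io import GeneModel, OccupancyTrack
from nucdyn.metagene import (
    build_profile_matrix, average_profile, scaled_gene_body_profile,
    exon_boundary_profiles, make_quintiles, tss_anchors, array_amplitude,
    DEFAULT_EXON_CLASSES,
)


def gaussian_track(length, centers, sd=25.0, height=1.0):
    x = np.arange(length, dtype=float)
    v = np.zeros(length)
    for c in centers:
        v += height * np.exp(-0.5 * ((x - c) / sd) ** 2)
    return OccupancyTrack({"c": v})


class TestBuildProfileMatrix:
    def test_constant_track_constant_cells(self):
        t = OccupancyTrack({"c": np.full(4000, 3.0)})
        m = build_profile_matrix(t, [("r", "c", 2000, "+")], (1000, 1000), 10)
        np.testing.assert_allclose(m.values, 3.0)

    def test_strand_mirror_rows_identical(self):
        """A plus anchor and a minus anchor over the mirror-image signal give
        identical rows."""
        v = np.concatenate([np.zeros(500), np.arange(100.0), np.zeros(500)])
        fwd = OccupancyTrack({"c": v})
        rev = OccupancyTrack({"c": v[::-1]})
        pos = 550
        m1 = build_profile_matrix(fwd, [("r", "c", pos, "+")], (200, 200), 10)
        m2 = build_profile_matrix(rev, [("r", "c", len(v) - 1 - pos, "-")],
                                  (200, 200), 10)
        np.testing.assert_allclose(m1.values, m2.values)

    def test_planted_dyad_argmax_bin(self):
        t = gaussian_track(4000, [2100])  # 100 bp downstream of the anchor
        m = build_profile_matrix(t, [("r", "c", 2000, "+")], (1000, 1000), 10)
        peak = m.bin_centers[np.nanargmax(m.values[0])]
        assert 95 <= peak <= 105

    def test_off_sequence_anchor_dropped(self):
        t = OccupancyTrack({"c": np.ones(100)})
        m = build_profile_matrix(t, [("bad", "c", 5000, "+"),
                                     ("ok", "c", 50, "+")], (20, 20), 10)
        assert m.row_ids == ["ok"]

    def test_edge_window_has_missing_bins(self):
        t = OccupancyTrack({"c": np.ones(100)})
        m = build_profile_matrix(t, [("r", "c", 5, "+")], (50, 50), 10)
        assert np.isnan(m.values[0][0])  # fully off-sequence bin
        assert m.values[0][-1] == 1.0

    def test_mass_bookkeeping(self, small_study):
        """Sum over bins x bin_size equals the raw signal sum over the
        window, for interior anchors on both strands."""
        _, _, genes, control, _, _ = small_study
        arr = control.values["chrS"]
        m = build_profile_matrix(control, tss_anchors(genes), (1000, 1000), 10)
        by_id = {g.gene_id: g for g in genes}
        for i, gid in enumerate(m.row_ids[:10]):
            g = by_id[gid]
            if g.strand == "+":
                raw = arr[g.tss - 1000:g.tss + 1000].sum()
            else:
                raw = arr[g.tss - 999:g.tss + 1001].sum()
            assert m.values[i].sum() * 10 == pytest.approx(raw, rel=1e-9)


class TestAverageProfile:
    def test_single_row_identity(self):
        t = gaussian_track(3000, [1500])
        m = build_profile_matrix(t, [("r", "c", 1400, "+")], (500, 500), 10)
        _, avg = average_profile(m)
        np.testing.assert_allclose(avg, m.values[0])

    def test_antiphase_cosines_cancel(self):
        x = np.arange(100)
        m = build_profile_matrix(
            OccupancyTrack({"c": 1 + 0.9 * np.cos(2 * np.pi * np.arange(4000) / 180)}),
            [("a", "c", 2000, "+")], (500, 500), 10)
        row_a = m.values[0]
        row_b = 2 * row_a.mean() - row_a  # exact antiphase partner
        import copy
        m2 = copy.deepcopy(m)
        m2.row_ids = ["a", "b"]
        m2.values = np.vstack([row_a, row_b])
        _, avg = average_profile(m2)
        assert np.ptp(avg) < 0.05 * np.ptp(row_a)

    def test_matches_brute_force_mean(self, rng):
        values = rng.normal(size=(100, 40))
        from nucdyn.metagene import ProfileMatrix
        m = ProfileMatrix([f"r{i}" for i in range(100)], "TSS", (200, 200),
                          10, values)
        _, avg = average_profile(m)
        np.testing.assert_allclose(avg, values.mean(axis=0))
        subset = [f"r{i}" for i in range(0, 100, 3)]
        _, avg_s = average_profile(m, subset)
        np.testing.assert_allclose(avg_s, values[::3].mean(axis=0))

    def test_empty_subset_rejected(self, small_study):
        _, _, genes, control, _, _ = small_study
        m = build_profile_matrix(control, tss_anchors(genes), (100, 100), 10)
        with pytest.raises(ValueError):
            average_profile(m, [])


class TestScaledGeneBody:
    def make_genes(self):
        return [GeneModel("g1", "c", "+", 3000, 4000, ((3000, 4000),)),
                GeneModel("g2", "c", "+", 6000, 8000, ((6000, 8000),))]

    def test_constant_track_flat(self):
        t = OccupancyTrack({"c": np.full(12000, 2.0)})
        prof = scaled_gene_body_profile(t, self.make_genes(), n_bins=50,
                                        flank=500, bin_size=10)
        np.testing.assert_allclose(prof, 2.0)

    def test_midpoint_dyads_align_at_center_bin(self):
        """Genes of lengths 1000 and 2000 with a dyad at their midpoints:
        the rescaled profile peaks at bin n_bins/2 (manual rescale oracle)."""
        t = gaussian_track(12000, [3500, 7000])
        n_bins, flank, b = 50, 500, 10
        prof = scaled_gene_body_profile(t, self.make_genes(), n_bins, flank, b)
        body = prof[flank // b: flank // b + n_bins]
        assert abs(int(np.argmax(body)) - n_bins // 2) <= 1

    def test_single_bin_equals_body_mean(self):
        t = gaussian_track(12000, [3500])
        g = self.make_genes()[0]
        prof = scaled_gene_body_profile(t, [g], n_bins=1, flank=100, bin_size=10)
        body_val = prof[10]
        assert body_val == pytest.approx(
            t.values["c"][g.start:g.end].mean(), rel=1e-6)


class TestExonBoundaryProfiles:
    def test_length_class_assignment(self):
        genes = [GeneModel("a", "c", "+", 1000, 1200, ((1000, 1200),)),   # 200
                 GeneModel("b", "c", "+", 3000, 3300, ((3000, 3300),))]   # 300
        t = OccupancyTrack({"c": np.ones(6000)})
        out = exon_boundary_profiles(t, genes, DEFAULT_EXON_CLASSES,
                                     window=(100, 200), bin_size=10)
        assert (170, 240) in out          # the 200-bp exon
        assert all(lo > 300 or hi < 300 for lo, hi in out)  # 300 in no class

    def test_planted_exon_nucleosome_peaks_inside_exon(self):
        g = GeneModel("a", "c", "+", 1000, 1200, ((1000, 1200),))
        t = gaussian_track(4000, [1100])  # dyad at exon center
        out = exon_boundary_profiles(t, [g], ((170, 240),), window=(100, 300),
                                     bin_size=10)
        centers, prof = out[(170, 240)]
        peak = centers[np.nanargmax(prof)]
        assert 0 <= peak <= 200

    def test_overlapping_classes_rejected(self):
        t = OccupancyTrack({"c": np.ones(100)})
        with pytest.raises(ValueError):
            exon_boundary_profiles(t, [], ((100, 200), (150, 250)))


class TestQuintiles:
    def test_ascending_direction(self):
        vals = {f"g{i}": float(i) for i in range(1, 11)}
        q = make_quintiles(vals, "ascending")
        assert sorted(q.members(1)) == ["g1", "g2"]
        assert sorted(q.members(5)) == ["g10", "g9"]

    def test_descending_direction(self):
        vals = {f"g{i}": float(i) for i in range(1, 11)}
        q = make_quintiles(vals, "descending")
        assert sorted(q.members(1)) == ["g10", "g9"]

    def test_ties_split_by_stable_order(self):
        vals = {f"g{i:02d}": 1.0 for i in range(10)}
        q = make_quintiles(vals, "ascending")
        sizes = [len(q.members(i)) for i in range(1, 6)]
        assert sizes == [2, 2, 2, 2, 2]
        assert q.assignment["g00"] == 1 and q.assignment["g09"] == 5

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            make_quintiles({"a": 1.0, "b": 2.0})

    def test_quintile_profiles_recover_planted_ordering(self, small_study):
        """Occupancy scaled inversely with GC quintile: profile levels must
        decrease monotonically from quintile 1 to 5."""
        _, genome, genes, control, _, _ = small_study
        from nucdyn.sequence_features import gc_window_content
        gc = {g.gene_id: gc_window_content(genome, g, "downstream", 1000)
              for g in genes}
        q = make_quintiles(gc, "ascending", "GC")
        arr = control.values["chrS"].copy()
        for g in genes:  # plant the coupling: scale each gene's window
            factor = (6 - q.assignment[g.gene_id]) / 3.0
            lo, hi = max(0, g.tss - 1100), min(len(arr), g.tss + 1100)
            arr[lo:hi] = arr[lo:hi] * factor
        coupled = OccupancyTrack({"chrS": arr})
        m = build_profile_matrix(coupled, tss_anchors(genes), (1000, 1000), 10)
        levels = []
        for i in range(1, 6):
            _, avg = average_profile(m, q.members(i))
            levels.append(np.nanmean(avg))
        assert all(a > b for a, b in zip(levels, levels[1:]))


class TestArrayAmplitude:
    def test_pure_cosine_amplitude(self):
        centers = np.arange(-500, 500, 10) + 5.0
        v = 1 + np.cos(2 * np.pi * centers / 180)
        amp = array_amplitude(centers, v, (-500, -50))
        assert amp == pytest.approx(2.0, rel=0.05)

    def test_flat_profile_zero(self):
        centers = np.arange(-500, 0, 10) + 5.0
        assert array_amplitude(centers, np.ones_like(centers), (-500, -50)) == 0.0
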