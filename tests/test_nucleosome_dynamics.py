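"""Caller, pairing and dynamic classification against construction oracles."""
import itertools

import numpy as np
import pytest
from scipy.stats import binom

from nucdyn.genomic_io import GeneModel, OccupancyTrack
from nucdyn.nucleosome_dynamics import (
    NucleosomeCall, call_nucleosomes, classify_dynamics, match_calls,
    region_rates, REGION_CLASSES,
)


def kernel_track(length, dyads, sd=25.0, mass=600.0, background=0.0):
    x = np.arange(length, dtype=float)
    v = np.full(length, background)
    for d, s, m in dyads:
        v += m * np.exp(-0.5 * ((x - d) / s) ** 2) / (s * np.sqrt(2 * np.pi))
    return OccupancyTrack({"c": v})


def call(dyad, mass_c, seq="c"):
    return NucleosomeCall(seq, dyad, 1.0, 20.0, (dyad - 75, dyad + 76), mass_c)


class TestCallNucleosomes:
    def test_flat_zero_track_empty(self):
        assert call_nucleosomes(OccupancyTrack({"c": np.zeros(1000)})) == []

    def test_single_planted_kernel(self):
        t = kernel_track(1000, [(500, 25.0, 600.0)])
        (c,) = call_nucleosomes(t)
        assert abs(c.dyad - 500) <= 2
        assert abs(c.fuzziness - 25) <= 2

    def test_two_dyads_300_apart(self):
        t = kernel_track(2000, [(600, 25.0, 600.0), (900, 25.0, 600.0)])
        calls = call_nucleosomes(t)
        assert len(calls) == 2
        assert abs(calls[0].dyad - 600) <= 2 and abs(calls[1].dyad - 900) <= 2

    def test_min_distance_constraint_enforced(self):
        with pytest.raises(ValueError):
            call_nucleosomes(OccupancyTrack({"c": np.ones(10)}),
                             smooth_sd=20, min_distance=30)

    def test_fuzziness_doubling_tracked_within_15pct(self):
        """Doubling the kernel SD of one planted nucleosome doubles its
        called fuzziness within 15% (base SD chosen well inside the
        footprint so truncation bias stays small)."""
        narrow = kernel_track(2000, [(1000, 15.0, 600.0)])
        wide = kernel_track(2000, [(1000, 30.0, 600.0)])
        (a,) = call_nucleosomes(narrow)
        (b,) = call_nucleosomes(wide)
        ratio = b.fuzziness / a.fuzziness
        assert 1.7 <= ratio <= 2.3


class TestMatchCalls:
    def test_identical_lists_pair_with_zero_shift(self):
        cs = [call(d, 100.0) for d in (200, 500, 800)]
        pairs, un_c, un_t = match_calls(cs, list(cs))
        assert len(pairs) == 3 and not un_c and not un_t
        assert all(c.dyad == t.dyad for c, t in pairs)

    def test_lone_control_is_loss(self):
        pairs, un_c, un_t = match_calls([call(500, 1.0)], [call(700, 1.0)])
        assert not pairs and len(un_c) == 1 and len(un_t) == 1

    def test_matches_brute_force_min_distance_matching(self, rng):
        """On well-spaced call sets (spacing >> max distance) the greedy
        mutual pairing equals exhaustive minimum-total-distance matching."""
        for _ in range(20):
            n_c, n_t = rng.integers(2, 6), rng.integers(2, 6)
            base = np.sort(rng.choice(np.arange(10, 5000, 400),
                                      size=max(n_c, n_t), replace=False))
            cs = [call(int(b), 1.0) for b in base[:n_c]]
            ts = [call(int(b + rng.integers(-90, 91)), 1.0) for b in base[:n_t]]
            pairs, _, _ = match_calls(cs, ts, 100)
            got = {(c.dyad, t.dyad) for c, t in pairs}

            # oracle: enumerate all pairings, maximise pairs then minimise
            # total distance
            best, best_key = None, None
            c_pos = [c.dyad for c in cs]
            t_pos = [t.dyad for t in ts]
            k = min(len(c_pos), len(t_pos))
            for size in range(k, -1, -1):
                for c_sub in itertools.combinations(range(len(c_pos)), size):
                    for t_perm in itertools.permutations(range(len(t_pos)), size):
                        if any(abs(c_pos[i] - t_pos[j]) > 100
                               for i, j in zip(c_sub, t_perm)):
                            continue
                        total = sum(abs(c_pos[i] - t_pos[j])
                                    for i, j in zip(c_sub, t_perm))
                        key = (-size, total)
                        if best_key is None or key < best_key:
                            best_key = key
                            best = {(c_pos[i], t_pos[j])
                                    for i, j in zip(c_sub, t_perm)}
                if best is not None:
                    break
            assert got == best


class TestClassifyDynamics:
    def tracks(self, length=2000):
        v = np.ones(length)
        t = OccupancyTrack({"c": v.copy()})
        return t, OccupancyTrack({"c": v.copy()})

    def run_single(self, delta, masses=(1000, 1000)):
        c = NucleosomeCall("c", 1000, 1.0, 20.0, (925, 1076), masses[0])
        t = NucleosomeCall("c", 1000 + delta, 1.0, 20.0,
                           (925 + delta, 1076 + delta), masses[1])
        tc, tt = self.tracks(3000)
        return classify_dynamics([(c, t)], [], [], tc, tt)[0]

    def test_delta_70_is_shift(self):
        d = self.run_single(70)
        assert "shift_5to3" in d.classes and d.shift_bp == 70

    def test_delta_30_is_not_shift(self):
        d = self.run_single(30)
        assert not any(c.startswith("shift") for c in d.classes)

    def test_boundaries_inclusive(self):
        assert any(c.startswith("shift") for c in self.run_single(50).classes)
        assert any(c.startswith("shift") for c in self.run_single(95).classes)
        assert not any(c.startswith("shift") for c in self.run_single(96).classes)

    def test_single_pair_binomial_oracle(self):
        """Masses 100 vs 200: p equals the exact two-sided Bin(300, 0.5)
        tail at 200, and the pair is occupancy_up at alpha=0.05."""
        d = self.run_single(0, masses=(100, 200))
        pmf_obs = binom.pmf(200, 300, 0.5)
        expected = binom.pmf(np.arange(301), 300, 0.5)
        p_oracle = expected[expected <= pmf_obs * (1 + 1e-10)].sum()
        assert d.p_occ == pytest.approx(p_oracle, rel=1e-6)
        assert "occupancy_up" in d.classes

    def test_direction_follows_gene_strand(self):
        gene = GeneModel("g", "c", "-", 200, 1800, ((200, 1800),))
        c = NucleosomeCall("c", 1000, 1.0, 20.0, (925, 1076), 500)
        t = NucleosomeCall("c", 1070, 1.0, 20.0, (995, 1146), 500)
        tc, tt = self.tracks(3000)
        (d,) = classify_dynamics([(c, t)], [], [], tc, tt, [gene])
        assert d.shift_bp == -70 and "shift_3to5" in d.classes
        assert not d.orientation_flagged

    def test_intergenic_direction_flagged(self):
        d = self.run_single(70)
        assert d.orientation_flagged

    def test_unmatched_become_gain_loss(self):
        tc, tt = self.tracks()
        out = classify_dynamics([], [call(500, 1.0)], [call(900, 1.0)], tc, tt)
        assert {d.classes[0] for d in out} == {"loss", "gain"}

    def test_planted_20bp_shifts_never_shift_classified(self):
        from nucdyn.synthetic_data import (SimulationConfig, simulate_genome,
                                           simulate_tracks)
        cfg = SimulationConfig(n_genes=40, seed=55, n_shift=40,
                               shift_range=(20, 20), poisson=False)
        _, genes, man = simulate_genome(cfg)
        control, treated, man = simulate_tracks(genes, cfg, man)
        calls_c = call_nucleosomes(control)
        calls_t = call_nucleosomes(treated)
        pairs, uc, ut = match_calls(calls_c, calls_t)
        dyn = classify_dynamics(pairs, uc, ut, control, treated, genes)
        assert not any(c.startswith("shift")
                       for d in dyn for c in d.classes)


class TestRegionRates:
    def setup_scene(self):
        gene = GeneModel("g", "c", "+", 2000, 5000,
                         ((2000, 3000), (4000, 5000)))
        lengths = {"c": 8000}
        return gene, lengths

    def test_partition_covers_genome(self):
        gene, lengths = self.setup_scene()
        df = region_rates([], [], [gene], lengths)
        assert df["region_bp"].sum() == 8000

    def test_promoter_bin_assignment(self):
        gene, lengths = self.setup_scene()
        calls = [call(1900, 1.0)]  # 100 bp upstream of the TSS
        df = region_rates([], calls, [gene], lengths)
        assert df.at["promoter_0_200", "nucleosome_count"] == 1

    def test_intron_assignment(self):
        gene, lengths = self.setup_scene()
        calls = [call(3500, 1.0)]
        df = region_rates([], calls, [gene], lengths)
        assert df.at["intron", "nucleosome_count"] == 1

    def test_counts_sum_to_totals(self, small_study):
        _, _, genes, control, treated, _ = small_study
        calls_c = call_nucleosomes(control)
        calls_t = call_nucleosomes(treated)
        pairs, uc, ut = match_calls(calls_c, calls_t)
        dyn = classify_dynamics(pairs, uc, ut, control, treated, genes)
        lengths = {s: len(v) for s, v in control.values.items()}
        df = region_rates(dyn, calls_c, genes, lengths)
        assert df["nucleosome_count"].sum() == len(calls_c)
        assert df["dynamic_count"].sum() == sum(1 for d in dyn if d.is_dynamic)

    def test_rate_formula(self):
        """10 dynamics in a 5-kb single-region genome with 50 nucleosomes:
        rate = 10 / 5 / 0.5 = 4.0."""
        lengths = {"c": 5000}
        calls = [call(i, 1.0) for i in range(50, 5000, 99)][:50]
        tc = OccupancyTrack({"c": np.ones(5000)})
        dyn = classify_dynamics(
            [], calls[:10], [], tc, tc)  # 10 losses = dynamic
        df = region_rates(dyn, calls, [], lengths)
        assert df.at["intergenic", "rate"] == pytest.approx(10 / 5 / 0.5)
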