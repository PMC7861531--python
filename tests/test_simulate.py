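"""Unit tests for the stochastic S-phase simulator and its oracles."""

import numpy as np
import pandas as pd
import pytest

import replifork as rf
from replifork import CRICK, WATSON, Genome, Origin
from replifork.simulate import (
    SPhaseModel,
    cell_rng,
    emit_okazaki_fragments,
    emit_ribo_reads,
    emit_sbfi_reads,
    expected_oem_oracle,
    productive_firing_fraction,
    simulate_cell,
    simulate_sample,
)

from .conftest import simple_model


def replicated_map(state, chrom, length):
    """Per-base (replicated, direction) arrays from a state's intervals."""
    rep = np.zeros(length, dtype=bool)
    direction = np.zeros(length, dtype=int)
    for s, e, d, _ in state.intervals[chrom]:
        rep[s:e] = True
        direction[s:e] = d
    return rep, direction


class TestSimulateCell:
    def test_single_origin_closed_form(self, single_origin_genome, single_origin, rng):
        model = simple_model()
        state = simulate_cell(model, single_origin_genome, [single_origin], 10.0, rng)
        rep, direction = replicated_map(state, "chrI", 100_000)
        # locus replicated iff |x - 50000| <= v * t  (first-passage rule)
        x = np.arange(100_000)
        np.testing.assert_array_equal(rep, np.abs(x - 50_000) <= 10_000)
        assert (direction[40_000:50_001] == -1).all()  # leftward left arm (origin base included)
        assert (direction[50_001:60_001] == +1).all()

    def test_two_origin_collision_at_midpoint(self, rng):
        genome = Genome({"chrI": 100_000})
        origins = [Origin("chrI", 39_900, 40_100, "a"), Origin("chrI", 59_900, 60_100, "b")]
        model = simple_model(2)
        state = simulate_cell(model, genome, origins, 15.0, rng)
        rep, direction = replicated_map(state, "chrI", 100_000)
        # forks meet exactly halfway between synchronous origins
        assert (direction[40_001:50_001] == +1).all()
        assert (direction[50_001:60_001] == -1).all()

    def test_direction_map_matches_bruteforce_argmin(self, rng):
        genome = Genome({"chrI": 50_000})
        origins = [Origin("chrI", p - 50, p + 50, f"o{i}")
                   for i, p in enumerate([6_000, 17_500, 24_000, 33_000, 44_000])]
        model = SPhaseModel(
            competence=np.ones(5),
            firing_mean=rng.uniform(0, 10, 5),
            firing_sd=np.zeros(5),
            fork_speed=float(rng.uniform(900, 1700)),
        )
        ts = 14.0
        state = simulate_cell(model, genome, origins, ts, np.random.default_rng(0))
        rep, direction = replicated_map(state, "chrI", 50_000)
        # exhaustive per-base first-passage scan
        pos = np.array([o.midpoint for o in origins])
        t = state.firing_times
        x = np.arange(50_000)
        arrivals = t[None, :] + np.abs(x[:, None] - pos[None, :]) / model.fork_speed
        k = np.argmin(arrivals, axis=1)  # ties -> leftmost, matching the spec rule
        exp_rep = arrivals[np.arange(len(x)), k] <= ts
        exp_dir = np.where(pos[k] < x, 1, -1) * exp_rep
        np.testing.assert_array_equal(rep, exp_rep)
        np.testing.assert_array_equal(direction, exp_dir)

    def test_passive_origin_never_owns_anything(self, rng):
        genome = Genome({"chrI": 100_000})
        origins = [Origin("chrI", 29_900, 30_100, "early"), Origin("chrI", 39_900, 40_100, "late")]
        model = SPhaseModel(
            competence=[1.0, 1.0], firing_mean=[0.0, 50.0], firing_sd=[0.0, 0.0],
            fork_speed=1000.0,
        )
        state = simulate_cell(model, genome, origins, 60.0, rng)
        owners = set(state.intervals["chrI"][:, 3].tolist())
        assert owners == {0}  # fork from "early" overruns "late" before t=50

    def test_chromosome_without_origins_is_unreplicated(self, rng):
        genome = Genome({"chrI": 100_000, "chrII": 200_000})
        origins = [Origin("chrI", 49_900, 50_100, "o")]
        state = simulate_cell(simple_model(), genome, origins, 10.0, rng)
        assert len(state.intervals["chrII"]) == 0

    def test_intervals_disjoint_and_sorted(self, rng):
        for trial in range(20):
            g, o, m = rf.random_model(np.random.default_rng(trial), n_origins=5)
            state = simulate_cell(m, g, o, 30.0, np.random.default_rng(trial + 100))
            ivs = state.intervals["chrI"]
            assert (ivs[1:, 0] >= ivs[:-1, 1]).all()


class TestEmitOkazaki:
    def test_rightward_interval_all_crick(self, single_origin_genome, single_origin, rng):
        model = simple_model(fragment_rate=5.0)
        state = simulate_cell(model, single_origin_genome, [single_origin], 10.0, rng)
        frags = emit_okazaki_fragments(state, model, rng)
        right = frags[frags["start"] > 50_100]
        left = frags[frags["end"] < 49_900]
        assert (right["strand"] == CRICK).all() and len(right) > 20
        assert (left["strand"] == WATSON).all() and len(left) > 20

    def test_expected_count_poisson(self, single_origin_genome, single_origin):
        model = simple_model(fragment_rate=2.0)
        totals = 0
        n_cells = 1000
        for c in range(n_cells):
            rng = cell_rng(7, c)
            state = simulate_cell(model, single_origin_genome, [single_origin], 10.0, rng)
            totals += len(emit_okazaki_fragments(state, model, rng))
        lam = 2.0 * 20_001 / 1000 * n_cells  # rate x replicated lagging length
        assert abs(totals - lam) < 3 * np.sqrt(lam)

    def test_mean_fragment_length(self, single_origin_genome, single_origin):
        model = simple_model(fragment_rate=3.0, okazaki_mean=165.0, okazaki_sd=30.0)
        lengths = []
        for c in range(300):
            rng = cell_rng(8, c)
            state = simulate_cell(model, single_origin_genome, [single_origin], 30.0, rng)
            f = emit_okazaki_fragments(state, model, rng)
            lengths.append((f["end"] - f["start"]).to_numpy())
        mean = np.concatenate(lengths).mean()
        assert abs(mean - 165.0) / 165.0 < 0.02

    def test_fragments_within_replicated_intervals(self, rng):
        g, o, m = rf.random_model(rng, fragment_rate=2.0)
        state = simulate_cell(m, g, o, 20.0, rng)
        frags = emit_okazaki_fragments(state, m, rng)
        rep, direction = replicated_map(state, "chrI", g["chrI"])
        for row in frags.itertuples(index=False):
            assert rep[row.start:row.end].all()


class TestEmitRibo:
    def test_eps_only_rightward_all_watson(self, single_origin_genome, single_origin, rng):
        model = simple_model(ribo_rate_pol_eps=5.0)
        state = simulate_cell(model, single_origin_genome, [single_origin], 10.0, rng)
        ribo = emit_ribo_reads(state, model, rng)
        right = ribo[ribo["start"] > 50_100]
        assert len(right) > 30 and (right["strand"] == WATSON).all()
        assert ((ribo["end"] - ribo["start"]) == 1).all()

    def test_all_rates_zero_empty(self, single_origin_genome, single_origin, rng):
        model = simple_model()
        state = simulate_cell(model, single_origin_genome, [single_origin], 10.0, rng)
        assert len(emit_ribo_reads(state, model, rng)) == 0

    def test_per_strand_totals_poisson(self, single_origin_genome, single_origin):
        model = simple_model(ribo_rate_pol_eps=1.0, ribo_rate_pol_delta=3.0)
        watson = crick = 0
        for c in range(500):
            rng = cell_rng(9, c)
            state = simulate_cell(model, single_origin_genome, [single_origin], 10.0, rng)
            ribo = emit_ribo_reads(state, model, rng)
            watson += int((ribo["strand"] == WATSON).sum())
            crick += int((ribo["strand"] == CRICK).sum())
        # each strand carries half leading (eps) + half lagging (delta) synthesis
        lam_per_strand = (1.0 + 3.0) * 20.0 * 500 / 2
        for got in (watson, crick):
            assert abs(got - lam_per_strand) < 3 * np.sqrt(lam_per_strand)

    def test_delta_only_is_lagging_strand(self, single_origin_genome, single_origin, rng):
        model = simple_model(ribo_rate_pol_delta=5.0)
        state = simulate_cell(model, single_origin_genome, [single_origin], 10.0, rng)
        ribo = emit_ribo_reads(state, model, rng)
        right = ribo[ribo["start"] > 50_100]
        assert len(right) > 30 and (right["strand"] == CRICK).all()


class TestEmitSbfi:
    def test_reads_only_at_sites(self, rng):
        sites = (("chrI", 10_000), ("chrI", 30_000), ("chrII", 5_000))
        model = simple_model(sbfi_sites=sites)
        reads = emit_sbfi_reads(model, 100.0, rng)
        assert set(zip(reads["chrom"], reads["start"])) <= {(c, p) for c, p in sites}
        lam = 100.0 * 3
        assert abs(len(reads) - lam) < 3 * np.sqrt(lam)

    def test_depth_linearity(self):
        model = simple_model(sbfi_sites=tuple(("chrI", 1000 * k) for k in range(1, 11)))
        n1 = len(emit_sbfi_reads(model, 100.0, np.random.default_rng(0)))
        n2 = len(emit_sbfi_reads(model, 200.0, np.random.default_rng(0)))
        assert abs(n2 - 2 * n1) < 6 * np.sqrt(2000)

    def test_zero_sites_error(self, rng):
        with pytest.raises(ValueError, match="sites"):
            emit_sbfi_reads(simple_model(), 100.0, rng)


class TestOracle:
    def test_isolated_origin_full_efficiency(self, single_origin_genome, single_origin):
        model = simple_model()
        table = expected_oem_oracle(model, single_origin_genome, [single_origin], 15.0)
        assert table["oem"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("p", [0.25, 0.5, 0.8])
    def test_competence_p_between_sure_neighbors(self, p):
        # closed form 2p - 1: non-firing cells get fully convergent flanks
        genome = Genome({"chrI": 200_000})
        origins = [Origin("chrI", 49_900, 50_100, "L"),
                   Origin("chrI", 99_900, 100_100, "M"),
                   Origin("chrI", 149_900, 150_100, "R")]
        model = SPhaseModel(competence=[1.0, p, 1.0], firing_mean=[0.0] * 3,
                            firing_sd=[0.0] * 3, fork_speed=1500.0)
        table = expected_oem_oracle(model, genome, origins, 200.0)
        mid = table.loc[table["id"] == "M", "oem"].iloc[0]
        assert mid == pytest.approx(2 * p - 1, abs=1e-6)

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(3)
        g, o, m = rf.random_model(rng, n_origins=3, chrom_len=180_000, fragment_rate=1.0)
        ts = 40.0
        oracle = expected_oem_oracle(m, g, o, ts)["oem"].to_numpy()
        ests = []
        for rep in range(10):
            samp = simulate_sample(m, g, o, ts, 5_000, seed=rep)
            ests.append(rf.oem_table(samp.okazaki, o)["oem"].to_numpy())
        ests = np.array(ests)
        se = ests.std(axis=0, ddof=1) / np.sqrt(len(ests))
        assert np.all(np.abs(ests.mean(axis=0) - oracle) < 3 * se)

    def test_budget_error(self):
        genome = Genome({"chrI": 10_000_000})
        origins = [Origin("chrI", 20_000 * k, 20_000 * k + 200, f"o{k}")
                   for k in range(1, 450)]
        model = simple_model(len(origins))
        with pytest.raises(ValueError, match="budget"):
            expected_oem_oracle(model, genome, origins, 30.0, budget=1e6)

    def test_monotone_decrease_with_passive_replication(self):
        # competence-0.5 origin between sure early neighbors: OEM non-increasing
        genome = Genome({"chrI": 150_000})
        origins = [Origin("chrI", 34_900, 35_100, "L"),
                   Origin("chrI", 74_900, 75_100, "M"),
                   Origin("chrI", 114_900, 115_100, "R")]
        model = SPhaseModel(competence=[1.0, 0.5, 1.0], firing_mean=[0.0, 0.0, 0.0],
                            firing_sd=[0.0] * 3, fork_speed=1000.0)
        times = [5.0, 15.0, 25.0, 32.0, 40.0, 60.0]
        oems = [expected_oem_oracle(model, genome, origins, t)
                .set_index("id")["oem"]["M"] for t in times]
        assert all(b <= a + 1e-12 for a, b in zip(oems, oems[1:]))
        # strictly decreasing once neighbor forks enter the flanks (> 30 min here)
        assert oems[-1] < oems[2] - 0.05
        assert oems[0] == pytest.approx(1.0, abs=1e-9)

    def test_depletion_lowers_oracle_oem(self):
        rng = np.random.default_rng(5)
        g, o, m = rf.random_model(rng, n_origins=4)
        md = m.with_depletion(0.5)
        from replifork.simulate import time_at_replicated_fraction
        t_full = time_at_replicated_fraction(m, g, o, 0.6, seed=1)
        t_depl = time_at_replicated_fraction(md, g, o, 0.6, seed=1)
        full = expected_oem_oracle(m, g, o, t_full)["oem"].to_numpy()
        depl = expected_oem_oracle(md, g, o, t_depl)["oem"].to_numpy()
        assert np.all(depl < full)


class TestSampleAndTruth:
    def test_deterministic_given_seed(self, single_origin_genome, single_origin):
        model = simple_model(fragment_rate=1.0, seed=5)
        a = simulate_sample(model, single_origin_genome, [single_origin], 10.0, 50)
        b = simulate_sample(model, single_origin_genome, [single_origin], 10.0, 50)
        pd.testing.assert_frame_equal(a.okazaki, b.okazaki)

    def test_different_seed_different_reads(self, single_origin_genome, single_origin):
        model = simple_model(fragment_rate=1.0)
        a = simulate_sample(model, single_origin_genome, [single_origin], 10.0, 50, seed=1)
        b = simulate_sample(model, single_origin_genome, [single_origin], 10.0, 50, seed=2)
        assert not a.okazaki.equals(b.okazaki)

    def test_productive_fraction_isolated_origin_equals_competence(
            self, single_origin_genome, single_origin):
        model = simple_model(competence=[0.6], firing_mean=[10.0], firing_sd=[2.0])
        frac = productive_firing_fraction(model, single_origin_genome, [single_origin],
                                          n_draws=20_000, seed=0)
        assert frac[0] == pytest.approx(0.6, abs=0.015)

    def test_depletion_scales_competence_and_speed(self):
        m = simple_model(competence=[0.8])
        d = m.with_depletion(0.5)
        assert d.effective_competence[0] == pytest.approx(0.4)
        assert d.effective_speed == pytest.approx(500.0)
        c_only = m.with_depletion(0.5, speed=False)
        assert c_only.effective_speed == pytest.approx(1000.0)

    def test_model_validation(self):
        with pytest.raises(ValueError, match="competence"):
            simple_model(competence=[1.5])
        with pytest.raises(ValueError, match="depletion"):
            simple_model().with_depletion(0.0)
        with pytest.raises(ValueError, match="rates"):
            simple_model(fragment_rate=-1.0)
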