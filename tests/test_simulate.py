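"""Origin-firing simulator: weights, sampling law, forks, readout tracks."""

import itertools
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from oriquant.genome import GenomeBuild, GenomicInterval
from oriquant.origins import Centromere, Origin, OriginSet, classify_cen_proximal
from oriquant.preprocess import replicate_correlation
from oriquant.simulate import (
    GENOTYPES,
    Genotype,
    SimConfig,
    assign_firing_weights,
    brdu_track,
    build_sim_fixture,
    dbf4_chip_track,
    sample_fired,
    simulate_cells,
    simulate_experiment,
)


def successive_draw_inclusion_probs(weights, k):
    """Exact inclusion probabilities of k successive weighted draws without
    replacement, by enumeration over ordered draw sequences."""
    n = len(weights)
    probs = np.zeros(n)
    for seq in itertools.permutations(range(n), k):
        p = 1.0
        remaining = list(range(n))
        total = float(sum(weights))
        for i in seq:
            p *= weights[i] / total
            total -= weights[i]
            remaining.remove(i)
        for i in seq:
            probs[i] += p
    return probs


def toy_fixture(weights_hint=None, spacing=30_000, chrom_length=300_000):
    cfg = SimConfig(chrom_count=1, chrom_length=chrom_length,
                    origin_spacing=spacing, cells=50)
    return cfg, build_sim_fixture(cfg, rng=np.random.default_rng(0))


class TestAssignFiringWeights:
    def _four_origin_set(self):
        origins = [
            Origin(GenomicInterval("c", 9_900, 10_100, name="plain1"), "plain1"),
            Origin(GenomicInterval("c", 49_900, 50_100, name="fkh"), "fkh",
                   fkh_activated=True),
            Origin(GenomicInterval("c", 99_900, 100_100, name="cen_ori"), "cen_ori"),
            Origin(GenomicInterval("c", 149_900, 150_100, name="plain2"), "plain2"),
        ]
        cens = [Centromere("c", 100_000, "CEN")]
        return OriginSet(origins), cens

    def test_hand_set_toy_arithmetic(self):
        oset, cens = self._four_origin_set()
        cfg = SimConfig(fkh_boost=2.0, cen_boost=3.0)
        w = assign_firing_weights(oset, cens, Genotype(), cfg, [0.5] * 4)
        np.testing.assert_allclose(w, [0.5, 1.0, 1.5, 0.5])

    def test_neutral_parameters_return_base_efficiencies(self):
        oset, cens = self._four_origin_set()
        cfg = SimConfig(fkh_boost=1.0, cen_boost=1.0)
        base = [0.2, 0.3, 0.4, 0.5]
        w = assign_firing_weights(oset, cens, Genotype(), cfg, base)
        np.testing.assert_allclose(w, base)

    def test_ctf19_loss_removes_exactly_the_cen_factor(self):
        oset, cens = self._four_origin_set()
        cfg = SimConfig(fkh_boost=2.0, cen_boost=3.0)
        base = [0.5] * 4
        wt = assign_firing_weights(oset, cens, Genotype(), cfg, base)
        mut = assign_firing_weights(oset, cens, Genotype(ctf19=False), cfg, base)
        np.testing.assert_allclose(mut, [0.5, 1.0, 0.5, 0.5])
        np.testing.assert_allclose(wt / mut, [1.0, 1.0, 3.0, 1.0])

    def test_cen_boost_decays_linearly_with_distance(self):
        cfg = SimConfig(cen_boost=4.0, cen_range=25_000.0, fkh_boost=1.0)
        cens = [Centromere("c", 100_000, "CEN")]
        mids = [100_000, 112_500, 125_000, 130_000]
        origins = [
            Origin(GenomicInterval("c", m - 100, m + 100, name=f"o{m}"), f"o{m}")
            for m in mids
        ]
        w = assign_firing_weights(OriginSet(origins), cens, Genotype(), cfg,
                                  [1.0] * 4)
        np.testing.assert_allclose(w, [4.0, 2.5, 1.0, 1.0])

    def test_zn_allele_keeps_fkh_but_loses_cen_boost(self):
        oset, cens = self._four_origin_set()
        cfg = SimConfig(fkh_boost=2.0, cen_boost=3.0)
        w = assign_firing_weights(oset, cens, Genotype(dbf4_allele="Zn*"), cfg,
                                  [0.5] * 4)
        np.testing.assert_allclose(w, 0.8 * np.array([0.5, 1.0, 0.5, 0.5]))

    def test_fkh1_sensitive_origin_requires_fkh1(self):
        origins = [
            Origin(GenomicInterval("c", 900, 1100, name="f1only"), "f1only",
                   fkh_activated=True, fkh1_sensitive=True),
            Origin(GenomicInterval("c", 4900, 5100, name="either"), "either",
                   fkh_activated=True),
        ]
        cfg = SimConfig(fkh_boost=3.0)
        w = assign_firing_weights(OriginSet(origins), [], Genotype(fkh1=False),
                                  cfg, [1.0, 1.0])
        np.testing.assert_allclose(w, [1.0, 3.0])


class TestSampleFired:
    def test_pool_of_zero_fires_nothing(self, rng):
        assert sample_fired(np.ones(5), 0, rng, 10).shape == (10, 0)

    def test_k1_law_matches_weight_fractions(self, rng):
        weights = np.array([1.0, 2.0, 3.0, 4.0])
        n = 20_000
        fired = sample_fired(weights, 1, rng, n)[:, 0]
        observed = np.bincount(fired, minlength=4)
        expected = n * weights / weights.sum()
        chi2, p = stats.chisquare(observed, expected)
        assert p > 1e-3

    def test_matches_enumeration_oracle(self, rng):
        weights = np.array([0.3, 1.0, 2.0, 0.5, 1.5, 0.7])
        exact = successive_draw_inclusion_probs(weights, 3)
        n = 40_000
        fired = sample_fired(weights, 3, rng, n)
        freq = np.bincount(fired.ravel(), minlength=6) / n
        se = np.sqrt(exact * (1 - exact) / n)
        assert np.all(np.abs(freq - exact) < 5 * se)

    def test_competition_raising_one_weight_lowers_others(self):
        base = np.array([0.5, 0.8, 1.0, 1.2, 0.6, 0.9, 1.1, 0.7, 1.3, 1.0])
        before = successive_draw_inclusion_probs(base, 3)
        boosted = base.copy()
        boosted[0] *= 4.0
        after = successive_draw_inclusion_probs(boosted, 3)
        assert after[0] > before[0]
        assert np.all(after[1:] <= before[1:] + 1e-12)

    def test_nonpositive_weights_rejected(self, rng):
        with pytest.raises(ValueError, match="positive"):
            sample_fired(np.array([1.0, 0.0]), 1, rng)


class TestSimulateCells:
    def test_single_origin_unclipped_extent(self):
        cfg = SimConfig(chrom_count=1, chrom_length=300_000,
                        origin_spacing=300_000, pool_size=1,
                        fork_speed=1000.0, duration_min=60.0,
                        synthesis_budget_bp=1e9)
        fixture = build_sim_fixture(cfg, rng=np.random.default_rng(0))
        cells = simulate_cells(np.ones(1), fixture, Genotype(), cfg,
                               np.random.default_rng(0), n_cells=1)
        (chrom, s, e), = cells[0].intervals
        assert e - s == 120_000  # 2 v T

    def test_budget_divides_among_forks(self):
        cfg = SimConfig(pool_size=40, synthesis_budget_bp=120_000.0,
                        fork_speed=100.0, duration_min=60.0, cells=5)
        fixture = build_sim_fixture(cfg, rng=np.random.default_rng(1))
        weights = np.ones(len(fixture.origin_set))
        cells = simulate_cells(weights, fixture, Genotype(), cfg,
                               np.random.default_rng(1), n_cells=5)
        for cell in cells:
            assert len(cell.fired) == 40
            per_side = 120_000.0 / (2 * 40)
            for _, s, e in cell.intervals:
                assert e - s <= 2 * per_side + 1

    def test_conservation_invariants(self, rng):
        cfg = SimConfig(cells=50)
        fixture = build_sim_fixture(cfg, rng=np.random.default_rng(2))
        weights = np.ones(len(fixture.origin_set))
        cells = simulate_cells(weights, fixture, Genotype(), cfg,
                               np.random.default_rng(2))
        v_t = cfg.fork_speed * cfg.duration_min
        for cell in cells:
            assert len(cell.fired) <= cfg.pool_size
            assert cell.replicated_bp <= 2 * v_t * len(cell.fired) + 1
            for chrom, s, e in cell.intervals:
                assert 0 <= s < e <= fixture.genome.length_of(chrom)

    def test_dc_runs_longer_in_hu(self):
        cfg = SimConfig(pool_size=1, synthesis_budget_bp=1e9,
                        chrom_count=1, chrom_length=300_000,
                        origin_spacing=300_000)
        fixture = build_sim_fixture(cfg, rng=np.random.default_rng(0))
        wt_cells = simulate_cells(np.ones(1), fixture, Genotype(), cfg,
                                  np.random.default_rng(0), n_cells=1)
        dc_cells = simulate_cells(np.ones(1), fixture,
                                  Genotype(dbf4_allele="dC"), cfg,
                                  np.random.default_rng(0), n_cells=1)
        assert dc_cells[0].replicated_bp / wt_cells[0].replicated_bp == \
            pytest.approx(90.0 / 60.0, rel=0.01)


class TestBrduTrack:
    def test_unreplicated_bins_always_zero(self, rng):
        cfg = SimConfig(chrom_count=1, cells=20)
        fixture = build_sim_fixture(cfg, rng=np.random.default_rng(3))
        weights = np.ones(len(fixture.origin_set))
        cells = simulate_cells(weights, fixture, Genotype(), cfg,
                               np.random.default_rng(3), n_cells=20)
        track = brdu_track(cells, fixture, cfg, rng)
        replicated = np.zeros(len(track.values["chr01"]), dtype=bool)
        for cell in cells:
            for _, s, e in cell.intervals:
                replicated[s // 50 : (e - 1) // 50 + 1] = True
        assert np.all(track.values["chr01"][~replicated] == 0)

    def test_fully_replicated_bins_have_poisson_mean_depth(self, rng):
        cfg = SimConfig(chrom_count=1, chrom_length=60_000,
                        origin_spacing=60_000, pool_size=1, read_depth=80.0,
                        synthesis_budget_bp=1e9, fork_speed=1000.0)
        fixture = build_sim_fixture(cfg, rng=np.random.default_rng(4))
        cells = simulate_cells(np.ones(1), fixture, Genotype(), cfg,
                               np.random.default_rng(4), n_cells=10)
        track = brdu_track(cells, fixture, cfg, rng)
        v = track.values["chr01"]  # whole chromosome replicated in every cell
        mean = v.mean()
        se = np.sqrt(cfg.read_depth / len(v))
        assert abs(mean - cfg.read_depth) < 4 * se

    def test_doubling_a_weight_never_lowers_its_window_signal(self):
        cfg = SimConfig(cells=400)
        fixture = build_sim_fixture(cfg, rng=np.random.default_rng(5))
        n = len(fixture.origin_set)
        target = 7
        freqs = {}
        for scale in (1.0, 2.0):
            got = []
            for seed in range(10):
                weights = np.ones(n)
                weights[target] *= scale
                cells = simulate_cells(weights, fixture, Genotype(), cfg,
                                       np.random.default_rng(100 + seed),
                                       n_cells=400)
                got.append(
                    np.mean([target in cell.fired for cell in cells])
                )
            freqs[scale] = np.array(got)
        assert np.all(freqs[2.0] >= freqs[1.0])


class TestDbf4ChipTrack:
    def test_zero_amplitude_gives_flat_background(self, rng):
        cfg = SimConfig(chip_cen_amp=0.0, chip_prox_amp=0.0, chip_depth=50.0)
        fixture = build_sim_fixture(cfg, rng=np.random.default_rng(6))
        track = dbf4_chip_track(fixture, Genotype(), cfg, rng)
        v = track.concatenated()
        expected = cfg.chip_depth * cfg.chip_background
        assert abs(v.mean() - expected) < 4 * np.sqrt(expected / len(v))

    def test_cen_windows_enriched_over_background(self, rng):
        cfg = SimConfig()
        fixture = build_sim_fixture(cfg, rng=np.random.default_rng(7))
        track = dbf4_chip_track(fixture, Genotype(), cfg, rng)
        for cen in fixture.centromeres[:4]:
            i = cen.position // cfg.bin_width
            assert track.values[cen.chrom][i] > 2 * cfg.chip_depth


class TestSimulateExperiment:
    def test_same_seed_is_bit_identical(self):
        cfg = SimConfig(chrom_count=2, cells=100)
        a, _, _ = simulate_experiment(cfg, {"WT": GENOTYPES["WT"]}, seed=11)
        b, _, _ = simulate_experiment(cfg, {"WT": GENOTYPES["WT"]}, seed=11)
        for ta, tb in zip(a["WT"].tracks, b["WT"].tracks):
            for chrom in ta.values:
                np.testing.assert_array_equal(ta.values[chrom], tb.values[chrom])

    def test_replicates_correlate_at_default_depth(self):
        # correlation is assessed on smoothed tracks, as in the pipeline
        from oriquant.preprocess import median_smooth

        cfg = SimConfig()
        repsets, _, _ = simulate_experiment(cfg, {"WT": GENOTYPES["WT"]}, seed=12)
        r = replicate_correlation(
            *[median_smooth(t) for t in repsets["WT"].tracks]
        )
        assert r > 0.9

    def test_fkh1_loss_shifts_firing_toward_cen_proximal(self):
        cfg = SimConfig(cells=500)
        diffs = []
        for seed in range(8):
            _, truth, fixture = simulate_experiment(
                cfg,
                {"WT": GENOTYPES["WT"], "fkh1∆": GENOTYPES["fkh1∆"]},
                replicates=1,
                seed=seed,
            )
            prox = classify_cen_proximal(
                fixture.origin_set, fixture.centromeres
            ).cen_proximal
            t = truth.pivot(index="origin", columns="genotype",
                            values="firing_frequency")
            cen = t.loc[sorted(prox)]
            diffs.append(float((cen["fkh1∆"] - cen["WT"]).mean()))
        # competition for the limiting pool: freed DDK flows to CEN-proximal
        assert np.mean(diffs) > 0
        assert sum(d > 0 for d in diffs) >= 7

    def test_truth_table_covers_all_origins_and_genotypes(self):
        cfg = SimConfig(chrom_count=2, cells=50)
        _, truth, fixture = simulate_experiment(
            cfg, {"WT": GENOTYPES["WT"], "ctf19∆": GENOTYPES["ctf19∆"]}, seed=13
        )
        assert set(truth["genotype"]) == {"WT", "ctf19∆"}
        assert len(truth) == 2 * len(fixture.origin_set)
        assert truth["firing_frequency"].between(0, 1).all()
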