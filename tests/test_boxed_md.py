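import numpy as np
import pytest
from scipy.integrate import quad

from gopull.boxed_md import (
    BoxRates,
    BoxStats,
    BXDConfig,
    BXDStats,
    equilibration_check,
    partition_boxes,
    pmf_from_rates,
    rates_from_stats,
    run_bxd,
    run_bxd_1d,
)
from gopull.langevin_engine import LangevinParams, PolynomialPotential

KT = 0.3


def boltzmann_box_pmf(potential, edges, kT=KT):
    """Quadrature oracle: −kT·ln of per-box Boltzmann weights, box 0 = 0."""
    Z = np.array(
        [
            quad(lambda x: np.exp(-potential(x) / kT), lo, hi)[0]
            for lo, hi in zip(edges[:-1], edges[1:])
        ]
    )
    return -kT * np.log(Z / Z[0])


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"rc_min": 0, "rc_max": 10, "box_width": 0},
            {"rc_min": 0, "rc_max": 10, "box_width": -1},
            {"rc_min": 0, "rc_max": 3, "box_width": 5.0},  # width > range
            {"rc_min": 0, "rc_max": 10, "box_width": 5.0, "events_per_box": 1},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            BXDConfig(**kwargs)


class TestPartitionBoxes:
    def test_exact_division(self):
        edges = partition_boxes(BXDConfig(10.0, 25.0, 5.0))
        np.testing.assert_allclose(edges, [10, 15, 20, 25])

    def test_truncated_final_box_warns(self):
        with pytest.warns(UserWarning, match="truncated"):
            edges = partition_boxes(BXDConfig(0.0, 12.0, 5.0))
        np.testing.assert_allclose(edges, [0, 5, 10, 12])

    def test_half_open_coverage(self):
        edges = partition_boxes(BXDConfig(-3.0, 9.0, 3.0))
        assert edges[0] == -3.0
        assert edges[-1] == 9.0
        assert np.all(np.diff(edges) > 0)


def _stats_from_counts(per_box, width=1.0):
    """Assemble BXDStats from (hits_up, hits_down, residence) triples."""
    boxes = []
    for m, (up, down, res) in enumerate(per_box):
        n = up + down
        walls = np.array([1] * up + [-1] * down)
        times = np.linspace(0, res, n, endpoint=False) if n else np.zeros(0)
        boxes.append(BoxStats(m * width, (m + 1) * width, up, down, res, times, walls))
    cfg = BXDConfig(0.0, len(per_box) * width, width, events_per_box=2)
    return BXDStats(boxes, cfg)


class TestRates:
    def test_arithmetic(self):
        stats = _stats_from_counts([(10, 40, 5.0), (10, 20, 2.0)])
        rates = rates_from_stats(stats)
        assert rates.k_up[0] == pytest.approx(2.0)
        assert rates.k_down[0] == pytest.approx(8.0)
        assert rates.k_down[1] == pytest.approx(10.0)

    def test_zero_upper_hits_error(self):
        stats = _stats_from_counts([(0, 40, 5.0), (10, 20, 2.0)])
        with pytest.raises(ValueError, match="events|smaller boxes"):
            rates_from_stats(stats)

    def test_double_residence_halves_rate(self):
        a = rates_from_stats(_stats_from_counts([(10, 10, 5.0), (5, 5, 5.0)]))
        b = rates_from_stats(_stats_from_counts([(10, 10, 10.0), (5, 5, 5.0)]))
        assert b.k_up[0] == pytest.approx(a.k_up[0] / 2.0)

    def test_nonpositive_residence_error(self):
        stats = _stats_from_counts([(10, 10, 0.0), (5, 5, 5.0)])
        with pytest.raises(ValueError, match="residence"):
            rates_from_stats(stats)


class TestPmfFromRates:
    def test_detailed_balance_flat(self):
        stats = _stats_from_counts([(10, 10, 1.0)] * 4)
        pmf = pmf_from_rates(rates_from_stats(stats), KT)
        np.testing.assert_allclose(pmf.free_energy, 0.0, atol=1e-12)

    def test_single_boundary_log_ratio(self):
        # k_f / k_b = e ⇒ ΔG = −kT
        rates = BoxRates(
            k_up=np.array([np.e, 1.0]),
            k_down=np.array([1.0, 1.0]),
            hits_up=np.array([1000.0, 1000.0]),
            hits_down=np.array([1000.0, 1000.0]),
            centers=np.array([0.5, 1.5]),
        )
        pmf = pmf_from_rates(rates, KT)
        assert pmf.free_energy[1] == pytest.approx(-0.3)

    def test_nonpositive_rate_error(self):
        rates = BoxRates(
            k_up=np.array([0.0, 1.0]),
            k_down=np.array([1.0, 1.0]),
            hits_up=np.array([0.0, 10.0]),
            hits_down=np.array([10.0, 10.0]),
            centers=np.array([0.5, 1.5]),
        )
        with pytest.raises(ValueError):
            pmf_from_rates(rates, KT)

    def test_anchored_at_zero_with_errors(self):
        stats = _stats_from_counts([(20, 60, 1.0), (30, 50, 1.0), (10, 40, 1.0)])
        pmf = pmf_from_rates(rates_from_stats(stats), KT)
        assert pmf.free_energy[0] == 0.0
        assert pmf.stderr[0] == 0.0
        assert np.all(np.diff(pmf.stderr) > 0)  # accumulates along the sweep


class TestRunBxd1d:
    def test_free_diffusion_symmetric_rates(self):
        # hits cluster strongly at a wall, so the standard error comes from
        # independent seeds rather than a Poisson count model
        pot = PolynomialPotential((0.0,))  # V = 0
        diffs = []
        for seed in range(8):
            cfg = BXDConfig(0.0, 1.0, 0.5, events_per_box=4000, min_time_per_box=200.0)
            stats = run_bxd_1d(pot, cfg, LangevinParams(dt=0.001), seed=seed)
            box = stats.boxes[0]
            diffs.append((box.hits_upper - box.hits_lower) / box.n_hits)
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * se + 1e-12

    def test_linear_potential_biases_lower_wall(self):
        pot = PolynomialPotential.linear(2.0)  # V = 2x: pushed toward lower wall
        cfg = BXDConfig(0.0, 1.0, 0.5, events_per_box=2000, min_time_per_box=100.0)
        stats = run_bxd_1d(pot, cfg, LangevinParams(dt=0.001), seed=4, x0=0.25)
        box = stats.boxes[0]
        assert box.hits_lower > box.hits_upper

    def test_seed_determinism(self):
        pot = PolynomialPotential.harmonic(1.0)
        cfg = BXDConfig(0.0, 1.5, 0.5, events_per_box=200)
        a = run_bxd_1d(pot, cfg, LangevinParams(), seed=8)
        b = run_bxd_1d(pot, cfg, LangevinParams(), seed=8)
        for ba, bb in zip(a.boxes, b.boxes):
            np.testing.assert_array_equal(ba.hit_walls, bb.hit_walls)
            np.testing.assert_array_equal(ba.hit_times, bb.hit_times)

    def test_initial_x_outside_first_box_raises(self):
        pot = PolynomialPotential.harmonic(1.0)
        cfg = BXDConfig(0.0, 1.5, 0.5)
        with pytest.raises(ValueError, match="first box"):
            run_bxd_1d(pot, cfg, LangevinParams(), seed=1, x0=0.9)

    def test_quota_failure_reported_with_box(self):
        pot = PolynomialPotential.harmonic(1.0)
        cfg = BXDConfig(0.0, 1.5, 0.5, events_per_box=100_000, max_steps_per_box=2_000)
        with pytest.raises(RuntimeError, match="box 0"):
            run_bxd_1d(pot, cfg, LangevinParams(), seed=1)

    def test_harmonic_oracle_two_boxes_quick(self):
        pot = PolynomialPotential.harmonic(1.0)
        cfg = BXDConfig(0.0, 1.0, 0.5, events_per_box=2000, min_time_per_box=1000.0)
        stats = run_bxd_1d(pot, cfg, LangevinParams(dt=0.001), seed=5)
        pmf = pmf_from_rates(rates_from_stats(stats), KT)
        oracle = boltzmann_box_pmf(pot, partition_boxes(cfg))
        np.testing.assert_allclose(pmf.free_energy, oracle, atol=0.08)

    def test_error_decreases_with_events(self):
        # averaged over seeds, 2000 events/box beats 500 events/box
        pot = PolynomialPotential.harmonic(1.0)
        edges = np.array([0.0, 0.5, 1.0, 1.5])
        oracle = boltzmann_box_pmf(pot, edges)

        def mean_err(events, seeds):
            errs = []
            for s in seeds:
                cfg = BXDConfig(0.0, 1.5, 0.5, events_per_box=events)
                stats = run_bxd_1d(pot, cfg, LangevinParams(dt=0.001), seed=s)
                pmf = pmf_from_rates(rates_from_stats(stats), KT)
                errs.append(np.abs(pmf.free_energy - oracle).max())
            return np.mean(errs)

        assert mean_err(2000, range(8)) < mean_err(500, range(100, 108))

    def test_box_width_invariance(self):
        pot = PolynomialPotential.harmonic(1.0)
        params = LangevinParams(dt=0.001)
        profiles = {}
        for width in (0.5, 0.25):
            cfg = BXDConfig(0.0, 2.0, width, events_per_box=2000, min_time_per_box=2000.0)
            stats = run_bxd_1d(pot, cfg, params, seed=6)
            pmf = pmf_from_rates(rates_from_stats(stats), KT)
            oracle = boltzmann_box_pmf(pot, partition_boxes(cfg))
            profiles[width] = np.abs(pmf.free_energy - oracle).max()
        # both widths recover their own oracle within a shared tolerance
        assert max(profiles.values()) < 0.12


class TestRunBxdCG:
    def test_initial_rc_outside_raises(self, bundle2):
        s, _, topo = bundle2
        cfg = BXDConfig(100.0, 120.0, 5.0)
        with pytest.raises(ValueError, match="first box"):
            run_bxd(topo, cfg, LangevinParams(), seed=0)

    def test_two_box_sweep_runs(self, two_bead_topology):
        cfg = BXDConfig(4.5, 7.5, 1.5, events_per_box=300, min_time_per_box=20.0)
        stats = run_bxd(two_bead_topology, cfg, LangevinParams(), seed=2)
        assert len(stats.boxes) == 2
        assert all(b.n_hits >= 300 for b in stats.boxes)
        pmf = pmf_from_rates(rates_from_stats(stats), KT)
        # stretching the contact out of its minimum costs free energy
        assert pmf.free_energy[-1] > 0

    def test_hit_log_dataframe(self, two_bead_topology):
        cfg = BXDConfig(4.5, 7.5, 1.5, events_per_box=50)
        stats = run_bxd(two_bead_topology, cfg, LangevinParams(), seed=2)
        df = stats.hit_log()
        assert set(df.columns) == {"box", "wall", "time"}
        assert set(df["wall"]) <= {"upper", "lower"}


class TestEquilibrationCheck:
    def test_stationary_stream_passes(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 10.0, 200))
        walls = rng.choice([1, -1], 200)
        box = BoxStats(0, 1, int((walls > 0).sum()), int((walls < 0).sum()), 10.0, times, walls)
        cfg = BXDConfig(0, 2, 1.0, events_per_box=2)
        report = equilibration_check(BXDStats([box], cfg))
        assert report.loc[0, "verdict"] == "pass"

    def test_drifting_stream_fails(self):
        # 10× more hits in the first half
        times = np.concatenate([np.linspace(0, 5, 180), np.linspace(5, 10, 20)])
        walls = np.ones(200, dtype=int)
        box = BoxStats(0, 1, 200, 0, 10.0, times, walls)
        cfg = BXDConfig(0, 2, 1.0, events_per_box=2)
        report = equilibration_check(BXDStats([box], cfg))
        assert report.loc[0, "verdict"] == "fail"

    def test_insufficient_data(self):
        times = np.linspace(0, 1, 30)
        walls = np.ones(30, dtype=int)
        box = BoxStats(0, 1, 30, 0, 1.0, times, walls)
        cfg = BXDConfig(0, 2, 1.0, events_per_box=2)
        report = equilibration_check(BXDStats([box], cfg))
        assert report.loc[0, "verdict"] == "insufficient data"
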