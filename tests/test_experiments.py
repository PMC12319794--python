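"""Experiment drivers and their statistics on small toy networks."""

import numpy as np
import pandas as pd
import pytest

from vasim.experiments import (
    GROUP_ORDER,
    MonteCarloSettings,
    SlopeEstimate,
    compare_slopes,
    fit_laminar_slopes,
    group_means,
    lamina_group,
    run_contribution_analysis,
    run_hct_sweep,
    run_so2_sweep,
    slope_recovery_coverage,
)
from vasim.network import ARTERY, MICROVESSEL, VEIN, VascularNetwork


@pytest.fixture(scope="module")
def toy_net():
    """A small labeled voxel: one vein, one artery, a few capillaries."""
    rng = np.random.default_rng(4)
    box = 150.0
    p0 = [[75.0, 0.0, 20.0], [40.0, 0.0, 30.0]]
    p1 = [[75.0, box, 20.0], [40.0, box, 30.0]]
    radius = [12.0, 7.0]
    comp = [VEIN, ARTERY]
    for _ in range(40):
        c = rng.uniform(10, box - 10, 3)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        p0.append((c - 25 * d).tolist())
        p1.append((c + 25 * d).tolist())
        radius.append(float(rng.uniform(2.0, 4.0)))
        comp.append(MICROVESSEL)
    p0, p1 = np.clip(np.array(p0), 0, box), np.clip(np.array(p1), 0, box)
    return VascularNetwork(
        p0, p1, np.array(radius), np.linalg.norm(p1 - p0, axis=1),
        compartment=np.array(comp, dtype=np.int8),
        box=np.array([[0.0, 0.0, 0.0], [box, box, box]]),
        name="toy",
    )


@pytest.fixture(scope="module")
def toy_mc():
    return MonteCarloSettings(n_spins=2000, n_reps=2, grid_spacing=5.0, seed=3)


@pytest.fixture(scope="module")
def sweep_df(toy_net, toy_mc):
    return run_so2_sweep(toy_net, so2_levels=(0.50, 0.62, 0.74, 0.86), mc=toy_mc)


class TestGrouping:
    def test_partition_of_sixteen(self):
        assert [lamina_group(i) for i in (1, 4)] == ["top", "top"]
        assert lamina_group(5) == "top_middle"
        assert lamina_group(12) == "middle_bottom"
        assert lamina_group(16) == "bottom"
        with pytest.raises(ValueError):
            lamina_group(17)


class TestSo2Sweep:
    def test_table_shape_and_echo_times(self, sweep_df):
        # 2 sequences x 4 states x 16 laminae x 2 reps
        assert len(sweep_df) == 2 * 4 * 16 * 2
        assert set(sweep_df["sequence"]) == {"GE", "SE"}
        assert sweep_df.attrs["manifest"]["experiment"] == "so2_sweep"

    def test_rates_fall_with_oxygenation(self, sweep_df):
        g = group_means(sweep_df, "dR2_pct")
        for seq in ("GE", "SE"):
            for grp in GROUP_ORDER:
                sub = g[(g["sequence"] == seq) & (g["lamina_group"] == grp)]
                y = sub.sort_values("so2_vein")["dR2_pct"].to_numpy()
                assert y[0] > y[-1] > -1e-9

    def test_dbold_is_negative_and_shrinks_with_so2(self, sweep_df):
        g = group_means(sweep_df, "dBOLD_pct")
        sub = g[(g["sequence"] == "GE") & (g["lamina_group"] == "top")]
        y = sub.sort_values("so2_vein")["dBOLD_pct"].to_numpy()
        assert np.all(y < 0) and y[-1] > y[0]

    def test_determinism(self, toy_net, toy_mc, sweep_df):
        again = run_so2_sweep(toy_net, so2_levels=(0.50, 0.62, 0.74, 0.86), mc=toy_mc)
        pd.testing.assert_frame_equal(again, sweep_df)


class TestContributions:
    def test_shares_sum_to_hundred(self, toy_net, toy_mc, sweep_df):
        tab = run_contribution_analysis(toy_net, mc=toy_mc, sweep_df=sweep_df)
        total = tab["ev_pct"] + tab["iv_art_pct"] + tab["iv_vein_pct"]
        np.testing.assert_allclose(total, 100.0, atol=1e-9)

    def test_zero_macrovascular_cbv_means_pure_ev(self, sweep_df):
        # laminae without macrovessels have EV share 100
        no_macro = sweep_df[(sweep_df["iva_frac"] == 0) & (sweep_df["ivv_frac"] == 0)]
        assert len(no_macro) > 0
        np.testing.assert_allclose(no_macro["ev_frac"], 100.0, atol=1e-9)

    def test_se_venous_share_exceeds_ge_at_high_so2(self, sweep_df):
        # venous blood T2 at 7T: SE 38 ms vs GE 9.4 ms near 89 % saturation
        top = sweep_df[(sweep_df["lamina_group"] == "top") & (sweep_df["so2_vein"] == 0.86)]
        ge = top[top["sequence"] == "GE"]["ivv_frac"].mean()
        se = top[top["sequence"] == "SE"]["ivv_frac"].mean()
        assert se > ge


@pytest.fixture(scope="module")
def hct_df(toy_net, toy_mc):
    return run_hct_sweep(
        toy_net, hct_levels=(0.35, 0.40, 0.45, 0.50, 0.55), so2_levels=(0.62,), mc=toy_mc
    )


class TestHctSweep:
    def test_reference_level_is_zero(self, hct_df):
        ref = hct_df[np.isclose(hct_df["hct"], 0.45)]
        np.testing.assert_allclose(ref["rel_dBOLD_pct"], 0.0, atol=1e-12)

    def test_levels_present(self, hct_df):
        assert sorted(hct_df["hct"].unique()) == [0.35, 0.40, 0.45, 0.50, 0.55]

    def test_response_decreases_with_hematocrit(self, hct_df):
        g = group_means(hct_df, "rel_dBOLD_pct")
        for seq in ("GE", "SE"):
            for grp in GROUP_ORDER:
                sub = g[(g["sequence"] == seq) & (g["lamina_group"] == grp)]
                y = sub.sort_values("hct")["rel_dBOLD_pct"].to_numpy()
                assert np.all(np.diff(y) < 0)

    def test_missing_reference_rejected(self, toy_net, toy_mc):
        with pytest.raises(ValueError, match="reference"):
            run_hct_sweep(toy_net, hct_levels=(0.35, 0.40), mc=toy_mc)


class TestSlopeStatistics:
    def _table(self, slope, noise, n_reps=4, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for rep in range(n_reps):
            for x in (0.5, 0.62, 0.74, 0.86):
                for lam in range(1, 17):
                    rows.append(
                        {
                            "sequence": "GE",
                            "lamina": lam,
                            "lamina_group": lamina_group(lam),
                            "so2_vein": x,
                            "rep": rep,
                            "dR2_pct": 3.0 + slope * x + rng.normal(0, noise),
                        }
                    )
        return pd.DataFrame(rows)

    def test_noiseless_data_recovers_exact_slope(self):
        est = fit_laminar_slopes(self._table(-10.0, 0.0), "dR2_pct", "so2_fraction")
        for grp in GROUP_ORDER:
            assert est[grp].slope == pytest.approx(-10.0)
            assert est[grp].ci95[0] == pytest.approx(est[grp].ci95[1])

    def test_ci_contains_the_estimate(self):
        est = fit_laminar_slopes(self._table(-10.0, 0.5), "dR2_pct", "so2_fraction")
        for e in est.values():
            assert e.ci95[0] <= e.slope <= e.ci95[1]

    def test_single_level_is_an_error(self):
        df = self._table(-10.0, 0.0)
        with pytest.raises(ValueError, match="two predictor levels"):
            fit_laminar_slopes(df[df["so2_vein"] == 0.5], "dR2_pct", "so2_fraction")

    def test_unknown_predictor_rejected(self):
        with pytest.raises(ValueError, match="predictor"):
            fit_laminar_slopes(self._table(-1.0, 0.0), "dR2_pct", "depth")


class TestCompareSlopes:
    def test_identical_samples_not_significant(self):
        s = np.array([1.0, 1.1, 0.9, 1.05])
        assert compare_slopes(s, s) > 0.99

    def test_separated_samples_highly_significant(self):
        rng = np.random.default_rng(1)
        a = -25.0 + rng.normal(0, 0.5, 20)
        b = -14.0 + rng.normal(0, 0.5, 20)
        assert compare_slopes(a, b) < 1e-3

    def test_degenerate_zero_variance_guard(self):
        assert compare_slopes(np.array([1.0, 1.0]), np.array([2.0, 2.0])) == 0.0
        assert compare_slopes(np.array([1.0, 1.0]), np.array([1.0, 1.0])) == 1.0
        with pytest.raises(ValueError):
            compare_slopes(np.array([1.0]), np.array([1.0, 2.0]))

    def test_works_on_estimates(self):
        a = SlopeEstimate(1.0, (0.5, 1.5), (0.9, 1.0, 1.1), "so2_fraction")
        b = SlopeEstimate(1.0, (0.5, 1.5), (0.95, 1.0, 1.05), "so2_fraction")
        assert 0.0 <= compare_slopes(a, b) <= 1.0


def test_slope_recovery_coverage_near_nominal():
    cov = slope_recovery_coverage(n_trials=300, seed=11)
    assert 0.88 <= cov <= 0.99
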