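"""Monte Carlo sampling, propagation, percentiles and CDF curves."""

import numpy as np
import pytest

from eggrisk import (
    ConfigError,
    DistributionSpec,
    MCConfig,
    SamplingError,
    compute_thq,
    cumulative_curve,
    default_mc_config,
    percentile,
    run_mc,
    sample,
)

Z95 = 1.6449  # standard normal 95th-percentile quantile


def rng(seed=0):
    return np.random.default_rng(seed)


class TestSample:
    def test_point_family_degenerate(self):
        out = sample(DistributionSpec("point", {"value": 7.158}), 5, rng())
        assert np.all(out == 7.158)

    def test_truncation_contract(self):
        out = sample(DistributionSpec("normal", {"mean": 0, "sd": 1},
                                      truncate_low=0.0), 5000, rng())
        assert out.min() >= 0.0

    def test_normal_p95_matches_closed_form(self):
        spec = DistributionSpec("normal", {"mean": 7.158, "sd": 0.248})
        out = sample(spec, 10**5, rng(42))
        assert np.percentile(out, 95) == pytest.approx(7.158 + Z95 * 0.248, abs=0.01)

    @pytest.mark.parametrize("spec", [
        DistributionSpec("uniform", {"low": 1.0, "high": 2.0}),
        DistributionSpec("triangular", {"low": 0.5, "mode": 1.0, "high": 3.0}),
        DistributionSpec("lognormal", {"mean_log": 0.0, "sd_log": 0.5}),
    ])
    def test_other_families_draw_within_support(self, spec):
        out = sample(spec, 2000, rng(1))
        assert out.min() >= 0.0
        assert np.isfinite(out).all()

    def test_infeasible_truncation_errors(self):
        spec = DistributionSpec("uniform", {"low": 0.0, "high": 1.0}, truncate_low=5.0)
        with pytest.raises(SamplingError):
            sample(spec, 100, rng())

    def test_invalid_scale_rejected(self):
        with pytest.raises(ConfigError):
            DistributionSpec("normal", {"mean": 0, "sd": 0.0})


class TestPercentile:
    def test_median_and_interpolated_p95(self):
        assert percentile([1, 2, 3, 4, 5], 50) == 3.0
        assert percentile([1, 2, 3, 4, 5], 95) == pytest.approx(4.8)

    def test_constant_draws(self):
        assert percentile([2.5] * 10, 37.3) == 2.5

    def test_order_invariance(self):
        draws = rng(5).normal(size=200)
        shuffled = rng(6).permutation(draws)
        for p in (5, 50, 95):
            assert percentile(draws, p) == percentile(shuffled, p)

    def test_domain_errors(self):
        with pytest.raises(ConfigError):
            percentile([], 50)
        with pytest.raises(ConfigError):
            percentile([1.0], 100)


class TestCumulativeCurve:
    def test_terminus_and_conservation(self):
        curve = cumulative_curve([1.0, 1.0, 2.0])
        assert curve[-1, 1] == 1.0
        assert sorted(curve[:, 0]) == [1.0, 1.0, 2.0]
        assert np.all(np.diff(curve[:, 0]) >= 0)
        assert np.all(np.diff(curve[:, 1]) >= 0)

    def test_cdf_at_p95_value_is_near_095(self):
        draws = rng(9).normal(size=20000)
        q = percentile(draws, 95)
        curve = cumulative_curve(draws)
        prob = curve[np.searchsorted(curve[:, 0], q), 1]
        assert prob == pytest.approx(0.95, abs=0.005)


class TestRunMc:
    def test_point_specs_collapse_to_deterministic(self, ep, analytes, pb_summary):
        cfg = MCConfig(seed=1, n_iter=50, specs={
            "concentration": DistributionSpec("point", {"value": 7.158}),
            "fir": DistributionSpec("point", {"value": ep.fir}),
            "wab": DistributionSpec("point", {"value": ep.wab}),
        })
        thq, ilcr = run_mc(pb_summary, ep, analytes["Pb"], cfg)
        expected = compute_thq(7.158, ep, analytes["Pb"])
        assert np.all(thq.draws == expected)
        assert len(set(thq.percentile_values.values())) == 1
        assert np.all(ilcr.draws == ilcr.draws[0])

    def test_seeded_determinism_bit_identical(self, ep, analytes, pb_summary):
        cfg = default_mc_config(pb_summary, ep, seed=123, n_iter=1000)
        a = run_mc(pb_summary, ep, analytes["Pb"], cfg)[0]
        b = run_mc(pb_summary, ep, analytes["Pb"], cfg)[0]
        assert np.array_equal(a.draws, b.draws)

    def test_p95_converges_to_analytic_quantile(self, ep, analytes, pb_summary):
        """THQ is linear in c, so p95(THQ) -> THQ(mu + z95*sigma)."""
        cfg = default_mc_config(pb_summary, ep, seed=7, n_iter=10**5)
        res = run_mc(pb_summary, ep, analytes["Pb"], cfg)[0]
        analytic = compute_thq(7.158 + Z95 * 0.248, ep, analytes["Pb"])
        assert res.percentile_values[95.0] == pytest.approx(analytic, rel=0.01)

    def test_mean_preserved_under_linearity(self, ep, analytes, pb_summary):
        cfg = default_mc_config(pb_summary, ep, seed=11, n_iter=10**5)
        res = run_mc(pb_summary, ep, analytes["Pb"], cfg)[0]
        assert res.mean == pytest.approx(
            compute_thq(pb_summary.mean, ep, analytes["Pb"]), rel=0.01
        )

    def test_cd_has_no_ilcr_output(self, ep, analytes, cd_summary):
        cfg = default_mc_config(cd_summary, ep, seed=2, n_iter=100)
        results = run_mc(cd_summary, ep, analytes["Cd"], cfg)
        assert [r.variable for r in results] == ["thq"]

    def test_sampled_fir_wab_path(self, ep, analytes, pb_summary):
        cfg = MCConfig(seed=3, n_iter=400, specs={
            "concentration": DistributionSpec("normal", {"mean": 7.158, "sd": 0.248}),
            "fir": DistributionSpec("uniform", {"low": 20.0, "high": 30.0}),
            "wab": DistributionSpec("normal", {"mean": 70.0, "sd": 5.0}),
        })
        thq, ilcr = run_mc(pb_summary, ep, analytes["Pb"], cfg)
        assert thq.draws.shape == (400,)
        assert (thq.draws > 0).all() and (ilcr.draws > 0).all()
        # paper-mode ILCR draws are EDI(µg) * CSF, i.e. 1000x the strict ones
        strict = run_mc(pb_summary, ep, analytes["Pb"], cfg, ilcr_mode="strict")[1]
        assert np.allclose(ilcr.draws, 1000.0 * strict.draws)

    def test_missing_concentration_spec_errors(self, ep, analytes, pb_summary):
        with pytest.raises(ConfigError, match="concentration"):
            run_mc(pb_summary, ep, analytes["Pb"], MCConfig(seed=1, specs={}))

    def test_variability_mode_uses_sd(self, ep, analytes, pb_summary):
        cfg = default_mc_config(pb_summary, ep, seed=5, n_iter=4000, uncertainty="sd")
        res = run_mc(pb_summary, ep, analytes["Pb"], cfg)[0]
        se_res = run_mc(
            pb_summary, ep, analytes["Pb"],
            default_mc_config(pb_summary, ep, seed=5, n_iter=4000),
        )[0]
        assert res.draws.std() > 3 * se_res.draws.std()
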