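"""Monte Carlo EDI/ILCR machinery: arithmetic, percentiles, classification."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pcbrisk.congeners import CONGENERS, Congener
from pcbrisk.distributions import DistributionSpec, MomentSpec, fit_lognormal_moments
from pcbrisk.errors import DataError, InvalidParameterError
from pcbrisk.exposure import (
    ExposureConfig,
    calibrate_exposure,
    compare_tdi,
    compute_edi,
    compute_ilcr,
    congener_contributions,
    run_mcs,
)


class TestComputeEdi:
    def test_zero_concentration(self):
        assert compute_edi(0.0, 0.03, 100.0, 365.0, 70.0, 70.0, 25550.0) == 0.0

    def test_cancellation_identity(self):
        # ef*ed == at and fat*ir/bw == 1 leaves EDI equal to the concentration
        c = 7.31
        assert compute_edi(c, 0.5, 140.0, 365.0, 10.0, 70.0, 3650.0) == pytest.approx(c)

    def test_matches_independent_arithmetic(self):
        rng = np.random.default_rng(1)
        oracle = lambda c, f, ir, ef, ed, bw, at: c * f * ir * ef * ed / (bw * at)
        for _ in range(20):
            args = rng.uniform(0.01, 100.0, size=7)
            assert compute_edi(*args) == pytest.approx(oracle(*args), rel=1e-12)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(InvalidParameterError):
            compute_edi(1.0, 0.03, 100.0, 365.0, 70.0, 0.0, 25550.0)


class TestRunMcs:
    def _point_model(self, value=1.0):
        return {c: DistributionSpec.point(value) for c in CONGENERS}

    def test_point_masses_give_flat_percentiles(self):
        dist = run_mcs(
            self._point_model(2.0), ExposureConfig.from_multiplier(0.5),
            n_iter=2000, seed=0,
        )
        tab = dist.percentiles
        assert (tab.nunique() == 1).all()
        assert tab["total"].iloc[0] == pytest.approx(6.0)  # 6 congeners * 2 * 0.5

    def test_median_matches_lognormal_quantile(self):
        # single-congener model with known log-scale parameters
        params = fit_lognormal_moments(4.0, 1.5)
        model = {Congener.PCB28: DistributionSpec.lognormal(4.0, 1.5)}
        k = 0.3
        n = 100_000
        dist = run_mcs(model, ExposureConfig.from_multiplier(k), n_iter=n, seed=2)
        median_theory = k * math.exp(params.mu)
        f = sps.lognorm.pdf(math.exp(params.mu), s=params.sigma, scale=math.exp(params.mu))
        se = k * math.sqrt(0.25 / n) / f
        obs = float(dist.percentiles.loc[50, Congener.PCB28.value])
        assert abs(obs - median_theory) < 3.0 * se

    def test_total_dominates_each_congener(self, survey):
        specs = {
            c: MomentSpec(
                mean=float(survey[c.value].mean()),
                sd=float(survey[c.value].std(ddof=1)),
                minimum=float(survey[c.value].min()),
                maximum=float(survey[c.value].max()),
            )
            for c in CONGENERS
        }
        dist = run_mcs(specs, ExposureConfig.from_multiplier(1.0), n_iter=5000, seed=3)
        for c in CONGENERS:
            assert (dist.percentiles["total"] >= dist.percentiles[c.value] - 1e-12).all()
        assert dist.percentiles["total"].is_monotonic_increasing
        assert np.allclose(dist.total, np.sum(list(dist.per_congener.values()), axis=0))

    def test_seeded_reproducibility(self):
        model = self._point_model()
        a = run_mcs(model, ExposureConfig.from_multiplier(1.0), n_iter=1500, seed=5)
        b = run_mcs(model, ExposureConfig.from_multiplier(1.0), n_iter=1500, seed=5)
        pd.testing.assert_frame_equal(a.percentiles, b.percentiles)

    def test_doubling_concentration_doubles_percentiles(self):
        m1 = {c: DistributionSpec.lognormal(2.0, 0.5) for c in CONGENERS}
        m2 = {c: DistributionSpec.lognormal(4.0, 1.0) for c in CONGENERS}
        a = run_mcs(m1, ExposureConfig.from_multiplier(1.0), n_iter=20_000, seed=6)
        b = run_mcs(m2, ExposureConfig.from_multiplier(1.0), n_iter=20_000, seed=6)
        ratio = b.percentiles / a.percentiles
        assert np.allclose(ratio.to_numpy(), 2.0, rtol=0.02)

    def test_small_n_iter_warns(self):
        with pytest.warns(UserWarning, match="n_iter"):
            run_mcs(self._point_model(), ExposureConfig.from_multiplier(1.0),
                    n_iter=100, seed=0)


class TestCalibrateExposure:
    def test_identity(self):
        assert calibrate_exposure(15.0, 15.0) == pytest.approx(1.0)

    def test_reference_yogurt_multiplier(self):
        assert calibrate_exposure(14.65, 14.3) == pytest.approx(0.9761, abs=1e-4)

    def test_reference_doogh_multiplier(self):
        assert calibrate_exposure(12.21, 1.01) == pytest.approx(0.0827, abs=1e-4)

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidParameterError):
            calibrate_exposure(0.0, 1.0)


class TestContributions:
    def _dist(self, values):
        model = {c: DistributionSpec.point(v) if v > 0 else None
                 for c, v in zip(CONGENERS, values)}
        model = {c: spec for c, spec in model.items() if spec is not None}
        return run_mcs(model, ExposureConfig.from_multiplier(1.0), n_iter=1000, seed=0)

    def test_single_congener_takes_all(self):
        dist = self._dist([0, 0, 0, 0, 0, 3.0])
        fracs = congener_contributions(dist)
        assert fracs[Congener.PCB180] == pytest.approx(1.0)

    def test_equal_point_masses_split_evenly(self):
        dist = self._dist([1.0] * 6)
        fracs = congener_contributions(dist)
        for f in fracs.values():
            assert f == pytest.approx(1.0 / 6.0)
        assert sum(fracs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_survey_means_make_pcb180_dominant(self):
        dist = self._dist([0.09, 0.19, 0.10, 0.48, 4.33, 9.98])
        fracs = congener_contributions(dist)
        assert fracs[Congener.PCB180] == pytest.approx(9.98 / 15.17, abs=1e-9)
        assert max(fracs, key=fracs.get) == Congener.PCB180


class TestIlcrTdi:
    def test_zero_exposure_zero_risk(self):
        res = compute_ilcr(np.zeros(100))
        assert (res.ilcr_draws == 0.0).all()
        assert res.classification == "acceptable"

    def test_reference_median_risk(self):
        # yogurt's reported median total intake, 14.3 ng/kg/day, at SF = 2
        res = compute_ilcr(np.full(10, 14.3), sf=2.0)
        assert res.ilcr_mean == pytest.approx(2.86e-5)
        assert res.classification == "acceptable"

    def test_gross_exceedance_flagged(self):
        res = compute_ilcr(np.full(10, 100_000.0), sf=2.0)
        assert res.ilcr_mean == pytest.approx(0.2)
        assert res.classification == "unacceptable"

    def test_sf_linearity(self):
        edi = np.random.default_rng(0).uniform(0.1, 20.0, size=1000)
        a = compute_ilcr(edi, sf=2.0)
        b = compute_ilcr(edi, sf=4.0)
        assert np.allclose(b.ilcr_draws, 2.0 * a.ilcr_draws)

    def test_negative_edi_rejected(self):
        with pytest.raises(DataError):
            compute_ilcr(np.array([-1.0]))

    @pytest.mark.parametrize(
        "edi,below",
        [(0.509, True), (10.0, False), (14.3, False)],
    )
    def test_tdi_comparison(self, edi, below):
        assert compare_tdi(edi) is below
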