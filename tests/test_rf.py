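"""RF link-budget equations, attenuation model, and the synthetic reading protocol."""

import math

import numpy as np
import pytest
from scipy import stats

from ospelm.exceptions import ConfigurationError, DomainError
from ospelm.rf import (
    AttenuationModel,
    DriftSpec,
    RFLinkParams,
    ScenarioRanges,
    TreeScenario,
    backscatter_power,
    effective_wood_path,
    friis_received_power,
    generate_dataset,
    load_reference_measurements,
    max_read_distance,
    mc_to_tau,
    simulate_reading,
    to_dbm,
)


class TestFriis:
    def test_constructed_identity(self):
        # lambda = 4*pi makes lambda^2/(16 pi^2 d^2) = 1 at d = 1
        p = RFLinkParams(ptx=1, gtx=1, gtag=1, wavelength=4 * math.pi, sensitivity=1)
        assert friis_received_power(p, 1.0) == pytest.approx(1.0, rel=1e-15)

    def test_inverse_square(self, link_params):
        for d in (0.2, 1.0, 3.7):
            assert friis_received_power(link_params, 2 * d) == pytest.approx(
                friis_received_power(link_params, d) / 4.0, rel=1e-12
            )

    def test_closed_form_oracle(self):
        # independent hand evaluation of lambda^2 / (16 pi^2) at unit everything
        p = RFLinkParams(ptx=1, gtx=1, gtag=1, wavelength=0.328, sensitivity=1)
        expected = 0.328**2 / (16.0 * math.pi**2)
        assert friis_received_power(p, 1.0) == pytest.approx(expected, rel=1e-14)

    def test_nonpositive_distance_rejected(self, link_params):
        with pytest.raises(DomainError):
            friis_received_power(link_params, 0.0)
        with pytest.raises(DomainError):
            friis_received_power(link_params, -1.0)


class TestMaxReadDistance:
    def test_inverts_friis(self, link_params):
        d_m = max_read_distance(link_params)
        assert friis_received_power(link_params, d_m) == pytest.approx(
            link_params.sensitivity, rel=1e-12
        )

    def test_constructed_identity(self):
        p = RFLinkParams(ptx=1, gtx=1, gtag=1, wavelength=4 * math.pi, sensitivity=1)
        assert max_read_distance(p) == pytest.approx(1.0, rel=1e-15)

    def test_sqrt_power_scaling(self, link_params):
        quad = RFLinkParams(
            ptx=4 * link_params.ptx,
            gtx=link_params.gtx,
            gtag=link_params.gtag,
            wavelength=link_params.wavelength,
            sensitivity=link_params.sensitivity,
        )
        assert max_read_distance(quad) == pytest.approx(2 * max_read_distance(link_params), rel=1e-12)

    def test_zero_sensitivity_rejected(self):
        with pytest.raises(DomainError):
            RFLinkParams(sensitivity=0.0)


class TestBackscatter:
    def test_tau_zero_gives_zero(self, link_params):
        assert backscatter_power(link_params, 0.5, 0.0) == 0.0

    def test_inverse_fourth_power(self, link_params):
        for d in (0.3, 1.0, 2.5):
            ratio = backscatter_power(link_params, d, 0.7) / backscatter_power(link_params, 2 * d, 0.7)
            assert ratio == pytest.approx(16.0, rel=1e-12)

    def test_closed_form_oracle(self):
        p = RFLinkParams(ptx=2.0, gtx=3.0, gtag=1.5, wavelength=0.3, sensitivity=1e-9)
        d, tau = 0.8, 0.6
        expected = 2.0 * (1.5 * 3.0 * 0.3**2 / (4 * math.pi * d) ** 2) ** 2 * tau
        assert backscatter_power(p, d, tau) == pytest.approx(expected, rel=1e-14)

    def test_tau_out_of_range_rejected(self, link_params):
        for tau in (-0.1, 1.1):
            with pytest.raises(DomainError):
                backscatter_power(link_params, 1.0, tau)


class TestMcToTau:
    def test_dry_wood_gives_impedance_match(self, attenuation):
        s = TreeScenario(mc=0.0, distance=0.5, humidity=50, dbh=0.2)
        assert mc_to_tau(s, attenuation) == attenuation.impedance_match

    def test_monotone_in_mc_and_dbh(self, attenuation):
        taus_mc = [
            mc_to_tau(TreeScenario(mc=mc, distance=0.5, humidity=50, dbh=0.2), attenuation)
            for mc in (0.0, 0.1, 0.2, 0.4)
        ]
        assert all(a >= b for a, b in zip(taus_mc, taus_mc[1:]))
        taus_dbh = [
            mc_to_tau(TreeScenario(mc=0.2, distance=0.5, humidity=50, dbh=dbh), attenuation)
            for dbh in (0.1, 0.2, 0.3)
        ]
        assert all(a >= b for a, b in zip(taus_dbh, taus_dbh[1:]))

    def test_through_diameter_closed_form(self):
        # path_saturation=None reduces to exp(-kappa * mc * dbh) exactly
        m = AttenuationModel(kappa_mc=40.0, impedance_match=1.0, path_saturation=None)
        s = TreeScenario(mc=0.2, distance=0.5, humidity=50, dbh=0.16)
        assert mc_to_tau(s, m) == pytest.approx(math.exp(-1.28), rel=1e-14)

    def test_saturating_path_closed_form(self):
        assert effective_wood_path(0.2, 0.05) == pytest.approx(0.05 * (1 - math.exp(-4.0)), rel=1e-14)
        assert effective_wood_path(0.2, None) == 0.2

    def test_always_in_unit_interval(self, attenuation):
        rng = np.random.default_rng(0)
        for _ in range(200):
            s = TreeScenario(
                mc=rng.uniform(0, 0.99),
                distance=rng.uniform(0.1, 5),
                humidity=rng.uniform(0, 100),
                dbh=rng.uniform(0.05, 1.0),
            )
            assert 0.0 < mc_to_tau(s, attenuation) <= 1.0


class TestToDbm:
    @pytest.mark.parametrize("watts,dbm", [(1e-3, 0.0), (1.0, 30.0), (1e-6, -30.0)])
    def test_reference_points(self, watts, dbm):
        assert to_dbm(watts) == pytest.approx(dbm, abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            to_dbm(0.0)


class TestSimulateReading:
    def test_zero_noise_matches_closed_form(self, scenario, link_params, attenuation):
        s = simulate_reading(scenario, link_params, attenuation, noise_halfwidth=0.0, rng_seed=0)
        expected_control = to_dbm(
            backscatter_power(link_params, scenario.distance, attenuation.impedance_match)
        )
        tau = mc_to_tau(scenario, attenuation)
        expected_sensing = (
            to_dbm(backscatter_power(link_params, scenario.distance, tau))
            + attenuation.humidity_coeff * scenario.humidity
        )
        assert s.rssi_control == pytest.approx(expected_control, abs=1e-12)
        assert s.rssi_sensing == pytest.approx(expected_sensing, abs=1e-12)

    def test_seed_determinism(self, scenario, link_params, attenuation):
        a = simulate_reading(scenario, link_params, attenuation, rng_seed=7)
        b = simulate_reading(scenario, link_params, attenuation, rng_seed=7)
        assert a == b

    def test_sensing_attenuated_below_control(self, scenario, link_params, attenuation):
        s = simulate_reading(scenario, link_params, attenuation, noise_halfwidth=0.0, rng_seed=0)
        assert s.rssi_sensing < s.rssi_control

    def test_averaging_noise_contraction(self, scenario, link_params, attenuation):
        """Monte-Carlo oracle: std of a 100-read average is ~1/10 of a single read."""
        single, avg = [], []
        for seed in range(1000):
            single.append(
                simulate_reading(scenario, link_params, attenuation, n_reads=1, rng_seed=seed).rssi_sensing
            )
            avg.append(
                simulate_reading(
                    scenario, link_params, attenuation, n_reads=100, rng_seed=10_000 + seed
                ).rssi_sensing
            )
        ratio = np.std(avg) / np.std(single)
        assert 0.08 <= ratio <= 0.12


class TestGenerateDataset:
    def test_cardinality(self, stream_1000):
        assert len(stream_1000) == 1000
        assert [s.timestamp_index for s in stream_1000] == list(range(1000))

    def test_seed_determinism(self):
        a = generate_dataset(50, rng_seed=5)
        b = generate_dataset(50, rng_seed=5)
        assert a == b

    def test_degenerate_mc_range(self):
        ranges = ScenarioRanges(mc=(0.25, 0.25))
        samples = generate_dataset(30, scenario_ranges=ranges, drift_spec=DriftSpec.none(), rng_seed=1)
        assert all(s.scenario.mc == 0.25 for s in samples)

    def test_no_drift_marginals_stationary(self):
        """With drift disabled, first and second half of the stream have the
        same scenario marginals (KS test on the aggregate of many seeds)."""
        hum_first, hum_second = [], []
        for seed in range(100):
            samples = generate_dataset(
                100, drift_spec=DriftSpec.none(), rng_seed=seed, n_reads=1, noise_halfwidth=0.0
            )
            hum = [s.scenario.humidity for s in samples]
            hum_first.extend(hum[:50])
            hum_second.extend(hum[50:])
        assert stats.ks_2samp(hum_first, hum_second).pvalue > 0.01

    def test_drift_shifts_late_stream(self):
        samples = generate_dataset(400, rng_seed=3)
        hum = np.array([s.scenario.humidity for s in samples])
        assert hum[300:].mean() > hum[:100].mean()

    def test_invalid_n_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_dataset(0, rng_seed=1)


class TestReferenceFixture:
    def test_row_count(self):
        assert len(load_reference_measurements()) == 10

    def test_first_row_values(self):
        r = load_reference_measurements()[0]
        assert r.scenario.mc == pytest.approx(0.148)
        assert r.scenario.distance == 0.3
        assert r.scenario.humidity == 54.0
        assert r.scenario.dbh == 0.16
        assert r.rssi_sensing == -10.05

    def test_far_distance_row(self):
        rows = [
            r for r in load_reference_measurements()
            if r.scenario.mc == pytest.approx(0.408) and r.scenario.distance == 0.6
        ]
        assert len(rows) == 1
        assert rows[0].rssi_sensing == -27.34

    def test_control_rssi_flagged_missing(self):
        assert all(r.rssi_control is None for r in load_reference_measurements())
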