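"""Steady-state relaxation-rate extraction, BVf/VSI, and mqBOLD StO2."""

import math

import numpy as np
import pytest

from mrvf.geometry import build_microvessel_geometry
from mrvf.physics import Physics
from mrvf.sequence import SequenceParams, SignalTrain, simulate_pair
from mrvf.steadystate import (
    bvf_steadystate,
    delta_r2,
    delta_r2star,
    mge_signal,
    qbold_rate,
    qbold_sto2,
    steadystate_maps,
    t2_fit,
    vsi,
)

PHYS = Physics()
SEQ = SequenceParams()
TIMES = np.asarray(SEQ.echo_times)


def _pair_from_rates(dr2s: float, dr2_val: float) -> tuple[SignalTrain, SignalTrain]:
    """Synthetic pre/post pair with exact log-linear contrast decay."""
    pre = np.exp(-TIMES / 80.0)
    post = pre.copy()
    fid = TIMES < SEQ.refocus_time
    post[fid] *= np.exp(-dr2s * TIMES[fid] * 1e-3)
    post[~fid] *= np.exp(-dr2_val * TIMES[~fid] * 1e-3)
    return SignalTrain(TIMES, pre, "pre"), SignalTrain(TIMES, post, "post")


class TestRateExtraction:
    def test_exact_log_linear_input_recovered(self):
        pre, post = _pair_from_rates(50.0, 20.0)
        assert delta_r2star(pre, post, SEQ) == pytest.approx(50.0, rel=1e-10)
        assert delta_r2(pre, post, SEQ) == pytest.approx(20.0, rel=1e-10)

    def test_identical_arms_give_zero(self):
        s = np.exp(-TIMES / 60.0)
        pre = SignalTrain(TIMES, s, "pre")
        post = SignalTrain(TIMES, s.copy(), "post")
        assert delta_r2star(pre, post, SEQ) == pytest.approx(0.0, abs=1e-12)
        assert delta_r2(pre, post, SEQ) == pytest.approx(0.0, abs=1e-12)

    def test_non_positive_signal_excluded(self):
        s = np.ones_like(TIMES)
        bad = s.copy()
        bad[3] = 0.0
        assert math.isnan(
            delta_r2star(SignalTrain(TIMES, bad), SignalTrain(TIMES, s, "post"), SEQ)
        )

    def test_simulated_small_vessels_diffusion_narrowing_ordering(self, seq, physics):
        # with water diffusion, the spin echo recovers part of the dephasing:
        # dR2 < dR2*
        g = build_microvessel_geometry(0.05, 5.0, 96, 128, seed=3)
        pre, post = simulate_pair(g, 800.0, seq, physics, sto2=0.8)
        dr2s = delta_r2star(pre, post, seq)
        dr2v = delta_r2(pre, post, seq)
        assert 0 < dr2v < dr2s

    def test_simulated_dr2star_near_static_dephasing_plateau(self, seq, physics):
        # dR2* ~ BVf * gamma*B0*dchi_SI/3 for radii in the static regime
        g = build_microvessel_geometry(0.05, 5.0, 96, 128, seed=3)
        pre, post = simulate_pair(g, 800.0, seq, physics, sto2=0.8)
        dr2s = delta_r2star(pre, post, seq)
        plateau = 0.05 * physics.gamma * physics.b0 * physics.delta_chi_uspio_ppm * 1e-6 / 3
        assert dr2s == pytest.approx(plateau, rel=0.25)


class TestBvfVsi:
    def test_zero_rate_zero_bvf(self):
        assert bvf_steadystate(0.0, PHYS) == 0.0

    def test_algebraic_round_trip(self):
        # bvf_steadystate inverts the static-dephasing forward relation
        for x in (0.01, 0.05, 0.16):
            dr2s = x * PHYS.gamma * PHYS.b0 * PHYS.delta_chi_uspio_ppm * 1e-6 / 3.0
            assert bvf_steadystate(dr2s, PHYS) == pytest.approx(x, rel=1e-12)

    def test_vsi_hand_computed_case(self):
        # dR2*=48.4, dR2=16.6, ADC=800: sqrt(4*pi*800/4400.41)*0.867=1.31047
        # * (48.4/16.6)^1.5 = 4.97823 -> 6.524 um (computed by hand beforehand)
        out = vsi(48.4, 16.6, 800.0, PHYS)
        gb = PHYS.gamma * PHYS.b0 * PHYS.delta_chi_uspio_ppm * 1e-6
        expected = 0.867 * math.sqrt(4 * math.pi * 800.0 / gb) * (48.4 / 16.6) ** 1.5
        assert out == pytest.approx(expected, rel=1e-12)
        assert out == pytest.approx(6.524, abs=2e-3)

    def test_vsi_scales_with_rate_ratio_to_three_halves(self):
        base = vsi(30.0, 15.0, 800.0, PHYS)
        assert vsi(60.0, 15.0, 800.0, PHYS) == pytest.approx(base * 2**1.5)
        assert vsi(30.0, 15.0, 1600.0, PHYS) == pytest.approx(base * math.sqrt(2))

    def test_non_positive_dr2_excluded(self):
        assert math.isnan(float(vsi(30.0, 0.0, 800.0, PHYS)))

    def test_generate_then_fit_round_trip_within_one_percent(self):
        # full pipeline on synthetic log-linear signals
        dr2s_true, dr2_true = 73.34, 18.0
        pre, post = _pair_from_rates(dr2s_true, dr2_true)
        dr2s = delta_r2star(pre, post, SEQ)
        dr2v = delta_r2(pre, post, SEQ)
        bvf = bvf_steadystate(dr2s, PHYS)
        v = vsi(dr2s, dr2v, 800.0, PHYS)
        assert bvf == pytest.approx(bvf_steadystate(dr2s_true, PHYS), rel=0.01)
        assert v == pytest.approx(vsi(dr2s_true, dr2_true, 800.0, PHYS), rel=0.01)


class TestQbold:
    def test_self_inverse_at_known_saturation(self):
        t = np.asarray([4.5 * k for k in range(1, 16)])
        s = mge_signal(t, t2_ms=55.0, bvf=0.035, sto2=0.70, physics=PHYS)
        rec = qbold_sto2(t, s, t2_ms=55.0, bvf=0.035, physics=PHYS)
        assert rec == pytest.approx(0.70, abs=0.01)

    def test_fully_oxygenated_signal_decays_at_pure_t2(self):
        t = np.asarray([4.5 * k for k in range(1, 16)])
        s = mge_signal(t, t2_ms=55.0, bvf=0.035, sto2=1.0, physics=PHYS)
        assert t2_fit(t, s) == pytest.approx(55.0, rel=1e-6)

    def test_hematocrit_mismatch_bias_is_monotone(self):
        # generate at increasing Hct, always fit at the default 0.357:
        # the apparent desaturation grows, so recovered StO2 drops
        t = np.asarray([4.5 * k for k in range(1, 16)])
        rec = []
        for hct in (0.357, 0.39, 0.42):
            gen_phys = Physics(hct_micro=hct)
            s = mge_signal(t, 55.0, 0.035, 0.70, gen_phys)
            rec.append(qbold_sto2(t, s, 55.0, 0.035, PHYS))
        assert rec[0] > rec[1] > rec[2]
        assert rec[0] == pytest.approx(0.70, abs=0.01)

    def test_out_of_range_saturation_excluded(self):
        t = np.asarray([4.5 * k for k in range(1, 16)])
        # decay much slower than T2 alone -> apparent StO2 > 1 -> excluded
        s = np.exp(-t / 200.0)
        assert math.isnan(qbold_sto2(t, s, t2_ms=55.0, bvf=0.035, physics=PHYS))

    def test_invalid_t2_or_bvf_excluded(self):
        t = np.asarray([15.0, 20.0, 25.0])
        s = np.exp(-t / 50.0)
        assert math.isnan(qbold_sto2(t, s, t2_ms=-1.0, bvf=0.03))
        assert math.isnan(qbold_sto2(t, s, t2_ms=50.0, bvf=0.5))

    def test_rate_coefficient_magnitude(self):
        # k = BVf * gamma*B0*dchi0_SI/3 * Hct_micro: a few s^-1 at BVf ~3.5%
        k = qbold_rate(0.035, PHYS)
        assert 10.0 < k < 60.0


class TestVolumeMaps:
    def _synth_volumes(self, bvf_grid, adc_val=800.0):
        shape = bvf_grid.shape
        n_echo = len(TIMES)
        pre = np.ones(shape + (n_echo,))
        post = np.empty_like(pre)
        fid = TIMES < SEQ.refocus_time
        for idx in np.ndindex(shape):
            dr2s = bvf_grid[idx] * PHYS.gamma * PHYS.b0 * PHYS.delta_chi_uspio_ppm * 1e-6 / 3
            dr2v = dr2s / 3.0
            decay = np.where(fid, np.exp(-dr2s * TIMES * 1e-3), np.exp(-dr2v * TIMES * 1e-3))
            post[idx] = decay
        adc = np.full(shape, adc_val)
        return pre, post, adc

    def test_uniform_bvf_volume_recovered(self):
        bvf_grid = np.full((4, 4, 1), 0.05)
        pre, post, adc = self._synth_volumes(bvf_grid)
        maps = steadystate_maps(pre, post, adc, SEQ, PHYS)
        assert np.allclose(maps.bvf, 0.05, rtol=1e-6)
        assert not maps.excluded.any()

    def test_validity_ranges_enforced(self):
        bvf_grid = np.array([[[0.05]], [[0.30]]])  # second voxel beyond 17%
        pre, post, adc = self._synth_volumes(bvf_grid)
        maps = steadystate_maps(pre, post, adc, SEQ, PHYS)
        assert not maps.excluded[0, 0, 0]
        assert maps.excluded[1, 0, 0]

    def test_adc_out_of_range_excluded(self):
        bvf_grid = np.full((1, 1, 1), 0.05)
        pre, post, adc = self._synth_volumes(bvf_grid, adc_val=4000.0)
        maps = steadystate_maps(pre, post, adc, SEQ, PHYS)
        assert maps.excluded.all()

    def test_sto2_map_round_trip(self):
        bvf_grid = np.full((2, 2, 1), 0.05)
        pre, post, adc = self._synth_volumes(bvf_grid)
        t = np.asarray([4.5 * k for k in range(1, 16)])
        mge = np.broadcast_to(
            mge_signal(t, 55.0, 0.05, 0.8, PHYS), (2, 2, 1, 15)
        ).copy()
        t2 = np.full((2, 2, 1), 55.0)
        # mqBOLD uses the *measured* steady-state BVf; here it matches truth
        maps = steadystate_maps(pre, post, adc, SEQ, PHYS, t2_map=t2, mge4d=mge,
                                mge_times_ms=t)
        assert np.allclose(maps.sto2, 0.8, atol=0.02)
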