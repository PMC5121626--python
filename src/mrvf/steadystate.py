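"""Analytic steady-state microvascular maps from the same raw signals.

The USPIO-induced changes in transverse relaxation rates are read off the
pre/post GESFIDE pair: dR2* from the log-linear slope of the FID echoes and
dR2 from the echo closest to the spin-echo time. Blood volume fraction and
vessel size index then follow the steady-state susceptibility-contrast
relations (Delta-chi in SI volume-susceptibility units; the familiar 4*pi
factors of the CGS formulation are folded into the conversion
chi_SI = 4*pi*chi_CGS):

    BVf = 3 * dR2* / (gamma * B0 * dchi_USPIO)
    VSI = 0.867 * sqrt(4*pi * ADC / (gamma * B0 * dchi_USPIO)) * (dR2*/dR2)^{3/2}

Tissue oxygen saturation uses the multiparametric quantitative-BOLD model:
the multi-gradient-echo decay beyond 10 ms is fitted with

    S(t) = Cte * exp(-t/T2) * exp(-BVf * (gamma*B0*dchi0/3) * Hct * (1 - StO2) * t)

taking T2 and BVf from their own maps and solving for (Cte, StO2).
Voxels failing to fit or falling outside the validity ranges
(ADC 0-3500 um^2/s, BVf 0-17%, VSI 0-50 um, StO2 0-100%) are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .physics import Physics, DEFAULT_PHYSICS
from .sequence import SequenceParams, SignalTrain

__all__ = [
    "SteadyStateMaps",
    "VALIDITY_RANGES",
    "delta_r2star",
    "delta_r2",
    "bvf_steadystate",
    "vsi",
    "qbold_rate",
    "mge_signal",
    "qbold_sto2",
    "t2_fit",
    "steadystate_maps",
]

# validity ranges of the analytic methods (exclusion outside)
VALIDITY_RANGES = {
    "adc": (0.0, 3500.0),  # um^2/s
    "bvf": (0.0, 0.17),
    "vsi": (0.0, 50.0),  # um
    "sto2": (0.0, 1.0),
}


def _fid_indices(times: np.ndarray, seq: SequenceParams) -> np.ndarray:
    """FID echoes used for the dR2* slope: echoes 2..8 (first echo skipped as transient)."""
    fid = np.flatnonzero(times < seq.refocus_time)
    return fid[1:] if fid.size > 2 else fid


def delta_r2star(
    pre: SignalTrain,
    post: SignalTrain,
    seq: SequenceParams | None = None,
    echo_indices: np.ndarray | None = None,
) -> float:
    """USPIO-induced change in R2* (1/s): slope of ln(pre/post) over FID echoes."""
    seq = seq or SequenceParams()
    idx = _fid_indices(pre.times, seq) if echo_indices is None else np.asarray(echo_indices)
    p, q = pre.signal[idx], post.signal[idx]
    if np.any(p <= 0) or np.any(q <= 0):
        return float("nan")
    t_s = pre.times[idx] * 1e-3
    y = np.log(p / q)
    slope = np.polyfit(t_s, y, 1)[0]
    return float(slope)


def delta_r2(
    pre: SignalTrain, post: SignalTrain, seq: SequenceParams | None = None
) -> float:
    """USPIO-induced change in R2 (1/s), from the echo nearest the spin-echo time."""
    seq = seq or SequenceParams()
    idx = int(np.argmin(np.abs(pre.times - seq.se_time)))
    p, q = pre.signal[idx], post.signal[idx]
    if p <= 0 or q <= 0:
        return float("nan")
    return float(math.log(p / q) / (pre.times[idx] * 1e-3))


def bvf_steadystate(dr2star: float, physics: Physics = DEFAULT_PHYSICS):
    """Steady-state blood volume fraction, BVf = 3 dR2* / (gamma B0 dchi_SI)."""
    dchi = physics.delta_chi_uspio_ppm * 1e-6
    return 3.0 * np.asarray(dr2star, dtype=float) / (physics.gamma * physics.b0 * dchi)


def vsi(dr2star, dr2, adc, physics: Physics = DEFAULT_PHYSICS):
    """Vessel size index in um.

    VSI = 0.867 * sqrt(4*pi*ADC / (gamma*B0*dchi_SI)) * (dR2*/dR2)^{3/2};
    ADC in um^2/s. Non-positive dR2 yields NaN (excluded voxel).
    """
    dr2star = np.asarray(dr2star, dtype=float)
    dr2 = np.asarray(dr2, dtype=float)
    adc = np.asarray(adc, dtype=float)
    dchi = physics.delta_chi_uspio_ppm * 1e-6
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (
            0.867
            * np.sqrt(4.0 * math.pi * adc / (physics.gamma * physics.b0 * dchi))
            * (dr2star / dr2) ** 1.5
        )
    return np.where(dr2 > 0, out, np.nan)


def qbold_rate(bvf: float, physics: Physics = DEFAULT_PHYSICS) -> float:
    """Deoxyhemoglobin dephasing rate coefficient k (1/s per unit (1-StO2))."""
    dchi0 = physics.delta_chi0_ppm * 1e-6
    return bvf * physics.gamma * physics.b0 * dchi0 / 3.0 * physics.hct_micro


def mge_signal(
    times_ms,
    t2_ms: float,
    bvf: float,
    sto2: float,
    physics: Physics = DEFAULT_PHYSICS,
    cte: float = 1.0,
) -> np.ndarray:
    """Forward quantitative-BOLD multi-gradient-echo decay model."""
    t_s = np.asarray(times_ms, dtype=float) * 1e-3
    k = qbold_rate(bvf, physics)
    return cte * np.exp(-t_s / (t2_ms * 1e-3)) * np.exp(-k * (1.0 - sto2) * t_s)


def qbold_sto2(
    times_ms,
    signal,
    t2_ms: float,
    bvf: float,
    physics: Physics = DEFAULT_PHYSICS,
    fit_min_te_ms: float = 10.0,
) -> float:
    """Fit StO2 from a multi-gradient-echo decay beyond 10 ms echo time.

    Returns NaN (excluded) when the fit fails or StO2 leaves [0, 1].
    """
    if t2_ms <= 0 or not 0.0 < bvf <= VALIDITY_RANGES["bvf"][1]:
        return float("nan")
    times_ms = np.asarray(times_ms, dtype=float)
    signal = np.asarray(signal, dtype=float)
    win = times_ms > fit_min_te_ms
    t = times_ms[win]
    s = signal[win]
    if t.size < 3 or np.any(s <= 0):
        return float("nan")
    k = qbold_rate(bvf, physics)
    r2_0 = 1.0 / (t2_ms * 1e-3)

    # log-linear solution seeds the nonlinear fit
    slope, intercept = np.polyfit(t * 1e-3, np.log(s), 1)
    sto2_seed = float(np.clip(1.0 - (-slope - r2_0) / k, -0.5, 1.5))

    def model(tm, cte, sto2):
        return cte * np.exp(-(r2_0 + k * (1.0 - sto2)) * tm * 1e-3)

    try:
        popt, _ = curve_fit(
            model, t, s, p0=[float(np.exp(intercept)), sto2_seed], maxfev=2000
        )
    except RuntimeError:
        return float("nan")
    sto2 = float(popt[1])
    lo, hi = VALIDITY_RANGES["sto2"]
    if not lo <= sto2 <= hi:
        return float("nan")
    return sto2


def t2_fit(times_ms, signal) -> float:
    """Mono-exponential T2 (ms) from a multi-spin-echo series (log-linear fit)."""
    times_ms = np.asarray(times_ms, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if np.any(signal <= 0):
        return float("nan")
    slope = np.polyfit(times_ms, np.log(signal), 1)[0]
    if slope >= 0:
        return float("nan")
    return float(-1.0 / slope)


@dataclass
class SteadyStateMaps:
    """Voxel-wise analytic maps; NaN marks unmappable voxels."""

    delta_r2: np.ndarray
    delta_r2_star: np.ndarray
    bvf: np.ndarray
    vsi: np.ndarray
    sto2: np.ndarray | None
    excluded: np.ndarray
    extra: dict = field(default_factory=dict)

    def named_maps(self) -> dict[str, np.ndarray]:
        maps = {
            "delta_r2": self.delta_r2,
            "delta_r2_star": self.delta_r2_star,
            "bvf_ss": self.bvf,
            "vsi": self.vsi,
            "excluded_ss": self.excluded.astype(np.uint8),
        }
        if self.sto2 is not None:
            maps["sto2_qbold"] = self.sto2
        maps.update(self.extra)
        return maps


def steadystate_maps(
    pre4d: np.ndarray,
    post4d: np.ndarray,
    adc_map: np.ndarray,
    seq: SequenceParams | None = None,
    physics: Physics = DEFAULT_PHYSICS,
    t2_map: np.ndarray | None = None,
    mge4d: np.ndarray | None = None,
    mge_times_ms=None,
) -> SteadyStateMaps:
    """Steady-state BVf/VSI (and mqBOLD StO2 if MGE data are given) maps."""
    seq = seq or SequenceParams()
    pre4d = np.asarray(pre4d, dtype=float)
    post4d = np.asarray(post4d, dtype=float)
    if pre4d.shape != post4d.shape:
        raise ValueError("pre and post volumes must share a shape")
    shape3 = pre4d.shape[:3]
    if adc_map.shape != shape3:
        raise ValueError("ADC map grid does not match the echo volumes")
    times = np.asarray(seq.echo_times[: pre4d.shape[3]])
    fid_idx = _fid_indices(times, seq)
    se_idx = int(np.argmin(np.abs(times - seq.se_time)))

    p = pre4d.reshape(-1, pre4d.shape[3])
    q = post4d.reshape(-1, pre4d.shape[3])
    ok = np.all(p[:, fid_idx] > 0, axis=1) & np.all(q[:, fid_idx] > 0, axis=1)
    ok &= (p[:, se_idx] > 0) & (q[:, se_idx] > 0)

    dr2s = np.full(p.shape[0], np.nan)
    dr2 = np.full(p.shape[0], np.nan)
    t_s = times[fid_idx] * 1e-3
    if np.any(ok):
        y = np.log(p[ok][:, fid_idx] / q[ok][:, fid_idx])
        A = np.vstack([t_s, np.ones_like(t_s)]).T
        coef, *_ = np.linalg.lstsq(A, y.T, rcond=None)
        dr2s[ok] = coef[0]
        dr2[ok] = np.log(p[ok, se_idx] / q[ok, se_idx]) / (times[se_idx] * 1e-3)

    bvf = bvf_steadystate(dr2s, physics)
    vsi_map = vsi(dr2s, dr2, adc_map.reshape(-1), physics)

    sto2 = None
    if mge4d is not None:
        if t2_map is None or mge_times_ms is None:
            raise ValueError("mqBOLD StO2 needs both t2_map and mge_times_ms")
        mge = np.asarray(mge4d, dtype=float).reshape(-1, mge4d.shape[3])
        t2_flat = np.asarray(t2_map, dtype=float).reshape(-1)
        sto2 = np.full(p.shape[0], np.nan)
        for i in range(p.shape[0]):
            if ok[i] and np.isfinite(bvf[i]):
                sto2[i] = qbold_sto2(mge_times_ms, mge[i], t2_flat[i], bvf[i], physics)

    excl = ~ok
    adc_flat = np.asarray(adc_map, dtype=float).reshape(-1)
    for arr, key in ((adc_flat, "adc"), (bvf, "bvf"), (vsi_map, "vsi")):
        lo, hi = VALIDITY_RANGES[key]
        excl |= ~np.isfinite(arr) | (arr < lo) | (arr > hi)
    if sto2 is not None:
        excl |= ~np.isfinite(sto2)

    return SteadyStateMaps(
        delta_r2=dr2.reshape(shape3),
        delta_r2_star=dr2s.reshape(shape3),
        bvf=np.asarray(bvf).reshape(shape3),
        vsi=np.asarray(vsi_map).reshape(shape3),
        sto2=None if sto2 is None else sto2.reshape(shape3),
        excluded=excl.reshape(shape3),
    )
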