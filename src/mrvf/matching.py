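"""Fingerprint construction and dictionary matching.

A voxel's fingerprint is the echo-wise ratio of its post- and pre-contrast
GESFIDE magnitudes (post/pre by default, configurable), with the last eight
echoes dropped for SNR. Because the ratio divides out any multiplicative
factor shared by the two acquisitions, it is insensitive to macroscopic B0,
B1 and microscopic T2 -- only susceptibility-driven mesoscopic dephasing
remains.

Matching is an exhaustive search: the dictionary row minimizing the reduced
chi-squared sum((fp - row)^2)/(n - 1) (unit variance weights, so the ranking
equals the SSE; first minimum wins on ties) yields the voxel's BVf, radius,
StO2 and, for large-vessel entries, orientation. Goodness of fit is reported
as r^2 = 1 - SS_res/SS_tot against the selected row, and map voxels with
r^2 below threshold (default 0.8) are excluded from ROI statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve

from .dictionary import Dictionary, restrict_to_adc
from .sequence import SignalTrain

__all__ = [
    "Fingerprint",
    "MatchResult",
    "ParametricMaps",
    "make_fingerprint",
    "smooth_inplane",
    "match_voxel",
    "match_volume",
]

R2_EXCLUDED = -np.inf  # sentinel for voxels that could not be matched


@dataclass
class Fingerprint:
    ratio: np.ndarray
    echo_times: np.ndarray
    n_dropped_tail: int = 8
    valid: bool = True

    def __post_init__(self) -> None:
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)


@dataclass
class MatchResult:
    bvf: float = np.nan
    radius_um: float = np.nan
    sto2: float = np.nan
    delta_chi_ppm: float = np.nan
    orientation_deg: float = np.nan
    adc_plane: float = np.nan
    r2: float = R2_EXCLUDED
    chi2: float = np.nan
    entry_index: int = -1

    @property
    def excluded(self) -> bool:
        return self.entry_index < 0


def make_fingerprint(
    pre: SignalTrain,
    post: SignalTrain,
    n_drop: int = 8,
    convention: str = "post_over_pre",
) -> Fingerprint:
    """Echo-wise signal ratio with the noisy tail echoes removed."""
    if pre.times.shape != post.times.shape or not np.allclose(pre.times, post.times):
        raise ValueError("pre and post arms must share echo times")
    if convention not in ("post_over_pre", "pre_over_post"):
        raise ValueError(f"unknown ratio convention {convention!r}")
    keep = slice(0, len(pre.times) - n_drop) if n_drop else slice(None)
    p, q = pre.signal[keep], post.signal[keep]
    times = pre.times[keep]
    denom, numer = (p, q) if convention == "post_over_pre" else (q, p)
    if np.any(denom <= 0) or not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        return Fingerprint(np.full(times.shape, np.nan), times, n_drop, valid=False)
    return Fingerprint(numer / denom, times, n_drop, valid=True)


def _gaussian_kernel_3x3(sigma: float) -> np.ndarray:
    g = np.exp(-0.5 * (np.arange(-1, 2) / sigma) ** 2)
    k = np.outer(g, g)
    return k / k.sum()


def smooth_inplane(volume: np.ndarray, sigma: float = 0.8) -> np.ndarray:
    """Per-slice, per-echo convolution with a unit-sum 3x3 Gaussian kernel."""
    volume = np.asarray(volume, dtype=float)
    if volume.shape[0] < 3 or volume.shape[1] < 3:
        raise ValueError("need at least 3x3 in-plane extent")
    kernel = _gaussian_kernel_3x3(sigma)
    out = np.empty_like(volume)
    for z in range(volume.shape[2]):
        for e in range(volume.shape[3]):
            out[:, :, z, e] = convolve(volume[:, :, z, e], kernel, mode="nearest")
    return out


def _result_from_row(dictionary: Dictionary, idx: int, r2: float, chi2: float) -> MatchResult:
    row = dictionary.params.iloc[idx]
    return MatchResult(
        bvf=float(row["bvf"]),
        radius_um=float(row["radius_um"]),
        sto2=float(row["sto2"]),
        delta_chi_ppm=float(row["delta_chi_ppm"]),
        orientation_deg=float(row["orientation_deg"]),
        adc_plane=float(dictionary.manifest.get("adc_plane", row["adc"])),
        r2=r2,
        chi2=chi2,
        entry_index=int(idx),
    )


def match_voxel(
    fp: Fingerprint, dictionary: Dictionary, adc_measured: float | None = None
) -> MatchResult:
    """Best-matching dictionary entry for one fingerprint."""
    if not fp.valid:
        return MatchResult()
    view = dictionary
    if adc_measured is not None and len(dictionary.adc_axis) > 1:
        view = restrict_to_adc(dictionary, adc_measured)
    if fp.ratio.shape[0] != view.entries.shape[1]:
        raise ValueError(
            f"fingerprint length {fp.ratio.shape[0]} does not match dictionary "
            f"row length {view.entries.shape[1]}"
        )
    sstot = float(np.sum((fp.ratio - fp.ratio.mean()) ** 2))
    if sstot == 0.0:
        return MatchResult()  # constant fingerprint: r^2 undefined
    sse = np.sum((view.entries - fp.ratio) ** 2, axis=1)
    best = int(np.argmin(sse))
    n = fp.ratio.shape[0]
    chi2 = float(sse[best]) / (n - 1)
    r2 = 1.0 - float(sse[best]) / sstot
    res = _result_from_row(view, best, r2, chi2)
    if view is not dictionary:
        # map the view row back to the full dictionary's index space
        res.entry_index = int(np.flatnonzero(
            dictionary.params["adc"].to_numpy() == view.manifest["adc_plane"]
        )[best])
    return res


@dataclass
class ParametricMaps:
    """Co-registered microvascular parameter maps plus fit quality."""

    bvf: np.ndarray
    radius_um: np.ndarray
    sto2: np.ndarray
    orientation_deg: np.ndarray
    r2: np.ndarray
    chi2: np.ndarray
    adc_plane: np.ndarray
    entry_index: np.ndarray
    excluded: np.ndarray
    r2_threshold: float = 0.8
    extra: dict = field(default_factory=dict)

    def named_maps(self) -> dict[str, np.ndarray]:
        base = {
            "bvf": self.bvf,
            "radius_um": self.radius_um,
            "sto2": self.sto2,
            "orientation_deg": self.orientation_deg,
            "r2": self.r2,
            "chi2": self.chi2,
            "adc_plane": self.adc_plane,
            "excluded": self.excluded.astype(np.uint8),
        }
        base.update(self.extra)
        return base


def match_volume(
    pre4d: np.ndarray,
    post4d: np.ndarray,
    adc_map: np.ndarray | None,
    dictionary: Dictionary,
    r2_threshold: float = 0.8,
    smooth: bool = True,
    smooth_sigma: float = 0.8,
    n_drop: int | None = None,
    convention: str | None = None,
) -> ParametricMaps:
    """Match every voxel of a pre/post multi-echo acquisition.

    Volumes are (nx, ny, nz, n_echoes) magnitude images on a common grid;
    ``adc_map`` selects the dictionary ADC hyperplane per voxel when the
    dictionary carries an ADC axis. Voxels whose fingerprint is invalid
    (non-positive pre-contrast signal) or whose best fit has r^2 below
    ``r2_threshold`` are flagged in the exclusion mask.
    """
    pre4d = np.asarray(pre4d, dtype=float)
    post4d = np.asarray(post4d, dtype=float)
    if pre4d.shape != post4d.shape:
        raise ValueError(
            f"pre volume shape {pre4d.shape} does not match post volume shape {post4d.shape}"
        )
    if adc_map is not None and adc_map.shape != pre4d.shape[:3]:
        raise ValueError(
            f"ADC map shape {adc_map.shape} does not match volume grid {pre4d.shape[:3]}"
        )
    n_drop = dictionary.manifest.get("n_drop", 8) if n_drop is None else n_drop
    convention = convention or dictionary.manifest.get("ratio_convention", "post_over_pre")
    if smooth:
        pre4d = smooth_inplane(pre4d, smooth_sigma)
        post4d = smooth_inplane(post4d, smooth_sigma)
    n_keep = pre4d.shape[3] - n_drop
    if n_keep != dictionary.entries.shape[1]:
        raise ValueError(
            f"{n_keep} kept echoes vs dictionary row length {dictionary.entries.shape[1]}"
        )
    shape3 = pre4d.shape[:3]
    p = pre4d[..., :n_keep].reshape(-1, n_keep)
    q = post4d[..., :n_keep].reshape(-1, n_keep)
    if convention == "pre_over_post":
        p, q = q, p
    with np.errstate(divide="ignore", invalid="ignore"):
        fp = q / p
    valid = np.all(p > 0, axis=1) & np.all(np.isfinite(fp), axis=1)
    sstot = np.sum((fp - fp.mean(axis=1, keepdims=True)) ** 2, axis=1)
    valid &= sstot > 0

    nvox = p.shape[0]
    out = {
        name: np.full(nvox, np.nan)
        for name in ("bvf", "radius_um", "sto2", "orientation_deg", "chi2", "adc_plane")
    }
    r2 = np.full(nvox, R2_EXCLUDED)
    entry_index = np.full(nvox, -1, dtype=np.int64)

    adc_axis = dictionary.adc_axis
    adc_flat = None if adc_map is None else np.asarray(adc_map, dtype=float).reshape(-1)
    if adc_flat is not None and len(adc_axis) > 1:
        plane_of = np.argmin(np.abs(adc_flat[:, None] - adc_axis[None, :]), axis=1)
    else:
        plane_of = np.zeros(nvox, dtype=int)
        adc_axis = np.asarray([float(dictionary.adc_axis[0])])

    adc_col = dictionary.params["adc"].to_numpy()
    pcols = {
        k: dictionary.params[k].to_numpy()
        for k in ("bvf", "radius_um", "sto2", "orientation_deg")
    }
    for i_plane, plane in enumerate(adc_axis):
        vox = np.flatnonzero(valid & (plane_of == i_plane))
        if vox.size == 0:
            continue
        rows = np.flatnonzero(adc_col == plane) if len(adc_axis) > 1 else np.arange(len(adc_col))
        entries = dictionary.entries[rows].astype(float)
        # ||fp - row||^2 = ||fp||^2 - 2 fp.row + ||row||^2, argmin over rows
        row_norm = np.einsum("ij,ij->i", entries, entries)
        f = fp[vox]
        cross = f @ entries.T
        sse_mat = row_norm[None, :] - 2.0 * cross
        best = np.argmin(sse_mat, axis=1)
        sse = (
            np.einsum("ij,ij->i", f, f)
            + sse_mat[np.arange(vox.size), best]
        )
        sse = np.maximum(sse, 0.0)
        gidx = rows[best]
        entry_index[vox] = gidx
        n = f.shape[1]
        out["chi2"][vox] = sse / (n - 1)
        r2[vox] = 1.0 - sse / sstot[vox]
        out["adc_plane"][vox] = plane
        for k, col in pcols.items():
            out[k][vox] = col[gidx]

    excluded = (~valid) | (r2 < r2_threshold)
    return ParametricMaps(
        bvf=out["bvf"].reshape(shape3),
        radius_um=out["radius_um"].reshape(shape3),
        sto2=out["sto2"].reshape(shape3),
        orientation_deg=out["orientation_deg"].reshape(shape3),
        r2=r2.reshape(shape3),
        chi2=out["chi2"].reshape(shape3),
        adc_plane=out["adc_plane"].reshape(shape3),
        entry_index=entry_index.reshape(shape3),
        excluded=excluded.reshape(shape3),
        r2_threshold=r2_threshold,
    )
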