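"""Digital brain-like phantoms with known microvascular ground truth.

The phantom stands in for the animal acquisitions: a small image grid is
partitioned into regions (bulk tissue, an elliptical "striatum" ROI and an
elliptical lesion), each carrying one microvascular parameter tuple
(BVf, radius, StO2/dchi, ADC, T2). Every voxel's pre/post GESFIDE echo
trains are simulated with the same engine, seed policy, sequence and physics
as the target dictionary; a multiplicative exp(-t/T2) decay is applied to
BOTH arms (it cancels in the fingerprint but makes the raw volumes
realistic) and Gaussian noise of standard deviation ``noise_sigma`` (as a
fraction of S(0)) is added to the magnitudes. Gaussian rather than Rician
noise is used: phantoms operate at SNR >= 20 where the two coincide.

In ``exact`` mode region parameters must sit on the dictionary's grid nodes,
so a zero-noise phantom round-trips pixel-perfectly through matching.

Lesion presets mimic the qualitative in vivo patterns: ``stroke_like`` has
lower BVf and StO2, larger vessels and reduced ADC than contralateral
tissue; ``tumor_like`` has larger vessels, lower StO2 and elevated ADC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dictionary import Dictionary, GridSpec, _build_geometry
from .sequence import simulate_gesfide
from .steadystate import mge_signal
from .fields import sto2_from_delta_chi

__all__ = [
    "Region",
    "PhantomSpec",
    "PhantomData",
    "default_phantom_spec",
    "generate_phantom",
    "roi_report",
]

MGE_TIMES_MS = [4.5 * k for k in range(1, 16)]  # 15 gradient echoes, dTE 4.5 ms


@dataclass
class Region:
    """One phantom region: an ellipse, or the remaining background tissue."""

    label: int
    name: str
    bvf: float
    radius_um: float
    delta_chi_ppm: float
    adc: float
    t2_ms: float
    orientation_deg: float | None = None
    center: tuple[float, float] | None = None  # voxel coords; None -> background
    axes: tuple[float, float] | None = None


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (24, 24, 3)
    regions: list[Region] = field(default_factory=list)
    noise_sigma: float = 0.0
    seed: int = 0
    lesion_kind: str = "none"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        regions = [Region(**r) for r in d.get("regions", [])]
        return cls(
            shape=tuple(d.get("shape", (24, 24, 3))),
            regions=regions,
            noise_sigma=float(d.get("noise_sigma", 0.0)),
            seed=int(d.get("seed", 0)),
            lesion_kind=d.get("lesion_kind", "none"),
        )


def _snap(value: float, axis) -> float:
    axis = np.asarray(axis, dtype=float)
    return float(axis[np.argmin(np.abs(axis - value))])


def default_phantom_spec(
    dictionary: Dictionary,
    lesion_kind: str = "stroke_like",
    shape: tuple[int, int, int] = (24, 24, 3),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> PhantomSpec:
    """Healthy-tissue phantom with two striatum ROIs, snapped onto the grid.

    Target values follow healthy rat striatum (BVf ~3.5%, radius ~7.3 um,
    StO2 ~82%, ADC ~800 um^2/s) and the corresponding lesion patterns; each
    is snapped to the nearest node of the dictionary's axes so exact-mode
    recovery is well defined.
    """
    p = dictionary.params
    bvf_ax = np.sort(p["bvf"].unique())
    rad_ax = np.sort(p["radius_um"].unique())
    dchi_ax = np.sort(p["delta_chi_ppm"].unique())
    adc_ax = dictionary.adc_axis
    phys = dictionary.physics
    dchi_of = lambda sto2: phys.delta_chi0_ppm * phys.hct * (1.0 - sto2)

    healthy = dict(
        bvf=_snap(0.035, bvf_ax),
        radius_um=_snap(7.3, rad_ax),
        delta_chi_ppm=_snap(dchi_of(0.825), dchi_ax),
        adc=_snap(800.0, adc_ax),
        t2_ms=55.0,
    )
    if lesion_kind == "stroke_like":
        lesion = dict(
            bvf=_snap(0.023, bvf_ax),
            radius_um=_snap(15.5, rad_ax),
            delta_chi_ppm=_snap(dchi_of(0.757), dchi_ax),
            adc=_snap(500.0, adc_ax),
            t2_ms=60.0,
        )
    elif lesion_kind == "tumor_like":
        lesion = dict(
            bvf=_snap(0.030, bvf_ax),
            radius_um=_snap(12.7, rad_ax),
            delta_chi_ppm=_snap(dchi_of(0.745), dchi_ax),
            adc=_snap(1100.0, adc_ax),
            t2_ms=75.0,
        )
    elif lesion_kind == "none":
        lesion = dict(healthy)
    else:
        raise ValueError(f"unknown lesion_kind {lesion_kind!r}")

    nx, ny, _ = shape
    regions = [
        Region(label=1, name="tissue", **healthy),
        Region(
            label=2,
            name="striatum_contra",
            **healthy,
            center=(nx * 0.28, ny * 0.5),
            axes=(nx * 0.16, ny * 0.22),
        ),
        Region(
            label=3,
            name="lesion" if lesion_kind != "none" else "striatum_ipsi",
            **lesion,
            center=(nx * 0.72, ny * 0.5),
            axes=(nx * 0.16, ny * 0.22),
        ),
    ]
    return PhantomSpec(
        shape=shape, regions=regions, noise_sigma=noise_sigma, seed=seed,
        lesion_kind=lesion_kind,
    )


@dataclass
class PhantomData:
    pre4d: np.ndarray
    post4d: np.ndarray
    adc_map: np.ndarray
    t2_map: np.ndarray
    mge4d: np.ndarray
    truth: dict[str, np.ndarray]
    roi_labels: np.ndarray
    echo_times: np.ndarray
    mge_times: np.ndarray


def _region_masks(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.shape
    labels = np.zeros(spec.shape, dtype=np.int32)
    background = [r for r in spec.regions if r.center is None]
    if background:
        labels[:] = background[0].label
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    for r in spec.regions:
        if r.center is None:
            continue
        cx, cy = r.center
        ax, ay = r.axes
        inside = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
        labels[inside, :] = r.label
    return labels


def generate_phantom(
    spec: PhantomSpec,
    dictionary: Dictionary,
    mode: str = "exact",
) -> PhantomData:
    """Render a phantom into pre/post GESFIDE volumes plus auxiliary maps.

    ``mode="exact"`` requires every region parameter tuple to sit on the
    dictionary's axes (configuration error otherwise) and reuses the
    dictionary's geometry seed policy, so the noiseless fingerprints equal
    dictionary rows. ``mode="free"`` simulates whatever values the regions
    carry.
    """
    if mode not in ("exact", "free"):
        raise ValueError(f"unknown mode {mode!r}")
    seq = dictionary.sequence
    physics = dictionary.physics
    grid = GridSpec.from_dict(dictionary.manifest["grid"])
    labels = _region_masks(spec)
    rng = np.random.default_rng(spec.seed)

    echo_times = np.asarray(seq.echo_times)
    n_echo = len(echo_times)
    shape4 = spec.shape + (n_echo,)
    pre4d = np.zeros(shape4)
    post4d = np.zeros(shape4)
    adc_map = np.zeros(spec.shape)
    t2_map = np.zeros(spec.shape)
    mge_times = np.asarray(MGE_TIMES_MS)
    mge4d = np.zeros(spec.shape + (len(mge_times),))
    truth = {
        k: np.full(spec.shape, np.nan)
        for k in ("bvf", "radius_um", "delta_chi_ppm", "sto2", "adc", "t2_ms", "orientation_deg")
    }

    cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
    for region in spec.regions:
        mask = labels == region.label
        if not mask.any():
            continue
        key = (region.bvf, region.radius_um, region.delta_chi_ppm, region.adc,
               region.orientation_deg)
        if key not in cache:
            cache[key] = _region_trains(region, grid, seq, physics, mode)
        pre_sig, post_sig = cache[key]
        decay = np.exp(-echo_times / region.t2_ms)
        pre4d[mask] = pre_sig * decay
        post4d[mask] = post_sig * decay
        adc_map[mask] = region.adc
        t2_map[mask] = region.t2_ms
        sto2 = float(np.clip(
            sto2_from_delta_chi(region.delta_chi_ppm, physics.hct, physics.delta_chi0_ppm),
            0.0, 1.0,
        ))
        mge4d[mask] = mge_signal(mge_times, region.t2_ms, region.bvf, sto2, physics)
        truth["bvf"][mask] = region.bvf
        truth["radius_um"][mask] = region.radius_um
        truth["delta_chi_ppm"][mask] = region.delta_chi_ppm
        truth["sto2"][mask] = sto2
        truth["adc"][mask] = region.adc
        truth["t2_ms"][mask] = region.t2_ms
        if region.orientation_deg is not None:
            truth["orientation_deg"][mask] = region.orientation_deg

    if spec.noise_sigma > 0:
        pre4d = pre4d + rng.normal(0.0, spec.noise_sigma, pre4d.shape)
        post4d = post4d + rng.normal(0.0, spec.noise_sigma, post4d.shape)
        mge4d = mge4d + rng.normal(0.0, spec.noise_sigma, mge4d.shape)

    return PhantomData(
        pre4d=pre4d,
        post4d=post4d,
        adc_map=adc_map,
        t2_map=t2_map,
        mge4d=mge4d,
        truth=truth,
        roi_labels=labels,
        echo_times=echo_times,
        mge_times=mge_times,
    )


def _axis_index(value: float, axis, name: str, mode: str) -> int:
    axis = np.asarray(axis, dtype=float)
    idx = int(np.argmin(np.abs(axis - value)))
    if mode == "exact" and not np.isclose(axis[idx], value, rtol=1e-9, atol=1e-12):
        raise ValueError(
            f"exact-mode phantom: {name}={value:g} is not a node of the "
            f"dictionary axis (nearest {axis[idx]:g})"
        )
    return idx


def _region_trains(region: Region, grid: GridSpec, seq, physics, mode):
    i_bvf = _axis_index(region.bvf, grid.bvf_values, "bvf", mode)
    i_rad = _axis_index(region.radius_um, grid.radius_values, "radius_um", mode)
    if mode == "exact":
        _axis_index(region.delta_chi_ppm, grid.delta_chi_values, "delta_chi_ppm", mode)
        _axis_index(region.adc, grid.adc_values, "adc", mode)
    if grid.geometry_kind == "two_large_vessels":
        i_orient = _axis_index(
            region.orientation_deg, grid.orientation_values, "orientation_deg", mode
        )
    else:
        i_orient = None
    geom = _build_geometry(grid, i_bvf, i_rad, i_orient)
    pre = simulate_gesfide(geom, region.delta_chi_ppm, region.adc, seq, physics, arm="pre")
    post = simulate_gesfide(
        geom, region.delta_chi_ppm + physics.delta_chi_uspio_ppm, region.adc, seq,
        physics, arm="post",
    )
    return pre.signal, post.signal


def roi_report(
    maps: dict[str, np.ndarray],
    roi_labels: np.ndarray,
    excluded: np.ndarray | None = None,
    roi_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Mean +/- sd per ROI for each map, with the exclusion fraction.

    Excluded voxels are omitted from the statistics; fully excluded ROIs are
    flagged.
    """
    if excluded is None:
        excluded = np.zeros(roi_labels.shape, dtype=bool)
    rows = []
    for label in np.unique(roi_labels):
        if label == 0:
            continue
        roi = roi_labels == label
        n_total = int(roi.sum())
        keep = roi & ~excluded
        n_kept = int(keep.sum())
        row = {
            "roi": int(label),
            "name": (roi_names or {}).get(int(label), f"roi_{label}"),
            "n_voxels": n_total,
            "excluded_fraction": 1.0 - n_kept / n_total,
            "fully_excluded": n_kept == 0,
        }
        for name, arr in maps.items():
            vals = arr[keep]
            vals = vals[np.isfinite(vals)]
            row[f"{name}_mean"] = float(vals.mean()) if vals.size else float("nan")
            row[f"{name}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
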