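"""Fingerprint dictionaries: parameter grids, batch simulation, storage.

Three presets mirror the published grids:

* ``A`` -- microvessel networks, 42 BVf x 32 radius x 29 dchi nodes at a
  fixed ADC of 800 um^2/s (38,976 fingerprints, i.e. 77,952 individual
  pre/post simulations);
* ``B`` -- preset A extended with a 27-node ADC axis from 500 to
  1800 um^2/s (1,052,352 fingerprints);
* ``C`` -- preset B plus two-large-vessel voxels: 5 BVf x 8 radius x
  6 orientation x 29 dchi x 14 ADC nodes (97,440 additional fingerprints).

The exact node lists of the original supplement are not reproduced here;
BVf and radius axes are log-spaced across the printed ranges at the printed
cardinalities, the dchi axis is linear from 0 to 1.4 ppm, and the ADC axes
are linear (step 50 for B; every other node for C). All axes can be
overridden through :class:`GridSpec`.

Each dictionary row is the pre/post signal-ratio fingerprint of one
parameter tuple; one geometry realization (one seed) is shared by all
dchi/ADC planes of a (BVf, radius, orientation) cell, and the per-cell seed
is derived deterministically from the manifest's base seed so any row can be
regenerated bit-exactly.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import __version__ as _version
from .geometry import build_large_vessel_geometry, build_microvessel_geometry
from .physics import Physics, DEFAULT_PHYSICS
from .sequence import SequenceParams

__all__ = [
    "GridSpec",
    "Dictionary",
    "DictionaryBuildError",
    "grid_preset",
    "build_dictionary",
    "restrict_to_adc",
    "geometry_seed",
]

_KIND_CODE = {"microvessel": 0, "two_large_vessels": 1}


class DictionaryBuildError(RuntimeError):
    """One or more grid tuples failed to simulate."""


@dataclass
class GridSpec:
    """Factorial parameter grid for one geometry family."""

    bvf_values: list[float]
    radius_values: list[float]
    delta_chi_values: list[float]
    adc_values: list[float]
    orientation_values: list[float] | None = None  # None -> isotropic microvessels
    geometry_kind: str = "microvessel"
    n_vessels: int = 96
    lattice_n: int = 256
    base_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bvf_values", "radius_values", "delta_chi_values", "adc_values"):
            vals = [float(v) for v in getattr(self, name)]
            if not vals:
                raise ValueError(f"{name} must be non-empty")
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{name} must be strictly increasing")
            setattr(self, name, vals)
        if self.orientation_values is not None:
            self.orientation_values = [float(v) for v in self.orientation_values]
        if self.geometry_kind not in _KIND_CODE:
            raise ValueError(f"unknown geometry_kind {self.geometry_kind!r}")
        if self.geometry_kind == "two_large_vessels" and self.orientation_values is None:
            raise ValueError("two_large_vessels grids need orientation_values")

    @property
    def n_entries(self) -> int:
        n = (
            len(self.bvf_values)
            * len(self.radius_values)
            * len(self.delta_chi_values)
            * len(self.adc_values)
        )
        if self.orientation_values is not None:
            n *= len(self.orientation_values)
        return n

    def tuples(self):
        """Yield (i_bvf, i_radius, i_orient, i_dchi, i_adc) index tuples in build order."""
        orient_idx = (
            range(len(self.orientation_values))
            if self.orientation_values is not None
            else [None]
        )
        yield from itertools.product(
            range(len(self.bvf_values)),
            range(len(self.radius_values)),
            orient_idx,
            range(len(self.delta_chi_values)),
            range(len(self.adc_values)),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


def grid_preset(name: str, lattice_n: int = 256, base_seed: int = 0):
    """Published parameter grids. Returns a GridSpec, or a pair for preset C."""
    name = name.upper()
    dchi = list(np.linspace(0.0, 1.4, 29))
    if name == "A":
        return GridSpec(
            bvf_values=list(np.geomspace(0.0025, 0.25, 42)),
            radius_values=list(np.geomspace(0.5, 100.0, 32)),
            delta_chi_values=dchi,
            adc_values=[800.0],
            lattice_n=lattice_n,
            base_seed=base_seed,
        )
    if name == "B":
        spec = grid_preset("A", lattice_n, base_seed)
        spec.adc_values = [500.0 + 50.0 * k for k in range(27)]
        return spec
    if name == "C":
        micro = grid_preset("B", lattice_n, base_seed)
        large = GridSpec(
            bvf_values=list(np.linspace(0.30, 0.50, 5)),
            radius_values=list(np.geomspace(50.0, 1000.0, 8)),
            delta_chi_values=dchi,
            adc_values=[500.0 + 100.0 * k for k in range(14)],
            orientation_values=list(np.linspace(0.0, 90.0, 6)),
            geometry_kind="two_large_vessels",
            n_vessels=2,
            lattice_n=lattice_n,
            base_seed=base_seed,
        )
        return micro, large
    raise ValueError(f"unknown preset {name!r}; expected A, B or C")


def geometry_seed(base_seed: int, kind: str, i_bvf: int, i_radius: int, i_orient) -> int:
    """Deterministic per-geometry seed; shared across dchi/ADC planes."""
    io = 0 if i_orient is None else int(i_orient) + 1
    ss = np.random.SeedSequence([int(base_seed), _KIND_CODE[kind], int(i_bvf), int(i_radius), io])
    return int(ss.generate_state(1)[0] % (2**31))


def _build_geometry(spec: GridSpec, i_bvf: int, i_radius: int, i_orient):
    seed = geometry_seed(spec.base_seed, spec.geometry_kind, i_bvf, i_radius, i_orient)
    bvf = spec.bvf_values[i_bvf]
    radius = spec.radius_values[i_radius]
    if spec.geometry_kind == "microvessel":
        return build_microvessel_geometry(
            bvf, radius, n_vessels=spec.n_vessels, lattice_n=spec.lattice_n, seed=seed
        )
    theta = spec.orientation_values[i_orient]
    return build_large_vessel_geometry(
        bvf, radius, theta, lattice_n=spec.lattice_n, seed=seed
    )


def _simulate_cell(spec, seq, physics, i_bvf, i_radius, i_orient, dchi_adc_pairs, n_drop):
    """Simulate all (dchi, adc) entries sharing one geometry realization."""
    from .matching import make_fingerprint

    geom = _build_geometry(spec, i_bvf, i_radius, i_orient)
    from .fields import compute_field

    unit = compute_field(geom, 1.0, physics.b0, physics.gamma).omega
    rows = []
    from .sequence import simulate_gesfide

    for i_dchi, i_adc in dchi_adc_pairs:
        dchi = spec.delta_chi_values[i_dchi]
        adc = spec.adc_values[i_adc]
        pre = simulate_gesfide(geom, dchi, adc, seq, physics, arm="pre", unit_omega=unit)
        post = simulate_gesfide(
            geom, dchi + physics.delta_chi_uspio_ppm, adc, seq, physics,
            arm="post", unit_omega=unit,
        )
        fp = make_fingerprint(pre, post, n_drop=n_drop)
        rows.append((fp.ratio, pre.signal, post.signal))
    return rows


@dataclass
class Dictionary:
    """Simulated fingerprint matrix plus its parameter table and provenance."""

    entries: np.ndarray  # (n_entries, n_kept_echoes)
    params: pd.DataFrame  # bvf, radius_um, delta_chi_ppm, sto2, adc, orientation_deg, geometry_kind
    echo_times: np.ndarray  # kept echo times, ms
    manifest: dict
    pre_trains: np.ndarray | None = None  # (n_entries, n_echoes) raw arms, if stored
    post_trains: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.entries.shape[0] != len(self.params):
            raise ValueError("entries and params length mismatch")

    def __len__(self) -> int:
        return self.entries.shape[0]

    @property
    def adc_axis(self) -> np.ndarray:
        return np.asarray(sorted(self.params["adc"].unique()))

    @property
    def physics(self) -> Physics:
        return Physics.from_dict(self.manifest["physics"])

    @property
    def sequence(self) -> SequenceParams:
        return SequenceParams.from_dict(self.manifest["sequence"])

    def concat(self, other: "Dictionary") -> "Dictionary":
        """Append another dictionary sharing echo times (e.g. preset C additions)."""
        if self.entries.shape[1] != other.entries.shape[1]:
            raise ValueError("fingerprint lengths differ")
        params = pd.concat([self.params, other.params], ignore_index=True)
        manifest = dict(self.manifest)
        manifest["concatenated"] = [self.manifest, other.manifest]
        return Dictionary(
            entries=np.vstack([self.entries, other.entries]),
            params=params,
            echo_times=self.echo_times,
            manifest=manifest,
        )

    # -- storage -------------------------------------------------------

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("entries", data=self.entries.astype(np.float32))
            f.create_dataset("echo_times", data=self.echo_times)
            if self.pre_trains is not None:
                f.create_dataset("pre_trains", data=self.pre_trains.astype(np.float32))
                f.create_dataset("post_trains", data=self.post_trains.astype(np.float32))
            g = f.create_group("params")
            for col in self.params.columns:
                data = self.params[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                g.create_dataset(col, data=data)
            f.attrs["manifest"] = json.dumps(self.manifest)

    @classmethod
    def load(cls, path) -> "Dictionary":
        import h5py

        with h5py.File(path, "r") as f:
            entries = f["entries"][...]
            echo_times = f["echo_times"][...]
            pre_tr = f["pre_trains"][...] if "pre_trains" in f else None
            post_tr = f["post_trains"][...] if "post_trains" in f else None
            cols = {}
            for col in f["params"]:
                data = f["params"][col][...]
                if data.dtype.kind == "S":
                    data = data.astype(str)
                cols[col] = data
            manifest = json.loads(f.attrs["manifest"])
        return cls(entries, pd.DataFrame(cols), echo_times, manifest,
                   pre_trains=pre_tr, post_trains=post_tr)


def build_dictionary(
    spec: GridSpec,
    seq: SequenceParams | None = None,
    physics: Physics = DEFAULT_PHYSICS,
    workers: int = 1,
    n_drop: int = 8,
    store_trains: bool = False,
) -> Dictionary:
    """Run the simulator over a grid; output is independent of ``workers``.

    Work is sharded by geometry cell (one realization per (BVf, radius,
    orientation)); any failing tuple aborts the build with a report listing
    the offending parameter combinations.
    """
    seq = seq or SequenceParams()
    plane_pairs = list(
        itertools.product(range(len(spec.delta_chi_values)), range(len(spec.adc_values)))
    )
    orient_idx = (
        list(range(len(spec.orientation_values)))
        if spec.orientation_values is not None
        else [None]
    )
    cells = list(
        itertools.product(
            range(len(spec.bvf_values)), range(len(spec.radius_values)), orient_idx
        )
    )

    def run_cell(cell):
        i_bvf, i_radius, i_orient = cell
        try:
            return _simulate_cell(
                spec, seq, physics, i_bvf, i_radius, i_orient, plane_pairs, n_drop
            )
        except Exception as exc:  # re-raised with context below
            return exc

    results = Parallel(n_jobs=workers)(delayed(run_cell)(c) for c in cells)
    failures = []
    for cell, res in zip(cells, results):
        if isinstance(res, Exception):
            i_bvf, i_radius, i_orient = cell
            failures.append(
                (spec.bvf_values[i_bvf], spec.radius_values[i_radius],
                 None if i_orient is None else spec.orientation_values[i_orient], repr(res))
            )
    if failures:
        lines = "\n".join(
            f"  bvf={b:g}, radius={r:g} um, orientation={o}: {e}" for b, r, o, e in failures
        )
        raise DictionaryBuildError(f"{len(failures)} grid cell(s) failed:\n{lines}")

    rows, pre_rows, post_rows, records = [], [], [], []
    phys = physics
    for cell, cell_rows in zip(cells, results):
        i_bvf, i_radius, i_orient = cell
        for (i_dchi, i_adc), (row, pre_sig, post_sig) in zip(plane_pairs, cell_rows):
            dchi = spec.delta_chi_values[i_dchi]
            rows.append(row)
            if store_trains:
                pre_rows.append(pre_sig)
                post_rows.append(post_sig)
            records.append(
                {
                    "bvf": spec.bvf_values[i_bvf],
                    "radius_um": spec.radius_values[i_radius],
                    "delta_chi_ppm": dchi,
                    "sto2": float(
                        np.clip(1.0 - dchi / (phys.delta_chi0_ppm * phys.hct), 0.0, 1.0)
                    ),
                    "adc": spec.adc_values[i_adc],
                    "orientation_deg": (
                        float("nan") if i_orient is None else spec.orientation_values[i_orient]
                    ),
                    "geometry_kind": spec.geometry_kind,
                }
            )
    entries = np.asarray(rows)
    kept = entries.shape[1]
    manifest = {
        "version": _version,
        "grid": spec.to_dict(),
        "sequence": seq.to_dict(),
        "physics": physics.to_dict(),
        "n_drop": n_drop,
        "ratio_convention": "post_over_pre",
        "n_kept_echoes": kept,
    }
    return Dictionary(
        entries=entries,
        params=pd.DataFrame.from_records(records),
        echo_times=np.asarray(seq.echo_times)[:kept],
        manifest=manifest,
        pre_trains=np.asarray(pre_rows) if store_trains else None,
        post_trains=np.asarray(post_rows) if store_trains else None,
    )


def restrict_to_adc(dictionary: Dictionary, adc_measured: float) -> Dictionary:
    """View of the grid hyperplane at the ADC node nearest the measurement.

    Measurements are rounded to the closest simulated ADC value (clamping at
    the axis ends); exact ties resolve toward the lower node.
    """
    if len(dictionary) == 0:
        raise ValueError("empty dictionary")
    axis = dictionary.adc_axis
    idx = int(np.argmin(np.abs(axis - adc_measured)))  # first minimum -> lower node
    plane = float(axis[idx])
    sel = dictionary.params["adc"].to_numpy() == plane
    manifest = dict(dictionary.manifest)
    manifest["adc_plane"] = plane
    return Dictionary(
        entries=dictionary.entries[sel],
        params=dictionary.params.loc[sel].reset_index(drop=True),
        echo_times=dictionary.echo_times,
        manifest=manifest,
        pre_trains=None if dictionary.pre_trains is None else dictionary.pre_trains[sel],
        post_trains=None if dictionary.post_trains is None else dictionary.post_trains[sel],
    )
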