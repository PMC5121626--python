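"""Virtual-voxel vascular geometries.

A simulated voxel is a square lattice (default 256 x 256 points) containing
the cross-sections of straight cylindrical vessels. Two families are
supported:

* microvessel networks -- many small vessels (default 96) spread uniformly
  at random, each with its own orientation to B0 drawn isotropically;
* two-large-vessel configurations -- exactly two parallel vessels sharing a
  prescribed angle to B0, used to model voxels dominated by macrovessels.

In both cases the physical voxel side is *derived* from the requested blood
volume fraction: L = sqrt(n_vessels * pi * r^2 / BVf), so the rasterized
occupancy tracks the target BVf. All placement, rasterization, field and
diffusion computations use periodic (wrap-around) boundary conditions with
the minimum-image convention; lattice point (i, j) sits at the center of
cell (i, j).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Vessel",
    "VoxelGeometry",
    "GeometryInfeasibleError",
    "build_microvessel_geometry",
    "build_large_vessel_geometry",
    "rasterize",
]


class GeometryInfeasibleError(RuntimeError):
    """Raised when vessels cannot be placed without overlap within the retry budget."""


@dataclass(frozen=True)
class Vessel:
    """One cylinder cross-section.

    ``cx``/``cy`` are lattice coordinates (floats in [0, lattice_n)),
    ``radius_um`` is the physical radius, ``theta_deg`` the angle between the
    cylinder axis and B0 (0 = parallel, 90 = perpendicular) and ``phi_deg``
    the in-plane azimuth of the B0 projection in the plane normal to the
    cylinder.
    """

    cx: float
    cy: float
    radius_um: float
    theta_deg: float
    phi_deg: float


@dataclass
class VoxelGeometry:
    lattice_n: int
    voxel_side_um: float
    vessels: list[Vessel]
    bvf_target: float
    seed: int
    kind: str = "microvessel"
    bvf_achieved: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.voxel_side_um <= 0:
            raise ValueError("voxel_side_um must be positive")
        for v in self.vessels:
            if v.radius_um <= 0:
                raise ValueError("vessel radii must be positive")
        if math.isnan(self.bvf_achieved):
            self.bvf_achieved = float(rasterize(self)[0].mean())

    @property
    def dx_um(self) -> float:
        """Lattice spacing, um per lattice unit."""
        return self.voxel_side_um / self.lattice_n

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "lattice_n": self.lattice_n,
            "voxel_side_um": self.voxel_side_um,
            "bvf_target": self.bvf_target,
            "bvf_achieved": self.bvf_achieved,
            "seed": self.seed,
            "kind": self.kind,
            "vessels": [
                [v.cx, v.cy, v.radius_um, v.theta_deg, v.phi_deg]
                for v in self.vessels
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "VoxelGeometry":
        vessels = [Vessel(*row) for row in d["vessels"]]
        return cls(
            lattice_n=int(d["lattice_n"]),
            voxel_side_um=float(d["voxel_side_um"]),
            vessels=vessels,
            bvf_target=float(d["bvf_target"]),
            seed=int(d["seed"]),
            kind=d.get("kind", "microvessel"),
            bvf_achieved=float(d.get("bvf_achieved", float("nan"))),
        )

    @classmethod
    def from_json(cls, s: str) -> "VoxelGeometry":
        return cls.from_dict(json.loads(s))


def _min_image(delta: np.ndarray, period: float) -> np.ndarray:
    """Wrap coordinate differences into (-period/2, period/2]."""
    return delta - period * np.round(delta / period)


def rasterize(geometry: VoxelGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize vessel cross-sections onto the lattice.

    Returns
    -------
    mask : bool array (n, n)
        True where the lattice point center lies inside any vessel.
    labels : int32 array (n, n)
        Index of the owning vessel (nearest center in units of its radius
        where disks would touch), -1 outside all vessels.
    """
    n = geometry.lattice_n
    mask = np.zeros((n, n), dtype=bool)
    labels = np.full((n, n), -1, dtype=np.int32)
    if not geometry.vessels:
        return mask, labels
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    dx = geometry.dx_um
    # normalized distance to each vessel surface; nearest wins on (forbidden) overlap
    best = np.full((n, n), np.inf)
    for k, v in enumerate(geometry.vessels):
        r_lat = v.radius_um / dx
        di = _min_image(ii - v.cx, n)
        dj = _min_image(jj - v.cy, n)
        rho2 = di * di + dj * dj
        inside = rho2 < r_lat * r_lat
        score = rho2 / (r_lat * r_lat)
        take = inside & (score < best)
        labels[take] = k
        best = np.where(take, score, best)
        mask |= inside
    return mask, labels


def _place_centers(
    rng: np.random.Generator,
    radii_lat: Sequence[float],
    lattice_n: int,
    max_attempts: int,
    context: str,
) -> list[tuple[float, float]]:
    """Rejection-sample non-overlapping periodic disk centers."""
    centers: list[tuple[float, float]] = []
    placed = np.empty((0, 2))
    placed_r = np.empty(0)
    for r in radii_lat:
        for _ in range(max_attempts):
            c = rng.uniform(0.0, lattice_n, size=2)
            if placed.shape[0]:
                d = _min_image(placed - c, lattice_n)
                if np.any(np.hypot(d[:, 0], d[:, 1]) < placed_r + r):
                    continue
            centers.append((float(c[0]), float(c[1])))
            placed = np.vstack([placed, c])
            placed_r = np.append(placed_r, r)
            break
        else:
            raise GeometryInfeasibleError(
                f"could not place vessel {len(centers) + 1} without overlap "
                f"after {max_attempts} attempts ({context})"
            )
    return centers


def build_microvessel_geometry(
    bvf: float,
    radius_um: float,
    n_vessels: int = 96,
    lattice_n: int = 256,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> VoxelGeometry:
    """Random network of ``n_vessels`` equal-radius microvessels.

    The voxel side is adapted to the BVf constraint,
    L = sqrt(n * pi * r^2 / BVf). Centers are uniform with periodic
    wrap-around and rejection-sampled to avoid overlap; each vessel draws an
    independent orientation with cos(theta) uniform on [0, 1] (isotropic on
    the hemisphere) and a uniform in-plane azimuth. Cross-sections are kept
    circular (the ellipticity of oblique sections is ignored).
    """
    if not 0.0 < bvf < 0.5:
        raise ValueError(f"bvf must lie in (0, 0.5), got {bvf}")
    if radius_um <= 0:
        raise ValueError("radius_um must be positive")
    if n_vessels < 1:
        raise ValueError("n_vessels must be >= 1")
    voxel_side = math.sqrt(n_vessels * math.pi * radius_um**2 / bvf)
    dx = voxel_side / lattice_n
    rng = np.random.default_rng(seed)
    r_lat = radius_um / dx
    centers = _place_centers(
        rng,
        [r_lat] * n_vessels,
        lattice_n,
        max_attempts,
        context=f"bvf={bvf}, radius={radius_um} um",
    )
    cos_theta = rng.uniform(0.0, 1.0, size=n_vessels)
    thetas = np.degrees(np.arccos(cos_theta))
    phis = rng.uniform(0.0, 360.0, size=n_vessels)
    vessels = [
        Vessel(cx, cy, radius_um, float(t), float(p))
        for (cx, cy), t, p in zip(centers, thetas, phis)
    ]
    return VoxelGeometry(lattice_n, voxel_side, vessels, bvf, seed, kind="microvessel")


def build_large_vessel_geometry(
    bvf: float,
    radius_um: float,
    theta_deg: float,
    lattice_n: int = 256,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> VoxelGeometry:
    """Voxel containing exactly two parallel large vessels at angle ``theta_deg`` to B0."""
    if not 0.0 <= theta_deg <= 90.0:
        raise ValueError(f"theta_deg must lie in [0, 90], got {theta_deg}")
    if not 0.0 < bvf < 0.6:
        raise ValueError(f"bvf must lie in (0, 0.6), got {bvf}")
    if radius_um <= 0:
        raise ValueError("radius_um must be positive")
    voxel_side = math.sqrt(2 * math.pi * radius_um**2 / bvf)
    dx = voxel_side / lattice_n
    rng = np.random.default_rng(seed)
    r_lat = radius_um / dx
    centers = _place_centers(
        rng,
        [r_lat, r_lat],
        lattice_n,
        max_attempts,
        context=f"bvf={bvf}, radius={radius_um} um (two large vessels)",
    )
    phi = float(rng.uniform(0.0, 360.0))
    vessels = [Vessel(cx, cy, radius_um, theta_deg, phi) for cx, cy in centers]
    return VoxelGeometry(
        lattice_n, voxel_side, vessels, bvf, seed, kind="two_large_vessels"
    )
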