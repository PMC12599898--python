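"""Analytic digital phantoms with continuous ground truth.

A :class:`PhantomScene` is a piecewise-analytic 3D HU field that can be
evaluated at any continuous (x, y, z) in mm.  It stands in for paired
thin/thick CT acquisitions: thin-slice volumes are rendered with a
boxcar slab model, while the oracle "true thick" volume integrates the
scene against a triangular slice-sensitivity profile by dense
quadrature.  The two forward models are deliberately different, so a
simulator that reconstructs the thick volume from the rendered thin
slices is tested on approximating a profile it does not trivially share
with the renderer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import SliceGeometry, determine_slice_locations
from .volume import AxialVolume

__all__ = [
    "Primitive",
    "PhantomScene",
    "NoiseSpec",
    "render_thin",
    "render_truth_thick",
    "add_noise",
    "preset_scenes",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class Primitive:
    """One analytic component of a scene.

    ``shape`` selects the geometry:

    - ``"ellipsoid"`` — hard-edged ellipsoid; ``semi_axes`` are the three
      semi-axis lengths in mm.
    - ``"gaussian"`` — smooth blob ``value * exp(-q2 / 2)`` with
      ``q2 = sum(((x - c) / semi_axes)**2)``; infinitely differentiable.
    - ``"slab"`` — constant between two z-planes (``center[2] ±
      semi_axes[2]``), unbounded in-plane; used for piecewise-constant
      z-profiles.

    ``mode`` is ``"replace"`` (set the HU value inside the support) or
    ``"add"`` (add the contribution to the field).
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    value: float
    shape: str = "ellipsoid"
    mode: str = "replace"

    def __post_init__(self) -> None:
        if self.shape not in ("ellipsoid", "gaussian", "slab"):
            raise ValueError(f"unknown primitive shape {self.shape!r}")
        if self.mode not in ("replace", "add"):
            raise ValueError(f"unknown primitive mode {self.mode!r}")
        if not all(a > 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive")


@dataclass(frozen=True)
class PhantomScene:
    """Background HU value plus primitives, evaluable anywhere.

    ``z_slope`` adds an affine-in-z ramp ``z_slope * z`` HU to the
    background, giving exactly linear axial profiles for quadrature
    oracles.  ``extent`` is the axial (z) range in mm within which the
    scene may be rendered.
    """

    background: float = 0.0
    primitives: tuple[Primitive, ...] = ()
    z_slope: float = 0.0
    extent: tuple[float, float] = (-100.0, 100.0)

    def sample_slice(
        self, z: float, rows: int, cols: int, spacing: tuple[float, float]
    ) -> np.ndarray:
        """Evaluate the scene on a pixel grid at axial position ``z``.

        Pixel (r, c) is evaluated at its centre; the grid is centred on
        the patient axis (x = y = 0).
        """
        y = (np.arange(rows) - (rows - 1) / 2.0) * spacing[0]
        x = (np.arange(cols) - (cols - 1) / 2.0) * spacing[1]
        xx = np.broadcast_to(x[None, :], (rows, cols))
        yy = np.broadcast_to(y[:, None], (rows, cols))
        out = np.full((rows, cols), self.background + self.z_slope * z, dtype=np.float64)
        for prim in self.primitives:
            cx, cy, cz = prim.center
            ax, ay, az = prim.semi_axes
            if prim.shape == "slab":
                if abs(z - cz) <= az:
                    if prim.mode == "replace":
                        out[:] = prim.value
                    else:
                        out += prim.value
                continue
            q2 = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 + ((z - cz) / az) ** 2
            if prim.shape == "ellipsoid":
                mask = q2 <= 1.0
                if prim.mode == "replace":
                    out[mask] = prim.value
                else:
                    out[mask] += prim.value
            else:  # gaussian
                contrib = prim.value * np.exp(-0.5 * q2)
                if prim.mode == "replace":
                    # replace within 3 sigma; outside, the blob is negligible
                    out = np.where(q2 <= 9.0, contrib, out)
                else:
                    out += contrib
        return out


@dataclass(frozen=True)
class NoiseSpec:
    """Seeded additive Gaussian HU noise.

    With ``thickness_scaling`` the effective sigma is
    ``sigma_hu * sqrt(t_ref / t)`` with ``t_ref`` = 1 mm: thinner slices
    integrate fewer photons per voxel and are noisier, thicker slices
    quieter.
    """

    sigma_hu: float
    seed: int
    thickness_scaling: bool = False

    def __post_init__(self) -> None:
        if self.sigma_hu < 0:
            raise ValueError(f"sigma_hu must be >= 0, got {self.sigma_hu}")


def _check_extent(scene: PhantomScene, geom: SliceGeometry) -> None:
    lo, hi = scene.extent
    if geom.start < lo or geom.end > hi:
        raise ValueError(
            f"geometry z-range [{geom.start}, {geom.end}] outside scene extent [{lo}, {hi}]"
        )


def render_thin(
    scene: PhantomScene,
    geom: SliceGeometry,
    grid: tuple[int, int, tuple[float, float]] = (64, 64, (1.0, 1.0)),
    subsamples: int = 11,
) -> AxialVolume:
    """Render a thin-slice acquisition of the scene (boxcar slab model).

    Each slice at centre l averages the scene over ``subsamples`` z-offsets
    spanning ``[l - t/2, l + t/2]`` uniformly — a boxcar sensitivity
    profile of width t.  ``subsamples`` should be odd so the slice centre
    itself is sampled; 1 degenerates to point sampling at the centre.
    """
    return _render(scene, geom, grid, subsamples, profile="boxcar")


def render_truth_thick(
    scene: PhantomScene,
    geom: SliceGeometry,
    grid: tuple[int, int, tuple[float, float]] = (64, 64, (1.0, 1.0)),
    subsamples: int = 101,
) -> AxialVolume:
    """Oracle thick-slice volume: triangular profile by dense quadrature.

    Each slice at centre p is the weighted average of the scene over
    ``[p - t, p + t]`` with weight ``max(0, 1 - |z - p| / t)``,
    normalized by the integrated weight.  This continuous integral is
    what the discrete triangular-weighted simulator approximates from
    thin slices, so it serves as ground truth for fidelity tests.
    """
    return _render(scene, geom, grid, subsamples, profile="triangular")


def _render(scene, geom, grid, subsamples, profile):
    if subsamples < 1:
        raise ValueError(f"subsamples must be >= 1, got {subsamples}")
    _check_extent(scene, geom)
    rows, cols, spacing = grid
    locations = determine_slice_locations(geom)
    t = geom.thickness
    if profile == "boxcar":
        if subsamples == 1:
            offsets, weights = np.array([0.0]), np.array([1.0])
        else:
            offsets = np.linspace(-t / 2.0, t / 2.0, subsamples)
            weights = np.ones(subsamples)
    else:
        offsets = np.linspace(-t, t, max(subsamples, 3))
        weights = np.maximum(0.0, 1.0 - np.abs(offsets) / t)
    weights = weights / weights.sum()
    vox = np.empty((len(locations), rows, cols), dtype=np.float64)
    for k, loc in enumerate(locations):
        acc = np.zeros((rows, cols), dtype=np.float64)
        for off, w in zip(offsets, weights):
            if w == 0.0:
                continue
            acc += w * scene.sample_slice(loc + off, rows, cols, spacing)
        vox[k] = acc
    return AxialVolume(
        voxels=vox, positions=locations, thickness=t, in_plane_spacing=spacing
    )


def add_noise(vol: AxialVolume, spec: NoiseSpec) -> AxialVolume:
    """Add seeded Gaussian HU noise; same spec and volume → same field."""
    sigma = spec.sigma_hu
    if spec.thickness_scaling:
        sigma = spec.sigma_hu * np.sqrt(1.0 / vol.thickness)
    if sigma == 0.0:
        return vol.copy()
    rng = np.random.default_rng(spec.seed)
    noisy = vol.voxels + rng.normal(0.0, sigma, size=vol.voxels.shape)
    return AxialVolume(
        voxels=noisy,
        positions=vol.positions.copy(),
        thickness=vol.thickness,
        in_plane_spacing=vol.in_plane_spacing,
    )


PRESET_NAMES = ("blobs", "step_wedge", "ramp", "shepp_like")


def preset_scenes(name: str) -> PhantomScene:
    """Deterministic named phantom scenes.

    - ``blobs`` — smooth Gaussian blobs of soft-tissue HU contrasts on a
      water background; smooth in all directions (for convergence tests).
    - ``step_wedge`` — piecewise-constant steps along z (edge-dominated).
    - ``ramp`` — HU affine in z with slope 10 HU/mm (gradient content).
    - ``shepp_like`` — hard-edged nested ellipsoids in the spirit of the
      Shepp-Logan head phantom.
    """
    if name == "blobs":
        return PhantomScene(
            background=0.0,
            primitives=(
                Primitive((0.0, 0.0, 12.0), (14.0, 11.0, 9.0), 180.0, "gaussian", "add"),
                Primitive((-9.0, 7.0, 26.0), (7.0, 9.0, 6.0), -120.0, "gaussian", "add"),
                Primitive((10.0, -6.0, 32.0), (6.0, 5.0, 8.0), 90.0, "gaussian", "add"),
                Primitive((3.0, 9.0, 44.0), (10.0, 8.0, 7.0), 140.0, "gaussian", "add"),
            ),
            extent=(-20.0, 80.0),
        )
    if name == "step_wedge":
        steps = []
        for k, hu in enumerate((-800.0, -100.0, 0.0, 60.0, 300.0, 1000.0)):
            steps.append(Primitive((0.0, 0.0, 10.0 * k + 5.0), (1e6, 1e6, 5.0), hu, "slab", "replace"))
        return PhantomScene(background=-1000.0, primitives=tuple(steps), extent=(-20.0, 100.0))
    if name == "ramp":
        return PhantomScene(background=0.0, z_slope=10.0, extent=(-100.0, 100.0))
    if name == "shepp_like":
        return PhantomScene(
            background=-1000.0,
            primitives=(
                Primitive((0.0, 0.0, 25.0), (28.0, 22.0, 24.0), 100.0, "ellipsoid", "replace"),
                Primitive((0.0, 0.0, 25.0), (24.0, 18.0, 20.0), 20.0, "ellipsoid", "replace"),
                Primitive((-8.0, 0.0, 22.0), (6.0, 9.0, 8.0), -30.0, "ellipsoid", "replace"),
                Primitive((8.0, -3.0, 28.0), (5.0, 6.0, 7.0), 300.0, "ellipsoid", "replace"),
                Primitive((0.0, 8.0, 30.0), (2.0, 2.0, 2.5), 800.0, "ellipsoid", "replace"),
            ),
            extent=(-10.0, 60.0),
        )
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
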