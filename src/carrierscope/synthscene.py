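"""Synthetic lightsheet scenes of cells on hydrogel microcarriers.

The generator builds ground-truth scenes — spherical gelMA-like microcarriers
(diameter 120 ± 6.2 μm), spread cells conforming to the carrier surface, one
~10 μm nucleus per cell, and small debris scatterers — and renders them into
multi-channel volumes with the contrast relationships the assay relies on:

* nuclear channel: bright nuclei only (DRAQ-5-like);
* cytoplasm channel: bright cell bodies, nucleus region at a reduced level
  (CellTracker Green is cytoplasmic);
* membrane channel: thin shell at the cell boundary (DiI-like);
* elastic scattering: cytoplasm bright, nucleus a low-signal cavity,
  microcarrier interior dimmer than the surrounding medium, debris small and
  dimmer than cells.

Rendering applies an anisotropic Gaussian PSF, optional depth attenuation and
stripe artifacts, then shot (Poisson) + Gaussian read noise.  Everything is
deterministic for a fixed seed; per-stage sub-seeds are derived from the
master seed so partial re-runs reproduce.

Per-microcarrier cell counts are drawn from a zero-truncated Poisson
(every populated carrier carries at least one cell), the same law the
analysis side fits, so parameter-recovery tests close the loop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .stats import ztp_rvs
from .volio import MultiChannelVolume, VoxelGeometry

__all__ = [
    "SceneParams",
    "OpticsParams",
    "SceneSpec",
    "SceneLabels",
    "GroundTruth",
    "sample_scene",
    "rasterize",
    "render",
    "ground_truth",
    "preset",
    "PRESET_NAMES",
]


@dataclass
class SceneParams:
    """Ground-truth scene composition.

    Defaults describe a mid-culture microcarrier sample: 120 ± 6.2 μm
    carriers, ~1800 μm³ spread cells, 10 μm nuclei, a zero-truncated Poisson
    cells-per-microcarrier law, and a sprinkling of 1–4 μm debris at large
    enough contrast to exercise the size/intensity debris filters.
    """

    domain_um: tuple[float, float, float] = (180.0, 220.0, 220.0)  # (z, y, x)
    n_carriers: int = 1
    packing: str = "dispersed"  # or "aggregate"
    carrier_diameter_um: float = 120.0
    carrier_diameter_sd_um: float = 6.2
    cpm_lambda: Optional[float] = 2.0  # ZTP rate; ignored if explicit_counts given
    explicit_counts: Optional[Sequence[int]] = None
    cell_volume_um3: float = 1800.0
    cell_volume_sd_um3: float = 300.0
    shell_thickness_um: float = 8.0  # spread-cell height above the carrier surface
    nucleus_diameter_um: float = 10.0
    n_debris: int = 10
    debris_diameter_um: tuple[float, float] = (1.0, 4.0)
    infiltration_fraction: float = 0.0  # cells extending a process into the core
    seed: int = 0

    def __post_init__(self):
        if self.packing not in ("dispersed", "aggregate"):
            raise ValueError(f"packing must be dispersed|aggregate, got {self.packing}")
        if self.carrier_diameter_um <= 0 or self.nucleus_diameter_um <= 0:
            raise ValueError("diameters must be > 0")
        if self.explicit_counts is None and (
            self.cpm_lambda is None or self.cpm_lambda <= 0
        ):
            raise ValueError("cpm_lambda must be > 0 when no explicit counts given")
        if self.explicit_counts is not None and len(self.explicit_counts) != self.n_carriers:
            raise ValueError("explicit_counts length must equal n_carriers")


@dataclass
class OpticsParams:
    """Image-formation model.

    Scatter-channel intensities must satisfy the assay's contrast contract:
    cytoplasm > medium > microcarrier interior, and nucleus (cavity) <
    cytoplasm.  Default shot-noise gain gives SNR 5 at the nominal nuclear
    peak (SNR = sqrt(I * gain) = sqrt(1000 * 0.025)).
    """

    psf_sigma_lateral_um: float = 1.0
    psf_sigma_axial_um: float = 2.0
    # fluorescence channels
    fluor_nucleus: float = 1000.0
    fluor_cytoplasm: float = 1000.0
    fluor_membrane: float = 1000.0
    cyto_nucleus_factor: float = 0.7  # CTG level inside the nucleus region
    debris_fluor_factor: float = 0.6  # debris vs. nuclear/cyto peak
    # elastic scattering channel
    scatter_cytoplasm: float = 1000.0
    scatter_medium: float = 300.0
    scatter_carrier: float = 150.0
    scatter_nucleus: float = 80.0  # the cavity
    scatter_debris: float = 600.0
    cortical_thickness_um: float = 3.5  # cytoplasm layer enclosing the cavity
    # noise / artifacts
    shot_gain: Optional[float] = 0.025  # detected photons per intensity unit; None = off
    scatter_shot_gain: Optional[float] = 0.1  # scattering is photon-rich (SNR 10)
    read_noise_sd: float = 5.0
    n_stripes: int = 0
    stripe_attenuation: float = 0.5
    depth_attenuation_per_um: float = 0.0

    def __post_init__(self):
        if self.psf_sigma_lateral_um < 0 or self.psf_sigma_axial_um < 0:
            raise ValueError("PSF sigmas must be >= 0")
        ok = (
            self.scatter_cytoplasm > self.scatter_medium > self.scatter_carrier
            and self.scatter_nucleus < self.scatter_cytoplasm
        )
        if not ok:
            raise ValueError(
                "scatter intensities must order cytoplasm > medium > carrier "
                "interior, with nucleus < cytoplasm (the cavity)"
            )

    @property
    def noiseless(self) -> "OpticsParams":
        """Copy with shot and read noise disabled (for noise-free renders)."""
        d = asdict(self)
        d.update(shot_gain=None, scatter_shot_gain=None, read_noise_sd=0.0)
        return OpticsParams(**d)


@dataclass
class SceneLabels:
    """Rasterized ground-truth label grids, all (z, y, x) int32, 0 = none."""

    carriers: np.ndarray
    cells: np.ndarray
    nuclei: np.ndarray
    debris: np.ndarray
    geometry: VoxelGeometry


@dataclass
class SceneSpec:
    """Sampled ground truth: object tables in physical μm coordinates.

    ``cells.volume_um3`` / ``nucleus_volume_um3`` are the exact rasterized
    mask volumes (voxel count × voxel volume) and are filled by
    :func:`rasterize`; before rasterization they are NaN and only the
    analytic ``target_volume_um3`` is available.
    """

    carriers: pd.DataFrame  # id, z_um, y_um, x_um, radius_um
    cells: pd.DataFrame
    debris: pd.DataFrame  # id, z_um, y_um, x_um, radius_um
    domain_um: tuple[float, float, float]
    shell_thickness_um: float
    lambda_true: Optional[float]
    seed: int
    labels: Optional[SceneLabels] = field(default=None, repr=False)

    def to_json(self) -> str:
        payload = {
            "domain_um": list(self.domain_um),
            "shell_thickness_um": self.shell_thickness_um,
            "lambda_true": self.lambda_true,
            "seed": self.seed,
            "carriers": self.carriers.to_dict(orient="records"),
            "cells": self.cells.drop(columns=["infiltrates"], errors="ignore")
            .to_dict(orient="records"),
            "debris": self.debris.to_dict(orient="records"),
        }
        return json.dumps(payload, indent=1, sort_keys=True, allow_nan=True)


# ---------------------------------------------------------------------------
# scene sampling


def _place_dispersed(rng, n, radii, domain, clearance, min_factor=1.15):
    """Uniform non-overlapping sphere centres; centre distance >= 1.15 (ri+rj).

    The 15% slack guarantees a dispersed scene never trips the default
    aggregate clustering criterion (contact factor 1.05).
    """
    centers = []
    tries = 0
    budget = 4000 * n
    while len(centers) < n:
        tries += 1
        if tries > budget:
            raise RuntimeError(
                f"packing failure: placed {len(centers)}/{n} microcarriers; "
                "domain too small"
            )
        i = len(centers)
        m = radii[i] + clearance
        lo = np.array([m, m, m])
        hi = np.asarray(domain) - m
        if np.any(hi <= lo):
            raise RuntimeError("domain too small for a microcarrier plus clearance")
        c = rng.uniform(lo, hi)
        if i:
            d = np.linalg.norm(c - np.asarray(centers), axis=1)
            if np.any(d < min_factor * (radii[i] + radii[:i])):
                continue
        centers.append(c)
    return np.array(centers)


def _place_aggregate(rng, n, radii, domain, clearance):
    """Connected cluster of touching spheres grown sphere by sphere."""
    domain = np.asarray(domain, dtype=float)
    centers = [domain / 2.0]
    tries = 0
    budget = 20000 * n
    while len(centers) < n:
        tries += 1
        if tries > budget:
            raise RuntimeError(
                f"packing failure: aggregate reached {len(centers)}/{n} spheres"
            )
        i = len(centers)
        j = rng.integers(0, i)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        c = centers[j] + (radii[i] + radii[j]) * u
        m = radii[i] + clearance
        if np.any(c < m) or np.any(c > domain - m):
            continue
        d = np.linalg.norm(c - np.asarray(centers), axis=1)
        if np.all(d >= 0.999 * (radii[i] + radii[:i])):
            centers.append(c)
    return np.array(centers)


def _cap_half_angle(volume, radius, thickness):
    """Half-angle of a spherical-shell cap of the given volume."""
    shell = (radius + thickness) ** 3 - radius**3
    cos_t = 1.0 - 3.0 * volume / (2.0 * np.pi * shell)
    return float(np.arccos(np.clip(cos_t, -1.0, 1.0)))


def _spread_directions(rng, thetas, min_gap=0.12, tries_per_cell=400):
    """Random unit anchor directions with pairwise angular separation.

    Required separation between cells i and j is theta_i + theta_j + min_gap
    (radians) so caps never overlap; relaxes gradually if the sphere gets
    crowded.
    """
    dirs: list[np.ndarray] = []
    gap = min_gap
    for i, ti in enumerate(thetas):
        placed = False
        while not placed:
            for _ in range(tries_per_cell):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                ok = all(
                    np.arccos(np.clip(np.dot(u, dirs[j]), -1, 1))
                    >= thetas[j] + ti + gap
                    for j in range(i)
                )
                if ok:
                    dirs.append(u)
                    placed = True
                    break
            else:
                gap *= 0.5  # crowded carrier: allow closer (still non-overlapping) caps
                if gap < 1e-3:
                    raise RuntimeError("could not place cells on carrier surface")
    return np.array(dirs)


def sample_scene(params: SceneParams) -> SceneSpec:
    """Sample a ground-truth scene; deterministic for a fixed seed."""
    ss = np.random.SeedSequence(params.seed)
    rng_place, rng_counts, rng_cells, rng_debris = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )

    n = params.n_carriers
    radii = rng_place.normal(
        params.carrier_diameter_um / 2.0, params.carrier_diameter_sd_um / 2.0, size=n
    )
    radii = np.clip(radii, 0.6 * params.carrier_diameter_um / 2.0, None)
    clearance = params.shell_thickness_um + params.nucleus_diameter_um / 2.0 + 4.0
    if params.packing == "dispersed":
        centers = _place_dispersed(rng_place, n, radii, params.domain_um, clearance)
    else:
        centers = _place_aggregate(rng_place, n, radii, params.domain_um, clearance)

    if params.explicit_counts is not None:
        counts = np.asarray(params.explicit_counts, dtype=np.int64)
        lambda_true = None
    else:
        counts = ztp_rvs(params.cpm_lambda, n, rng_counts)
        lambda_true = params.cpm_lambda

    carriers = pd.DataFrame(
        {
            "id": np.arange(n),
            "z_um": centers[:, 0],
            "y_um": centers[:, 1],
            "x_um": centers[:, 2],
            "radius_um": radii,
            "n_cells": counts,
        }
    )

    cell_rows = []
    rn = params.nucleus_diameter_um / 2.0
    t = params.shell_thickness_um
    cell_id = 0
    for ci in range(n):
        k = int(counts[ci])
        if k == 0:
            continue
        vols = np.clip(
            rng_cells.normal(params.cell_volume_um3, params.cell_volume_sd_um3, k),
            300.0,
            None,
        )
        thetas = [_cap_half_angle(v, radii[ci], t) for v in vols]
        dirs = _spread_directions(rng_cells, thetas)
        for j in range(k):
            u = dirs[j]
            nuc = centers[ci] + (radii[ci] + t / 2.0) * u
            cell_rows.append(
                {
                    "id": cell_id,
                    "carrier_id": ci,
                    "anchor_z": u[0],
                    "anchor_y": u[1],
                    "anchor_x": u[2],
                    "theta_rad": thetas[j],
                    "target_volume_um3": vols[j],
                    "volume_um3": np.nan,
                    "nucleus_z_um": nuc[0],
                    "nucleus_y_um": nuc[1],
                    "nucleus_x_um": nuc[2],
                    "nucleus_radius_um": rn,
                    "nucleus_volume_um3": np.nan,
                    "infiltrates": bool(
                        rng_cells.uniform() < params.infiltration_fraction
                    ),
                }
            )
            cell_id += 1
    cells = pd.DataFrame(
        cell_rows,
        columns=[
            "id", "carrier_id", "anchor_z", "anchor_y", "anchor_x", "theta_rad",
            "target_volume_um3", "volume_um3", "nucleus_z_um", "nucleus_y_um",
            "nucleus_x_um", "nucleus_radius_um", "nucleus_volume_um3", "infiltrates",
        ],
    )

    # debris in the medium, clear of carriers and their cell shells
    deb_rows = []
    lo_d, hi_d = params.debris_diameter_um
    attempts = 0
    while len(deb_rows) < params.n_debris and attempts < 200 * max(params.n_debris, 1):
        attempts += 1
        r = rng_debris.uniform(lo_d, hi_d) / 2.0
        c = rng_debris.uniform([r + 1] * 3, np.asarray(params.domain_um) - r - 1)
        d2surf = np.linalg.norm(c - centers, axis=1) - radii if n else np.array([np.inf])
        if np.min(d2surf) > t + rn + r + 2.0:
            deb_rows.append(
                {"id": len(deb_rows), "z_um": c[0], "y_um": c[1], "x_um": c[2],
                 "radius_um": r}
            )
    debris = pd.DataFrame(
        deb_rows, columns=["id", "z_um", "y_um", "x_um", "radius_um"]
    )

    return SceneSpec(
        carriers=carriers,
        cells=cells,
        debris=debris,
        domain_um=tuple(params.domain_um),
        shell_thickness_um=t,
        lambda_true=lambda_true,
        seed=params.seed,
    )


# ---------------------------------------------------------------------------
# rasterization


def _bbox_slices(center, radius, geometry, shape):
    """Grid slices covering a sphere of `radius` around `center` (z,y,x μm)."""
    sl = []
    for c, r, p, n in zip(center, (radius,) * 3, geometry.pitch_zyx, shape):
        lo = max(int(np.floor((c - r) / p - 0.5)) - 1, 0)
        hi = min(int(np.ceil((c + r) / p - 0.5)) + 2, n)
        sl.append(slice(lo, hi))
    return tuple(sl)


def _local_coords(slices, geometry):
    """Voxel-centre coordinate grids (μm) for a bbox, open-grid broadcastable."""
    return [
        ((np.arange(s.start, s.stop) + 0.5) * p).reshape(
            [-1 if i == ax else 1 for i in range(3)]
        )
        for ax, (s, p) in enumerate(zip(slices, geometry.pitch_zyx))
    ]


def _paint_sphere(grid, center, radius, geometry, value):
    sl = _bbox_slices(center, radius, geometry, grid.shape)
    zz, yy, xx = _local_coords(sl, geometry)
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    mask = d2 <= radius**2
    region = grid[sl]
    region[mask & (region == 0)] = value
    return int(mask.sum())


def rasterize(scene: SceneSpec, geometry: VoxelGeometry) -> SceneLabels:
    """Rasterize the scene into label grids and fix the exact true volumes.

    After this call ``scene.cells.volume_um3`` equals the painted cell-mask
    voxel count × voxel volume exactly (likewise nucleus volumes); the
    result is also attached as ``scene.labels``.
    """
    shape = tuple(
        int(round(ext / p)) for ext, p in zip(scene.domain_um, geometry.pitch_zyx)
    )
    max_r = float(scene.carriers.radius_um.max()) if len(scene.carriers) else 0.0
    reach = max_r + scene.shell_thickness_um
    for ext, need in zip(scene.domain_um, (2 * reach,) * 3):
        if ext < need:
            raise ValueError("scene does not fit in the voxel grid domain")

    carr = np.zeros(shape, dtype=np.int32)
    cell = np.zeros(shape, dtype=np.int32)
    nucl = np.zeros(shape, dtype=np.int32)
    debr = np.zeros(shape, dtype=np.int32)
    voxvol = geometry.voxel_volume

    centers = scene.carriers[["z_um", "y_um", "x_um"]].to_numpy()
    radii = scene.carriers["radius_um"].to_numpy()
    for i, (c, r) in enumerate(zip(centers, radii)):
        _paint_sphere(carr, c, r, geometry, i + 1)

    t = scene.shell_thickness_um
    cell_vols = np.zeros(len(scene.cells))
    nuc_vols = np.zeros(len(scene.cells))
    for idx, row in scene.cells.iterrows():
        ci = int(row.carrier_id)
        C = centers[ci]
        R = radii[ci]
        u = np.array([row.anchor_z, row.anchor_y, row.anchor_x])
        sl = _bbox_slices(C, R + t, geometry, shape)
        zz, yy, xx = _local_coords(sl, geometry)
        dz, dy, dx = zz - C[0], yy - C[1], xx - C[2]
        dist = np.sqrt(dz**2 + dy**2 + dx**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = (dz * u[0] + dy * u[1] + dx * u[2]) / np.where(dist > 0, dist, 1)
        cap = (dist >= R) & (dist <= R + t) & (cosang >= np.cos(row.theta_rad))
        if row.infiltrates:
            # thin process burrowing toward the carrier core
            axial = dz * u[0] + dy * u[1] + dx * u[2]
            radial2 = dist**2 - axial**2
            cap |= (radial2 <= 2.0**2) & (axial >= 0.3 * R) & (dist < R)
        region = cell[sl]
        sel = cap & (region == 0)
        region[sel] = idx + 1

        nuc_c = np.array([row.nucleus_z_um, row.nucleus_y_um, row.nucleus_x_um])
        n_nuc = _paint_sphere(nucl, nuc_c, row.nucleus_radius_um, geometry, idx + 1)
        nuc_vols[idx] = n_nuc * voxvol

    # cell body = cap shell plus its nucleus (CellTracker fills the whole cell)
    nuc_in = nucl > 0
    cell_grown = cell.copy()
    cell_grown[nuc_in & (cell_grown == 0)] = nucl[nuc_in & (cell_grown == 0)]
    cell = cell_grown
    counts = np.bincount(cell.ravel(), minlength=len(scene.cells) + 1)
    cell_vols = counts[1 : len(scene.cells) + 1] * voxvol

    for _, row in scene.debris.iterrows():
        _paint_sphere(
            debr,
            np.array([row.z_um, row.y_um, row.x_um]),
            row.radius_um,
            geometry,
            int(row.id) + 1,
        )

    scene.cells["volume_um3"] = cell_vols
    scene.cells["nucleus_volume_um3"] = nuc_vols
    labels = SceneLabels(carr, cell, nucl, debr, geometry)
    scene.labels = labels
    return labels


# ---------------------------------------------------------------------------
# rendering


def render(
    scene: SceneSpec,
    optics: OpticsParams,
    geometry: VoxelGeometry,
    channels: Sequence[str] = ("nuclear", "cytoplasm", "membrane", "scatter"),
    noise_seed: Optional[int] = None,
) -> MultiChannelVolume:
    """Render the scene into a multi-channel volume.

    Pipeline per channel: paint pure labels -> Gaussian PSF blur -> optional
    depth attenuation -> optional stripe artifacts -> shot + read noise,
    clipped at zero.  Deterministic: noise and stripe placement derive from
    the scene seed unless ``noise_seed`` is given.
    """
    labels = scene.labels if scene.labels is not None else rasterize(scene, geometry)
    if labels.geometry != geometry:
        labels = rasterize(scene, geometry)

    cell_sup = labels.cells > 0
    nuc_sup = labels.nuclei > 0
    deb_sup = labels.debris > 0
    struct = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(cell_sup, structure=struct)
    n_cort = max(1, int(round(optics.cortical_thickness_um / min(geometry.pitch_zyx))))
    cort_eroded = (
        ndimage.binary_erosion(cell_sup, structure=struct, iterations=n_cort)
        if n_cort > 1
        else eroded
    )

    fields = []
    roles = tuple(channels)
    for role in roles:
        f = np.zeros(labels.cells.shape, dtype=np.float32)
        if role == "nuclear":
            f[nuc_sup] = optics.fluor_nucleus
            f[deb_sup] = optics.debris_fluor_factor * optics.fluor_nucleus
        elif role == "cytoplasm":
            f[cell_sup] = optics.fluor_cytoplasm
            f[nuc_sup] = optics.cyto_nucleus_factor * optics.fluor_cytoplasm
            f[deb_sup] = optics.debris_fluor_factor * optics.fluor_cytoplasm
        elif role == "membrane":
            f[cell_sup & ~eroded] = optics.fluor_membrane
        elif role == "scatter":
            f[:] = optics.scatter_medium
            f[labels.carriers > 0] = optics.scatter_carrier
            f[cell_sup] = optics.scatter_cytoplasm
            # cavity: nucleus wrapped in a cortical cytoplasm layer thick
            # enough to survive the PSF blur, so it stays a closed hole that
            # per-object hole filling can recover
            f[nuc_sup & cort_eroded] = optics.scatter_nucleus
            f[deb_sup] = optics.scatter_debris
        else:
            raise ValueError(f"unknown channel role {role!r}")
        fields.append(f)

    sig_vox = (
        optics.psf_sigma_axial_um / geometry.dz,
        optics.psf_sigma_lateral_um / geometry.dy,
        optics.psf_sigma_lateral_um / geometry.dx,
    )
    base_seed = scene.seed if noise_seed is None else noise_seed
    rng_stripe = np.random.default_rng([base_seed, 101])
    rng_noise = np.random.default_rng([base_seed, 102])

    out = []
    for role, f in zip(roles, fields):
        gain = optics.scatter_shot_gain if role == "scatter" else optics.shot_gain
        if any(s > 0 for s in sig_vox):
            f = ndimage.gaussian_filter(f, sigma=sig_vox)
        if optics.depth_attenuation_per_um > 0:
            z_um = (np.arange(f.shape[0]) + 0.5) * geometry.dz
            f = f * np.exp(-optics.depth_attenuation_per_um * z_um).astype(
                np.float32
            ).reshape(-1, 1, 1)
        if optics.n_stripes > 0:
            rows = rng_stripe.choice(f.shape[1], size=optics.n_stripes, replace=False)
            f = f.copy()
            f[:, rows, :] *= optics.stripe_attenuation
        if gain is not None:
            f = rng_noise.poisson(f * gain).astype(np.float32) / gain
        if optics.read_noise_sd > 0:
            f = f + rng_noise.normal(0.0, optics.read_noise_sd, f.shape).astype(
                np.float32
            )
        out.append(np.clip(f, 0.0, None).astype(np.float32))

    return MultiChannelVolume(
        np.stack(out), geometry, roles, provenance=f"synthscene seed={scene.seed}"
    )


# ---------------------------------------------------------------------------
# ground truth


@dataclass(frozen=True)
class GroundTruth:
    """Exact quantities the pipeline should recover from a rendered scene."""

    per_carrier: pd.DataFrame  # carrier_id, n_cells
    cells: pd.DataFrame  # cell_id, carrier_id, volume_um3, nucleus_volume_um3
    cpm_histogram: dict  # {k >= 1: n carriers with k cells}
    total_cells: int
    total_carriers: int
    total_cell_volume_um3: float

    def to_frame(self) -> pd.DataFrame:
        """Flat single-table form for truth.csv."""
        rows = [
            {"kind": "carrier", "id": int(r.carrier_id), "carrier_id": int(r.carrier_id),
             "n_cells": int(r.n_cells), "volume_um3": np.nan}
            for r in self.per_carrier.itertuples()
        ] + [
            {"kind": "cell", "id": int(r.cell_id), "carrier_id": int(r.carrier_id),
             "n_cells": np.nan, "volume_um3": float(r.volume_um3)}
            for r in self.cells.itertuples()
        ]
        return pd.DataFrame(rows, columns=["kind", "id", "carrier_id", "n_cells",
                                           "volume_um3"])


def ground_truth(scene: SceneSpec) -> GroundTruth:
    """Truth tables for a scene.

    Uses exact rasterized volumes when the scene has been rasterized/rendered,
    else the analytic target volumes.
    """
    per_carrier = scene.carriers[["id", "n_cells"]].rename(
        columns={"id": "carrier_id"}
    )
    vols = scene.cells["volume_um3"]
    if vols.isna().any():
        vols = scene.cells["target_volume_um3"]
    cells = pd.DataFrame(
        {
            "cell_id": scene.cells["id"],
            "carrier_id": scene.cells["carrier_id"],
            "volume_um3": vols,
            "nucleus_volume_um3": scene.cells["nucleus_volume_um3"],
        }
    )
    populated = per_carrier[per_carrier.n_cells >= 1]
    hist_series = populated.n_cells.value_counts().sort_index()
    cpm_hist = {int(k): int(v) for k, v in hist_series.items()}
    return GroundTruth(
        per_carrier=per_carrier,
        cells=cells,
        cpm_histogram=cpm_hist,
        total_cells=int(per_carrier.n_cells.sum()),
        total_carriers=int(len(per_carrier)),
        total_cell_volume_um3=float(vols.sum()),
    )


# ---------------------------------------------------------------------------
# presets (desk-scale study conditions; 2 μm isotropic voxels)

DEFAULT_GEOMETRY = VoxelGeometry(2.0, 2.0, 2.0)

PRESET_NAMES = (
    "single_carrier",
    "dispersed7",
    "aggregate20",
    "nuclei_benchmark",
    "growth_series",
)


def preset(name: str, seed: int = 0):
    """Named study conditions.

    Returns ``(SceneParams, OpticsParams, VoxelGeometry)``, except
    ``growth_series`` which returns a list of such triples (8 samples with
    increasing cells-per-microcarrier rate).
    """
    optics = OpticsParams()
    g = DEFAULT_GEOMETRY
    if name == "single_carrier":
        return (
            SceneParams(domain_um=(180, 220, 220), n_carriers=1,
                        explicit_counts=[3], n_debris=5, seed=seed),
            optics, g,
        )
    if name == "dispersed7":
        return (
            SceneParams(domain_um=(330, 660, 660), n_carriers=7,
                        cpm_lambda=2.0, n_debris=10, seed=seed),
            optics, g,
        )
    if name == "aggregate20":
        return (
            SceneParams(domain_um=(760, 760, 760), n_carriers=20,
                        packing="aggregate", cpm_lambda=2.0, n_debris=10, seed=seed),
            optics, g,
        )
    if name == "nuclei_benchmark":
        # 100 nuclei per scene; 2 μm debris at 0.6x nuclear intensity
        return (
            SceneParams(domain_um=(340, 680, 680), n_carriers=10,
                        explicit_counts=[10] * 10, n_debris=20,
                        debris_diameter_um=(2.0, 2.0), seed=seed),
            optics, g,
        )
    if name == "growth_series":
        lams = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0)
        out = []
        for i, lam in enumerate(lams):
            out.append(
                (
                    SceneParams(domain_um=(330, 640, 640), n_carriers=8,
                                cpm_lambda=lam, n_debris=10, seed=seed * 1000 + i),
                    optics, g,
                )
            )
        return out
    raise ValueError(f"unknown preset {name!r}; valid: {PRESET_NAMES}")
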