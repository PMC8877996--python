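"""Synthetic 3D T2-like liver phantom with exact ground truth.

The generator emulates the features of breath-hold axial T2-weighted
abdominal MRI that make automated cyst segmentation hard:

* an ellipsoidal liver region of interest on a moderately dark body
  background;
* many near-spherical hyperintense cysts of heterogeneous size and
  intensity, placed with a minimum centre separation so that narrow
  gaps between neighbouring cysts exist;
* bright tubular vessels running obliquely through the liver across
  slices — on thick slices their in-plane cross-sections are blob-like
  and intensity alone cannot distinguish them from cysts, so a
  region-based level set includes them (the characteristic failure mode
  that interactive removal is designed to fix);
* a smooth low-order polynomial intensity bias field and additive
  Gaussian noise.

Everything is reproducible: the same spec and seed give bit-identical
volumes and masks. The cyst ground-truth mask is a subset of the liver
ROI and disjoint from the vessel mask (a clearance gap of liver-intensity
voxels separates vessels from cysts).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .errors import PackingError, ParameterError
from .interaction import AffinityConfig, ClickEvent, EditSession, replay_session
from .volumes import BinaryMask, ImageVolume, check_congruent

__all__ = ["PhantomSpec", "generate_phantom", "scripted_cleanup_session"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity parameters of the synthetic phantom.

    Defaults are sized so that a full segment-edit-evaluate experiment
    runs in minutes on one CPU while exercising every failure mode:
    a 64x96x96 grid of thick axial slices (8 mm) with in-plane 1.5 mm
    voxels, 25 cysts of radius 2-8 voxels at normalized intensity
    0.7-1.0 over a 0.35 liver, and 3 oblique bright vessels of tube
    radius 2.
    """

    shape: tuple[int, int, int] = (64, 96, 96)
    spacing: tuple[float, float, float] = (8.0, 1.5, 1.5)  # thick axial slices
    liver_semiaxes: tuple[float, float, float] = (26.0, 40.0, 40.0)
    n_cysts: int = 25
    cyst_radius: tuple[float, float] = (2.0, 8.0)
    cyst_intensity: tuple[float, float] = (0.7, 1.0)
    min_separation_gap: float = 2.0  # extra voxels beyond the sum of radii
    n_vessels: int = 3
    vessel_radius: float = 2.0
    vessel_intensity: float = 0.9
    vessel_drift: tuple[float, float] = (2.0, 3.5)  # in-plane voxels per slice
    vessel_clearance: int = 2  # dilation of cysts that vessels must avoid
    liver_intensity: float = 0.35
    background_intensity: float = 0.12
    noise_sigma: float = 0.03
    bias_amplitude: float = 0.05
    max_placement_tries: int = 500

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise ParameterError(f"bad shape {self.shape}")
        if min(self.spacing) <= 0:
            raise ParameterError(f"spacing must be positive, got {self.spacing}")
        for name in ("n_cysts", "n_vessels"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        lo, hi = self.cyst_radius
        if not 0 < lo <= hi:
            raise ParameterError(f"bad cyst radius range {self.cyst_radius}")
        for name in ("cyst_intensity",):
            lo, hi = getattr(self, name)
            if not 0 <= lo <= hi <= 1:
                raise ParameterError(f"{name} must lie within [0, 1]")
        if self.noise_sigma < 0 or self.bias_amplitude < 0:
            raise ParameterError("noise_sigma and bias_amplitude must be >= 0")

    def to_json(self, path: str | Path, seed: int | None = None) -> None:
        payload = asdict(self)
        if seed is not None:
            payload["seed"] = seed
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> tuple["PhantomSpec", int | None]:
        with open(path) as fh:
            payload = json.load(fh)
        seed = payload.pop("seed", None)
        for key in ("shape", "spacing", "liver_semiaxes", "cyst_radius",
                    "cyst_intensity", "vessel_drift"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload), seed


def _index_grids(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")


def _liver_mask(spec: PhantomSpec) -> np.ndarray:
    zz, rr, cc = _index_grids(spec.shape)
    cz, cr, cco = ((n - 1) / 2.0 for n in spec.shape)
    az, ar, ac = spec.liver_semiaxes
    return ((zz - cz) / az) ** 2 + ((rr - cr) / ar) ** 2 + ((cc - cco) / ac) ** 2 <= 1.0


def _place_cysts(
    spec: PhantomSpec, liver: np.ndarray, rng: np.random.Generator
) -> list[tuple[np.ndarray, float, float]]:
    """Sample (center, radius, intensity) triples honouring the separation rule."""
    centers: list[np.ndarray] = []
    radii: list[float] = []
    out: list[tuple[np.ndarray, float, float]] = []
    liver_idx = np.argwhere(liver)
    for i in range(spec.n_cysts):
        placed = False
        for _ in range(spec.max_placement_tries):
            center = liver_idx[rng.integers(len(liver_idx))].astype(float)
            radius = float(rng.uniform(*spec.cyst_radius))
            ok = all(
                np.linalg.norm(center - c0) >= radius + r0 + spec.min_separation_gap
                for c0, r0 in zip(centers, radii)
            )
            if ok:
                intensity = float(rng.uniform(*spec.cyst_intensity))
                centers.append(center)
                radii.append(radius)
                out.append((center, radius, intensity))
                placed = True
                break
        if not placed:
            raise PackingError(
                f"placed only {i} of {spec.n_cysts} cysts within "
                f"{spec.max_placement_tries} tries each; reduce count/radius "
                "or the separation gap"
            )
    return out


def _rasterize_sphere(mask: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Voxels within ``radius`` of ``center`` in index space (local window only)."""
    lo = np.maximum(np.floor(center - radius).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius).astype(int) + 1, mask.shape)
    zz, rr, cc = np.meshgrid(*(np.arange(a, b) for a, b in zip(lo, hi)), indexing="ij")
    ball = (
        (zz - center[0]) ** 2 + (rr - center[1]) ** 2 + (cc - center[2]) ** 2
    ) <= radius**2
    window = np.zeros_like(mask)
    window[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = ball
    return window


def _paint_ball(mask: np.ndarray, center: np.ndarray, radius: float) -> None:
    """In-place union of a ball into ``mask`` (local window; no full-grid alloc)."""
    lo = np.maximum(np.floor(center - radius).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius).astype(int) + 1, mask.shape)
    if np.any(lo >= hi):
        return
    zz, rr, cc = np.meshgrid(*(np.arange(a, b) for a, b in zip(lo, hi)), indexing="ij")
    ball = (
        (zz - center[0]) ** 2 + (rr - center[1]) ** 2 + (cc - center[2]) ** 2
    ) <= radius**2
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= ball


def _vessel_tube(
    spec: PhantomSpec, rng: np.random.Generator
) -> np.ndarray:
    """A gently curved intra-hepatic tube, rasterized as a union of balls.

    The centerline drifts in-plane from slice to slice (so thick-slice
    cross-sections are cyst-like blobs) and is kept inside the liver
    ellipsoid, sliding along its boundary when the drift would exit —
    hepatic vessels run within the liver.
    """
    nz, nr, nc = spec.shape
    rho = spec.vessel_radius
    cz, cr, cc = ((n - 1) / 2.0 for n in spec.shape)
    az, ar, ac = spec.liver_semiaxes
    drift_speed = float(rng.uniform(*spec.vessel_drift))
    theta = float(rng.uniform(0, 2 * np.pi))
    dr, dc = drift_speed * np.cos(theta), drift_speed * np.sin(theta)
    r0 = float(cr - dr * nz / 2 + rng.normal(0, nr / 10))
    c0 = float(cc - dc * nz / 2 + rng.normal(0, nc / 10))
    amp_r, amp_c = rng.uniform(-4, 4, size=2)
    period = float(rng.uniform(nz / 2, nz))
    margin = 0.88  # keep the centerline off the capsule so the tube stays interior
    mask = np.zeros(spec.shape, dtype=bool)
    ts = np.arange(0, nz - 1 + 1e-9, 0.25)
    for t in ts:
        s2 = 1.0 - ((t - cz) / az) ** 2
        if s2 <= 0.02:
            continue  # slice beyond the liver's axial extent
        s = float(np.sqrt(s2))
        wobble = np.sin(2 * np.pi * t / period)
        r = r0 + dr * t + amp_r * wobble
        c = c0 + dc * t + amp_c * wobble
        # clamp into the in-plane liver ellipse of this slice
        e = np.sqrt(((r - cr) / (ar * s)) ** 2 + ((c - cc) / (ac * s)) ** 2)
        if e > margin:
            r = cr + (r - cr) * margin / e
            c = cc + (c - cc) * margin / e
        _paint_ball(mask, np.array([t, r, c]), rho)
    return mask


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-order polynomial field scaled to ±bias_amplitude."""
    if spec.bias_amplitude == 0:
        return np.zeros(spec.shape)
    zz, rr, cc = _index_grids(spec.shape)
    # normalized coordinates in [-1, 1]
    x = 2 * zz / max(spec.shape[0] - 1, 1) - 1
    y = 2 * rr / max(spec.shape[1] - 1, 1) - 1
    w = 2 * cc / max(spec.shape[2] - 1, 1) - 1
    coef = rng.uniform(-1, 1, size=7)
    f = (
        coef[0] * x + coef[1] * y + coef[2] * w
        + coef[3] * x * y + coef[4] * y * w + coef[5] * x * w
        + coef[6] * (x**2 - y**2)
    )
    peak = float(np.abs(f).max())
    if peak == 0:
        return np.zeros(spec.shape)
    return spec.bias_amplitude * f / peak


def generate_phantom(
    spec: PhantomSpec | None = None, seed: int = 0
) -> tuple[ImageVolume, BinaryMask, BinaryMask, BinaryMask]:
    """Generate a phantom volume with exact masks.

    Returns ``(volume, cyst_gt, vessels, liver_roi)``. The intensity
    model is: background, liver and vessel plateaus plus per-cyst
    plateaus, plus the bias field, clipped to [0, 1], plus Gaussian
    noise. Identical (spec, seed) pairs give bit-identical outputs.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    liver = _liver_mask(spec)
    if not liver.any():
        raise PackingError("liver ellipsoid lies outside the grid")

    vol = np.full(spec.shape, spec.background_intensity, dtype=np.float64)
    vol[liver] = spec.liver_intensity

    cysts = np.zeros(spec.shape, dtype=bool)
    for center, radius, intensity in _place_cysts(spec, liver, rng):
        ball = _rasterize_sphere(cysts, center, radius) & liver
        cysts |= ball
        vol[ball] = intensity

    vessels = np.zeros(spec.shape, dtype=bool)
    if spec.n_vessels > 0:
        if spec.vessel_clearance > 0 and cysts.any():
            keep_out = ndi.binary_dilation(
                cysts, structure=ndi.generate_binary_structure(3, 1),
                iterations=spec.vessel_clearance,
            )
        else:
            keep_out = np.zeros(spec.shape, dtype=bool)
        for _ in range(spec.n_vessels):
            tube = _vessel_tube(spec, rng) & ~keep_out
            vessels |= tube
        vol[vessels] = spec.vessel_intensity

    vol += _bias_field(spec, rng)
    np.clip(vol, 0.0, 1.0, out=vol)
    if spec.noise_sigma > 0:
        vol += rng.normal(0.0, spec.noise_sigma, size=spec.shape)

    sp = spec.spacing
    return (
        ImageVolume(vol, sp),
        BinaryMask(cysts, sp),
        BinaryMask(vessels, sp),
        BinaryMask(liver, sp),
    )


def _snap_to_component(component: np.ndarray) -> tuple[int, int, int]:
    """Component centroid snapped to the nearest true voxel (lexicographic ties)."""
    idx = np.argwhere(component)
    centroid = idx.mean(axis=0)
    d2 = ((idx - centroid) ** 2).sum(axis=1)
    # argmin over C-ordered argwhere rows -> lexicographic tie-break
    return tuple(int(v) for v in idx[int(np.argmin(d2))])


def _cleanup_round(
    mask: BinaryMask,
    vessel_mask: BinaryMask,
    cyst_gt_mask: BinaryMask | None,
) -> list[ClickEvent]:
    """Events a reviewer would issue against the current mask: one
    ``smart_remove`` per connected vessel component present in the mask,
    one ``smart_add`` per ground-truth cyst component entirely absent."""
    structure = ndi.generate_binary_structure(3, 1)
    events: list[ClickEvent] = []
    labels, n = ndi.label(vessel_mask.data, structure=structure)
    for lab in range(1, n + 1):
        in_mask = (labels == lab) & mask.data
        if not in_mask.any():
            continue
        seed = _snap_to_component(in_mask)
        events.append(
            ClickEvent(kind="smart_remove", coordinate=seed, overrides={"scope": "3d"})
        )
    if cyst_gt_mask is not None:
        labels, n = ndi.label(cyst_gt_mask.data, structure=structure)
        for lab in range(1, n + 1):
            comp = labels == lab
            if (comp & mask.data).any():
                continue
            seed = _snap_to_component(comp)
            events.append(
                ClickEvent(kind="smart_add", coordinate=seed, overrides={"scope": "3d"})
            )
    return events


def scripted_cleanup_session(
    level_set_mask: BinaryMask,
    vessel_mask: BinaryMask,
    cyst_gt_mask: BinaryMask | None = None,
    volume: ImageVolume | None = None,
    defaults: AffinityConfig | None = None,
    max_rounds: int = 10,
) -> EditSession:
    """Build the deterministic edit session that fixes the level-set output.

    One ``smart_remove`` event is emitted per connected vessel component
    present in the level-set mask, seeded at the component-in-mask
    centroid snapped to the nearest true voxel. If the cyst ground truth
    is supplied, one ``smart_add`` is emitted per cyst component entirely
    missed by the level set, seeded the same way. Smart events run with
    ``scope="3d"`` so a single click follows a structure through slices.

    If the (normalized) ``volume`` is supplied, the session is built
    iteratively the way a reviewer works: each round of clicks is
    simulated by replay and further rounds are appended until no vessel
    component remains in the mask and no cyst component is missing (noise
    can break the affinity chain mid-vessel, so one click does not always
    clear a whole component). Without the volume a single round is
    scripted. The session is a pure function of its inputs.
    """
    check_congruent(level_set_mask, vessel_mask)
    if cyst_gt_mask is not None:
        check_congruent(level_set_mask, cyst_gt_mask)
    defaults = defaults or AffinityConfig()

    events = _cleanup_round(level_set_mask, vessel_mask, cyst_gt_mask)
    if volume is None:
        return EditSession(events=tuple(events), defaults=defaults)

    all_events: list[ClickEvent] = []
    mask = level_set_mask
    for _ in range(max_rounds):
        if not events:
            break
        all_events.extend(events)
        mask = replay_session(volume, mask, EditSession(tuple(events), defaults))
        events = _cleanup_round(mask, vessel_mask, cyst_gt_mask)
    return EditSession(events=tuple(all_events), defaults=defaults)
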