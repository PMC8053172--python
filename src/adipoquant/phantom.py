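"""Digital body phantoms with analytic ground truth for Dixon imaging.

The phantom is a stack of axial slices of a stylized torso: an elliptical body
cross-section with, from the outside in, a thin lean skin layer, a subcutaneous
adipose ring (SCAT), a lean muscle/fascia ring and a visceral cavity containing
randomly placed adipose blobs (VAT).  An optional subcutaneous tumor bulges out
of the body wall.  Every voxel carries ground-truth water and fat densities, so
a simulated multi-echo acquisition has an exact per-voxel reference.

Longitudinal series are generated by rescaling compartment geometry so that
ground-truth volumes follow prescribed trajectories (e.g. VAT shrinking to 75 %
of baseline), which is how treatment- or cachexia-driven change is emulated.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy.optimize import brentq

from .protocols import AcquisitionProtocol, EchoSeries

__all__ = [
    "TISSUE_LABELS",
    "COMPARTMENT_LABELS",
    "TumorSpec",
    "PhantomSpec",
    "LabeledAnatomy",
    "build_phantom",
    "simulate_echoes",
    "make_longitudinal",
    "write_dataset",
    "read_dataset",
    "mouse_spec",
    "human_spec",
]

# Tissue codes (anatomical layers)
TISSUE_LABELS = {
    "background": 0,
    "skin": 1,
    "scat": 2,
    "muscle": 3,
    "cavity": 4,
    "vat": 5,
    "tumor": 7,
}

# Compartment codes shared with the segmentation module:
# 0 background, 1 SCAT, 2 VAT, 3 LTW, 4 excluded (tumor ground truth maps to 4).
COMPARTMENT_LABELS = {"background": 0, "scat": 1, "vat": 2, "ltw": 3, "excluded": 4}


@dataclass(frozen=True)
class TumorSpec:
    """Subcutaneous tumor: a disc centred on the body outline."""

    angle_deg: float = 35.0
    radius_mm: float = 3.0
    fat_fraction: float = 0.1
    slices: tuple[int, ...] | None = None  # default: all slices


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue composition and simulation parameters of a phantom.

    All lengths are in mm.  ``seed`` fixes VAT blob placement and the noise
    stream; the same spec and seed always reproduce the same phantom.
    """

    n_slices: int = 3
    body_semiaxes_mm: tuple[float, float] = (12.0, 14.0)  # (row, col) semi-axes
    skin_thickness_mm: float = 0.5
    scat_thickness_mm: float = 1.2
    muscle_thickness_mm: float = 2.0
    vat_blob_count: int = 6
    vat_blob_radius_mm: tuple[float, float] = (0.9, 1.6)
    lean_fat_fraction: float = 0.05
    adipose_fat_fraction: float = 0.9
    lean_density: float = 1.0
    adipose_density: float = 0.95
    tumor: TumorSpec | None = None
    b0_amplitude_hz: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    slice_profile: tuple[float, ...] | None = None  # per-slice outline scale

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if min(self.body_semiaxes_mm) <= 0:
            raise ValueError("body semi-axes must be positive")
        rim = self.skin_thickness_mm + self.scat_thickness_mm + self.muscle_thickness_mm
        if rim >= min(self.body_semiaxes_mm):
            raise ValueError(
                "skin+SCAT+muscle thickness exceeds the body semi-axis: "
                f"{rim:.2f} mm >= {min(self.body_semiaxes_mm):.2f} mm"
            )
        if self.skin_thickness_mm < 0 or self.scat_thickness_mm < 0 or self.muscle_thickness_mm < 0:
            raise ValueError("layer thicknesses must be non-negative")
        for ff in (self.lean_fat_fraction, self.adipose_fat_fraction):
            if not 0.0 <= ff <= 1.0:
                raise ValueError("fat fractions must lie in [0, 1]")
        if not 0.0 <= self.lean_fat_fraction <= 0.1:
            raise ValueError("lean fat fraction must lie in [0, 0.1]")
        if not 0.8 <= self.adipose_fat_fraction <= 1.0:
            raise ValueError("adipose fat fraction must lie in [0.8, 1.0]")
        if self.vat_blob_count < 0:
            raise ValueError("vat_blob_count must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.slice_profile is not None and len(self.slice_profile) != self.n_slices:
            raise ValueError("slice_profile length must equal n_slices")


@dataclass
class LabeledAnatomy:
    """Voxelized phantom with ground truth.

    ``tissue`` holds anatomical layer codes (:data:`TISSUE_LABELS`),
    ``compartments`` the derived ground-truth compartment codes
    (:data:`COMPARTMENT_LABELS`), and ``water``/``fat`` the proton-density
    maps used by the signal simulator (water + fat ≤ 1 everywhere).
    """

    tissue: np.ndarray
    water: np.ndarray
    fat: np.ndarray
    compartments: np.ndarray
    spacing: tuple[float, float, float]  # (row, col, slice) mm

    @property
    def body_mask(self) -> np.ndarray:
        return self.tissue > 0

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing[0] * self.spacing[1] * self.spacing[2]

    def compartment_volumes_mm3(self) -> dict[str, float]:
        """Ground-truth compartment volumes in mm³ (1 mm³ = 1 µl)."""
        v = self.voxel_volume_mm3
        return {
            name: float(np.count_nonzero(self.compartments == code) * v)
            for name, code in COMPARTMENT_LABELS.items()
            if name != "background"
        }


def mouse_spec(**overrides) -> PhantomSpec:
    """Mouse-scale phantom defaults (pairs with the 7 T three-echo protocol)."""
    base = dict(
        n_slices=3,
        body_semiaxes_mm=(12.0, 14.0),
        skin_thickness_mm=0.5,
        scat_thickness_mm=1.2,
        muscle_thickness_mm=2.0,
        vat_blob_count=6,
        vat_blob_radius_mm=(0.9, 1.6),
        b0_amplitude_hz=150.0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


def human_spec(**overrides) -> PhantomSpec:
    """Human abdomen-scale phantom defaults (pairs with the 3 T dual-echo protocol)."""
    base = dict(
        n_slices=3,
        body_semiaxes_mm=(120.0, 160.0),
        skin_thickness_mm=3.0,
        scat_thickness_mm=20.0,
        muscle_thickness_mm=15.0,
        vat_blob_count=5,
        vat_blob_radius_mm=(12.0, 20.0),
        b0_amplitude_hz=60.0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


# ---------------------------------------------------------------------------
# geometry


def _grid_mm(protocol: AcquisitionProtocol) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-centre coordinates in mm relative to the matrix centre."""
    rows, cols = protocol.matrix
    dy, dx = protocol.in_plane_spacing
    y = (np.arange(rows) - (rows - 1) / 2.0) * dy
    x = (np.arange(cols) - (cols - 1) / 2.0) * dx
    return np.meshgrid(y, x, indexing="ij")


def _ellipse_mask(yy: np.ndarray, xx: np.ndarray, a: float, b: float) -> np.ndarray:
    """Voxel centres strictly inside the ellipse with semi-axes (a=row, b=col)."""
    if a <= 0 or b <= 0:
        return np.zeros_like(yy, dtype=bool)
    return (yy / a) ** 2 + (xx / b) ** 2 <= 1.0


def _scat_inner_thickness(a: float, b: float, t0: float, factor: float) -> float:
    """Ring thickness t giving ``factor`` times the area of the thickness-``t0`` ring.

    The ring lies between the ellipse (a, b) and (a − t, b − t); its area is
    π[ab − (a−t)(b−t)], linear-quadratic in t, so the rescaled thickness has a
    closed form.
    """
    if t0 == 0:
        return 0.0
    s = a + b
    target = factor * (t0 * s - t0 * t0)
    disc = s * s - 4.0 * target
    if disc < 0:
        raise ValueError("infeasible SCAT scale factor")
    t = (s - np.sqrt(disc)) / 2.0
    if t <= 0 and factor > 0:
        raise ValueError("SCAT ring vanished under the requested scale factor")
    return t


@dataclass(frozen=True)
class _BlobPlan:
    centers_mm: np.ndarray  # (n, 2) (y, x)
    radii_mm: np.ndarray  # (n,)


def _plan_blobs(spec: PhantomSpec) -> _BlobPlan:
    """Place VAT blobs inside the visceral cavity, reproducibly from the seed."""
    rng = np.random.default_rng(spec.seed)
    a, b = spec.body_semiaxes_mm
    rim = spec.skin_thickness_mm + spec.scat_thickness_mm + spec.muscle_thickness_mm
    ca, cb = a - rim, b - rim  # cavity semi-axes
    scale_min = min(spec.slice_profile) if spec.slice_profile else 1.0
    centers, radii = [], []
    for _ in range(spec.vat_blob_count):
        r = rng.uniform(*spec.vat_blob_radius_mm)
        # keep the blob fully inside the cavity of the *smallest* slice
        margin_a = scale_min * ca - r
        margin_b = scale_min * cb - r
        if margin_a <= 0 or margin_b <= 0:
            raise ValueError("VAT blob does not fit inside the visceral cavity")
        for _attempt in range(200):
            u, v = rng.uniform(-1, 1, size=2)
            if u * u + v * v <= 1.0:
                break
        centers.append((u * margin_a, v * margin_b))
        radii.append(r)
    return _BlobPlan(np.asarray(centers, dtype=float).reshape(-1, 2), np.asarray(radii, dtype=float))


def _slice_tissue(
    spec: PhantomSpec,
    yy: np.ndarray,
    xx: np.ndarray,
    slice_index: int,
    blobs: _BlobPlan,
    vat_radius_scale: float,
    scat_t: float,
    body_scale: float,
) -> np.ndarray:
    """Tissue labels for one slice."""
    profile = spec.slice_profile or (1.0,) * spec.n_slices
    a = spec.body_semiaxes_mm[0] * profile[slice_index] * body_scale
    b = spec.body_semiaxes_mm[1] * profile[slice_index] * body_scale
    body = _ellipse_mask(yy, xx, a, b)
    skin_in = _ellipse_mask(yy, xx, a - spec.skin_thickness_mm, b - spec.skin_thickness_mm)
    scat_in = _ellipse_mask(
        yy, xx, a - spec.skin_thickness_mm - scat_t, b - spec.skin_thickness_mm - scat_t
    )
    rim = spec.skin_thickness_mm + scat_t + spec.muscle_thickness_mm
    cavity = _ellipse_mask(yy, xx, a - rim, b - rim)

    sl = np.zeros(yy.shape, dtype=np.uint8)
    sl[body] = TISSUE_LABELS["skin"]
    sl[skin_in] = TISSUE_LABELS["scat"]
    sl[scat_in] = TISSUE_LABELS["muscle"]
    sl[cavity] = TISSUE_LABELS["cavity"]
    for (cy, cx), r in zip(blobs.centers_mm, blobs.radii_mm):
        rr = r * vat_radius_scale
        if rr <= 0:
            continue
        blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= rr**2
        sl[blob & cavity] = TISSUE_LABELS["vat"]

    if spec.tumor is not None and (spec.tumor.slices is None or slice_index in spec.tumor.slices):
        th = np.deg2rad(spec.tumor.angle_deg)
        cy, cx = a * np.sin(th), b * np.cos(th)
        bump = (yy - cy) ** 2 + (xx - cx) ** 2 <= spec.tumor.radius_mm**2
        sl[bump] = TISSUE_LABELS["tumor"]
    return sl


def _rasterize(
    spec: PhantomSpec,
    protocol: AcquisitionProtocol,
    blobs: _BlobPlan,
    vat_radius_scale: float = 1.0,
    scat_thickness_mm: float | None = None,
    body_scale: float = 1.0,
) -> LabeledAnatomy:
    yy, xx = _grid_mm(protocol)
    n = spec.n_slices
    tissue = np.zeros((n, *protocol.matrix), dtype=np.uint8)
    scat_t = spec.scat_thickness_mm if scat_thickness_mm is None else scat_thickness_mm
    for s in range(n):
        tissue[s] = _slice_tissue(spec, yy, xx, s, blobs, vat_radius_scale, scat_t, body_scale)

    water = np.zeros_like(tissue, dtype=float)
    fat = np.zeros_like(tissue, dtype=float)
    lean = np.isin(tissue, [TISSUE_LABELS["skin"], TISSUE_LABELS["muscle"], TISSUE_LABELS["cavity"]])
    adipose = np.isin(tissue, [TISSUE_LABELS["scat"], TISSUE_LABELS["vat"]])
    water[lean] = spec.lean_density * (1.0 - spec.lean_fat_fraction)
    fat[lean] = spec.lean_density * spec.lean_fat_fraction
    water[adipose] = spec.adipose_density * (1.0 - spec.adipose_fat_fraction)
    fat[adipose] = spec.adipose_density * spec.adipose_fat_fraction
    if spec.tumor is not None:
        tum = tissue == TISSUE_LABELS["tumor"]
        water[tum] = spec.lean_density * (1.0 - spec.tumor.fat_fraction)
        fat[tum] = spec.lean_density * spec.tumor.fat_fraction

    comp = np.zeros_like(tissue, dtype=np.uint8)
    comp[tissue == TISSUE_LABELS["scat"]] = COMPARTMENT_LABELS["scat"]
    comp[tissue == TISSUE_LABELS["vat"]] = COMPARTMENT_LABELS["vat"]
    comp[lean] = COMPARTMENT_LABELS["ltw"]
    comp[tissue == TISSUE_LABELS["tumor"]] = COMPARTMENT_LABELS["excluded"]

    return LabeledAnatomy(
        tissue=tissue, water=water, fat=fat, compartments=comp, spacing=protocol.spacing
    )


def build_phantom(spec: PhantomSpec, protocol: AcquisitionProtocol) -> LabeledAnatomy:
    """Rasterize the phantom anatomy on the protocol's voxel grid.

    The SCAT layer is a closed annulus between the skin and the muscle ring,
    VAT blobs lie strictly inside the muscle boundary, and the optional tumor
    is a subcutaneous bump labeled distinctly.
    """
    return _rasterize(spec, protocol, _plan_blobs(spec))


# ---------------------------------------------------------------------------
# signal simulation


def _b0_field(spec_amp: float, shape: tuple[int, int, int]) -> np.ndarray:
    """Smooth low-order polynomial off-resonance field scaled to ±spec_amp Hz."""
    n, rows, cols = shape
    yn = np.linspace(-1, 1, rows)[:, None]
    xn = np.linspace(-1, 1, cols)[None, :]
    field = np.empty((n, rows, cols))
    for s in range(n):
        p = 0.25 + 0.5 * xn + 0.35 * yn + 0.4 * xn * yn + 0.3 * (xn**2 - yn**2) + 0.05 * s
        field[s] = p
    peak = np.max(np.abs(field))
    if peak > 0:
        field *= spec_amp / peak
    return field


def simulate_echoes(
    anatomy: LabeledAnatomy,
    protocol: AcquisitionProtocol,
    b0_amplitude_hz: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    phi0: float = 0.0,
) -> EchoSeries:
    """Simulate the complex multi-echo Dixon signal on the phantom.

    Per voxel, with water density W, fat density F, off-resonance ψ (Hz) and
    echo time TE_k (s):

        s_k = (W + F·exp(i·2π·Δf·TE_k)) · exp(i·(φ0 + 2π·ψ·TE_k)) + n_k,

    where n_k is complex Gaussian noise with standard deviation
    ``noise_sd × mean in-body first-echo magnitude`` on each of the real and
    imaginary channels.
    """
    if anatomy.tissue.shape[1:] != tuple(protocol.matrix):
        raise ValueError("anatomy grid does not match the protocol matrix")
    te = protocol.echo_times_s
    df = protocol.fat_water_offset_hz
    psi = _b0_field(b0_amplitude_hz, anatomy.tissue.shape) if b0_amplitude_hz else np.zeros(
        anatomy.tissue.shape
    )
    fat_phasor = np.exp(2j * np.pi * df * te)  # (K,)
    base = anatomy.water[..., None] + anatomy.fat[..., None] * fat_phasor
    phase = np.exp(1j * (phi0 + 2.0 * np.pi * psi[..., None] * te))
    signal = base * phase
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        body = anatomy.body_mask
        ref = float(np.abs(signal[..., 0])[body].mean()) if body.any() else 1.0
        sd = noise_sd * ref
        noise = rng.normal(scale=sd, size=signal.shape) + 1j * rng.normal(
            scale=sd, size=signal.shape
        )
        signal = signal + noise
    return EchoSeries(
        data=signal,
        protocol=protocol,
        meta={"b0_amplitude_hz": b0_amplitude_hz, "noise_sd": noise_sd, "seed": seed,
              "psi_true_hz": psi},
    )


# ---------------------------------------------------------------------------
# longitudinal series


def _ring_area(a: float, b: float, t: float) -> float:
    return np.pi * (a * b - max(a - t, 0.0) * max(b - t, 0.0))


def make_longitudinal(
    spec: PhantomSpec,
    protocol: AcquisitionProtocol,
    trajectory: dict[str, Sequence[float]],
) -> list[tuple[LabeledAnatomy, EchoSeries]]:
    """Generate a timepoint series whose compartment volumes follow ``trajectory``.

    ``trajectory`` maps compartment names (``vat``, ``scat``, ``ltw``) to
    per-timepoint scale factors; the first factor of each must be 1.  VAT is
    scaled through the blob radii (area ∝ r²), SCAT through the ring thickness
    (closed form) and LTW through the body outline (solved numerically while
    holding the SCAT ring area fixed).  Ground-truth volumes track the factors
    to within rasterization tolerance.
    """
    lengths = {len(v) for v in trajectory.values()}
    if len(lengths) != 1:
        raise ValueError("all trajectories must have the same number of timepoints")
    n_t = lengths.pop()
    for name, factors in trajectory.items():
        if name not in ("vat", "scat", "ltw"):
            raise ValueError(f"unknown compartment {name!r} in trajectory")
        if abs(factors[0] - 1.0) > 1e-12:
            raise ValueError("the first (baseline) scale factor must be 1")
        if any(f <= 0 for f in factors):
            raise ValueError("scale factors must be positive")

    blobs = _plan_blobs(spec)
    a, b = spec.body_semiaxes_mm
    a_in = a - spec.skin_thickness_mm
    b_in = b - spec.skin_thickness_mm
    area_body = np.pi * a * b
    area_scat0 = _ring_area(a_in, b_in, spec.scat_thickness_mm)
    area_vat0 = float(np.pi * np.sum(blobs.radii_mm**2))
    area_ltw0 = area_body - area_scat0 - area_vat0

    yy, xx = _grid_mm(protocol)

    def counts(vat_scale: float, scat_t: float, body_scale: float) -> dict[str, int]:
        c = {"scat": 0, "vat": 0, "ltw": 0}
        lean = (TISSUE_LABELS["skin"], TISSUE_LABELS["muscle"], TISSUE_LABELS["cavity"])
        for s in range(spec.n_slices):
            sl = _slice_tissue(spec, yy, xx, s, blobs, vat_scale, scat_t, body_scale)
            c["scat"] += int(np.count_nonzero(sl == TISSUE_LABELS["scat"]))
            c["vat"] += int(np.count_nonzero(sl == TISSUE_LABELS["vat"]))
            c["ltw"] += int(np.count_nonzero(np.isin(sl, lean)))
        return c

    base = counts(1.0, spec.scat_thickness_mm, 1.0)

    def refine(key: str, target: float, p0: float, evalf, spread: float = 0.08) -> float:
        """Two-stage scan picking the parameter whose rasterized count is closest."""
        best_p, best_err = p0, abs(evalf(p0)[key] - target)
        lo, hi = p0 * (1 - spread), p0 * (1 + spread)
        for _ in range(2):
            for p in np.linspace(lo, hi, 17):
                err = abs(evalf(p)[key] - target)
                if err < best_err:
                    best_p, best_err = p, err
            step = (hi - lo) / 16
            lo, hi = best_p - step, best_p + step
        return best_p

    out = []
    for t in range(n_t):
        f_vat = trajectory.get("vat", [1.0] * n_t)[t]
        f_scat = trajectory.get("scat", [1.0] * n_t)[t]
        f_ltw = trajectory.get("ltw", [1.0] * n_t)[t]

        scat_t = _scat_inner_thickness(a_in, b_in, spec.scat_thickness_mm, f_scat)
        vat_scale = float(np.sqrt(f_vat))
        body_scale = 1.0
        if abs(f_ltw - 1.0) > 1e-12:
            area_vat_t = area_vat0 * f_vat

            def ltw_area(s: float) -> float:
                ai = a * s - spec.skin_thickness_mm
                bi = b * s - spec.skin_thickness_mm
                return np.pi * (a * s) * (b * s) - _ring_area(ai, bi, scat_t) - area_vat_t

            target = f_ltw * area_ltw0
            try:
                body_scale = brentq(lambda s: ltw_area(s) - target, 0.3, 3.0, xtol=1e-10)
            except ValueError as exc:
                raise ValueError("infeasible LTW scale factor") from exc

        # the analytic scales carry O(perimeter/area) rasterization bias for
        # thin rings and small blobs; refine each against rasterized counts
        if abs(f_scat - 1.0) > 1e-12:
            scat_t = refine(
                "scat", f_scat * base["scat"], scat_t,
                lambda p: counts(vat_scale, p, body_scale),
            )
        if abs(f_vat - 1.0) > 1e-12:
            vat_scale = refine(
                "vat", f_vat * base["vat"], vat_scale,
                lambda p: counts(p, scat_t, body_scale),
            )
        if abs(f_ltw - 1.0) > 1e-12:
            body_scale = refine(
                "ltw", f_ltw * base["ltw"], body_scale,
                lambda p: counts(vat_scale, scat_t, p),
            )

        anatomy = _rasterize(
            spec,
            protocol,
            blobs,
            vat_radius_scale=vat_scale,
            scat_thickness_mm=scat_t,
            body_scale=body_scale,
        )
        for name in trajectory:
            if anatomy.compartment_volumes_mm3()[name] <= 0:
                raise ValueError(f"compartment {name!r} vanished at timepoint {t}")
        series = simulate_echoes(
            anatomy,
            protocol,
            b0_amplitude_hz=spec.b0_amplitude_hz,
            noise_sd=spec.noise_sd,
            seed=spec.seed + t,
        )
        out.append((anatomy, series))
    return out


# ---------------------------------------------------------------------------
# I/O


def _save_nifti(arr: np.ndarray, spacing: tuple[float, float, float], path: str) -> None:
    affine = np.diag([spacing[1], spacing[0], spacing[2], 1.0])
    # store as (cols, rows, slices[, echoes]) so the affine maps voxel axes to mm
    data = np.moveaxis(arr, (0, 1, 2), (2, 1, 0))
    nib.save(nib.Nifti1Image(np.ascontiguousarray(data), affine), path)


def _load_nifti(path: str) -> np.ndarray:
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    return np.moveaxis(data, (2, 1, 0), (0, 1, 2))


def write_dataset(series: EchoSeries, anatomy: LabeledAnatomy, path: str) -> dict[str, str]:
    """Write the series, ground-truth maps and a JSON sidecar under ``path``.

    Complex data are stored as separate real/imaginary NIfTI volumes so the
    round trip is exact.  Returns the mapping of artifact names to file paths.
    """
    if not os.path.isdir(path):
        raise FileNotFoundError(f"output directory does not exist: {path}")
    p = series.protocol
    files = {}

    def put(name: str, arr: np.ndarray) -> None:
        fp = os.path.join(path, f"{name}.nii.gz")
        _save_nifti(arr, p.spacing, fp)
        files[name] = fp

    if np.iscomplexobj(series.data):
        put("echoes_real", series.data.real.astype(np.float64))
        put("echoes_imag", series.data.imag.astype(np.float64))
    else:
        put("echoes_mag", series.data.astype(np.float64))
    put("tissue", anatomy.tissue.astype(np.uint8))
    put("compartments_truth", anatomy.compartments.astype(np.uint8))
    put("water_truth", anatomy.water)
    put("fat_truth", anatomy.fat)

    sidecar = {
        "field_strength_T": p.field_strength,
        "echo_times_ms": list(p.echo_times),
        "spacing_mm": list(p.spacing),
        "matrix": list(p.matrix),
        "shift_ppm": p.fat_water_shift_ppm,
        "gyromagnetic_ratio_mhz_per_t": p.gyromagnetic_ratio,
        "seed": series.meta.get("seed"),
        "b0_amplitude_hz": series.meta.get("b0_amplitude_hz"),
        "noise_sd": series.meta.get("noise_sd"),
        "magnitude_only": bool(series.magnitude_only),
    }
    sp = os.path.join(path, "protocol.json")
    with open(sp, "w") as fh:
        json.dump(sidecar, fh, indent=2)
    files["sidecar"] = sp
    return files


def read_dataset(path: str) -> tuple[EchoSeries, LabeledAnatomy]:
    """Round-trip reader for :func:`write_dataset` outputs."""
    sp = os.path.join(path, "protocol.json")
    if not os.path.isfile(sp):
        raise FileNotFoundError(f"missing sidecar: {sp}")
    with open(sp) as fh:
        sidecar = json.load(fh)
    protocol = AcquisitionProtocol(
        field_strength=sidecar["field_strength_T"],
        echo_times=tuple(sidecar["echo_times_ms"]),
        in_plane_spacing=tuple(sidecar["spacing_mm"][:2]),
        slice_thickness=sidecar["spacing_mm"][2],
        matrix=tuple(sidecar["matrix"]),
        fat_water_shift_ppm=sidecar["shift_ppm"],
        gyromagnetic_ratio=sidecar["gyromagnetic_ratio_mhz_per_t"],
    )
    real_p = os.path.join(path, "echoes_real.nii.gz")
    if os.path.isfile(real_p):
        data = _load_nifti(real_p) + 1j * _load_nifti(os.path.join(path, "echoes_imag.nii.gz"))
        magnitude_only = False
    else:
        data = _load_nifti(os.path.join(path, "echoes_mag.nii.gz"))
        magnitude_only = True
    series = EchoSeries(
        data=data,
        protocol=protocol,
        magnitude_only=magnitude_only,
        meta={k: sidecar.get(k) for k in ("seed", "b0_amplitude_hz", "noise_sd")},
    )
    anatomy = LabeledAnatomy(
        tissue=_load_nifti(os.path.join(path, "tissue.nii.gz")).astype(np.uint8),
        water=_load_nifti(os.path.join(path, "water_truth.nii.gz")),
        fat=_load_nifti(os.path.join(path, "fat_truth.nii.gz")),
        compartments=_load_nifti(os.path.join(path, "compartments_truth.nii.gz")).astype(np.uint8),
        spacing=protocol.spacing,
    )
    return series, anatomy
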