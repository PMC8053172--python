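"""Per-slice active-contour (snake) segmentation of body compartments.

The pipeline mirrors whole-body fat segmentation on Dixon fat images: per
axial slice a body mask is derived from the total signal (W + F), the outer
skin contour of each connected component initializes a closed snake, and the
snake propagates inward under a balloon pressure until it locks onto the
sharp fat→muscle edge at the deep fascia.  Voxels between the skin and the
converged contour with high fat fraction are subcutaneous fat (SCAT), fatty
voxels inside it are visceral fat (VAT), and the remaining water-dominant
body voxels form the lean tissue water compartment (LTW).

The snake minimizes

    E = α Σ|v_{i+1} − v_i|² + β Σ|v_{i+1} − 2v_i + v_{i−1}|² − Σ |∇(G_σ ∗ I)|(v_i)

by semi-implicit gradient descent, with an inward balloon force κ that is
gated by a look-ahead test: pressure is applied only while fat-like signal
lies ahead of the contour, so the snake escapes the skin edge, crosses the
bright SCAT ring and stops at the fascia instead of collapsing through it.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_closing, binary_fill_holes, gaussian_filter, map_coordinates
from skimage import measure, morphology
from skimage.draw import polygon2mask
from skimage.filters import threshold_otsu

from .dixon import FatWaterResult

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_SCAT",
    "LABEL_VAT",
    "LABEL_LTW",
    "LABEL_EXCLUDED",
    "SnakeParams",
    "Contour",
    "BodyCompartments",
    "body_mask",
    "outer_contour",
    "evolve_snake",
    "label_compartments",
    "segment_volume",
    "apply_manual_override",
]

logger = logging.getLogger(__name__)

LABEL_BACKGROUND, LABEL_SCAT, LABEL_VAT, LABEL_LTW, LABEL_EXCLUDED = 0, 1, 2, 3, 4
_VALID_LABELS = frozenset({0, 1, 2, 3, 4})


@dataclass(frozen=True)
class SnakeParams:
    """Active-contour parameters (all weights dimensionless, lengths in voxels).

    ``alpha``/``beta`` weight contour tension and stiffness, ``kappa`` the
    inward balloon pressure, ``gamma`` the explicit step size, ``sigma`` the
    Gaussian scale of the edge map.  Convergence requires the mean vertex
    displacement to stay below ``tol`` for ``patience`` consecutive
    iterations.  ``edge_weight`` scales the edge attraction and
    ``balloon_gate``/``lookahead`` control the look-ahead pressure gate.
    """

    n_vertices: int = 200
    alpha: float = 0.1
    beta: float = 0.05
    kappa: float = 0.3
    gamma: float = 1.0
    sigma: float = 2.0
    max_iter: int = 500
    tol: float = 0.01
    patience: int = 5
    edge_weight: float = 2.0
    balloon_gate: float = 0.2
    lookahead: float = 4.0

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.kappa, self.gamma, self.sigma, self.edge_weight) < 0:
            raise ValueError("snake weights must be non-negative")
        if self.n_vertices < 16:
            raise ValueError("n_vertices must be >= 16")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.patience < 1 or self.max_iter < 1:
            raise ValueError("patience and max_iter must be >= 1")


#: Mouse-scale default (smaller matrix, fewer vertices).
MOUSE_SNAKE = SnakeParams(n_vertices=120)


@dataclass
class Contour:
    """Closed polygon in voxel coordinates (row, col), counter-clockwise.

    "Counter-clockwise" means positive signed area in array coordinates
    (x = col, y = row).  Vertices carry sub-voxel precision.
    """

    vertices: np.ndarray  # (n, 2) rows, cols
    slice_index: int = 0
    component_id: int = 0
    converged: bool = True
    n_iterations: int = 0
    energy_history: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def signed_area(self) -> float:
        y, x = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def mean_radius(self) -> float:
        c = self.vertices.mean(axis=0)
        return float(np.mean(np.linalg.norm(self.vertices - c, axis=1)))

    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.sum(np.linalg.norm(d, axis=1)))


@dataclass
class BodyCompartments:
    """Per-voxel compartment labels {0 bg, 1 SCAT, 2 VAT, 3 LTW, 4 excluded}."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    slice_range: tuple[int, int] | None = None
    audit: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not set(np.unique(self.labels)).issubset(_VALID_LABELS):
            raise ValueError("labels contain invalid codes")

    def counts(self) -> dict[str, int]:
        u, n = np.unique(self.labels, return_counts=True)
        names = {0: "background", 1: "scat", 2: "vat", 3: "ltw", 4: "excluded"}
        out = {v: 0 for v in names.values()}
        for code, cnt in zip(u, n):
            out[names[int(code)]] = int(cnt)
        return out


# ---------------------------------------------------------------------------
# body masking and skin contour


def body_mask(image: np.ndarray, min_area: int = 50) -> np.ndarray:
    """Binary body mask from a 2-D total-signal image.

    Otsu threshold, morphological closing (disk radius 2), hole filling and
    removal of components smaller than ``min_area``.  Returns an empty mask
    for (near-)constant slices.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("body_mask expects a 2-D image")
    if not np.any(img > 0) or np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=bool)
    thr = threshold_otsu(img)
    mask = img > thr
    mask = binary_closing(mask, structure=morphology.disk(2))
    mask = binary_fill_holes(mask)
    lab = measure.label(mask, connectivity=2)
    keep = np.flatnonzero(np.bincount(lab.ravel())[1:] >= min_area) + 1
    return np.isin(lab, keep)


def mask_components(mask: np.ndarray) -> list[np.ndarray]:
    """Connected components of a body mask, sorted by area (largest first)."""
    lab = measure.label(mask, connectivity=2)
    comps = [(lab == i) for i in range(1, lab.max() + 1)]
    comps.sort(key=lambda m: -int(m.sum()))
    return comps


def _resample_closed(vertices: np.ndarray, n: int) -> np.ndarray:
    closed = np.vstack([vertices, vertices[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    if total == 0:
        return np.repeat(vertices[:1], n, axis=0)
    targets = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(targets, arclen, closed[:, 0])
    out[:, 1] = np.interp(targets, arclen, closed[:, 1])
    return out


def outer_contour(component: np.ndarray, n_vertices: int = 200, slice_index: int = 0,
                  component_id: int = 0) -> Contour:
    """Outer boundary polygon of a mask component, resampled to ``n_vertices``."""
    comp = np.asarray(component, dtype=bool)
    if not comp.any():
        raise ValueError("component is empty")
    contours = measure.find_contours(comp.astype(float), 0.5)
    if not contours:
        raise ValueError("no boundary found")
    verts = max(contours, key=lambda c: len(c))
    if np.allclose(verts[0], verts[-1]):
        verts = verts[:-1]
    n = n_vertices
    if len(verts) < n_vertices:
        n = max(len(verts), 4)
        logger.warning("component boundary has only %d points; reducing vertices", len(verts))
    c = Contour(_resample_closed(verts, n), slice_index, component_id)
    if c.signed_area() < 0:
        c.vertices = c.vertices[::-1].copy()
    return c


# ---------------------------------------------------------------------------
# snake evolution


def _implicit_matrix(n: int, params: SnakeParams) -> np.ndarray:
    """(I + γ(αD2 + βD4))⁻¹ for a closed contour of n vertices."""
    d2 = np.zeros(n)
    d2[[0, 1, -1]] = [2.0, -1.0, -1.0]
    d4 = np.zeros(n)
    d4[[0, 1, 2, -2, -1]] = [6.0, -4.0, 1.0, 1.0, -4.0]
    first_row = params.gamma * (params.alpha * d2 + params.beta * d4)
    first_row[0] += 1.0
    M = np.empty((n, n))
    for i in range(n):
        M[i] = np.roll(first_row, i)
    return np.linalg.inv(M)


def _inward_normals(vertices: np.ndarray, ccw: bool) -> np.ndarray:
    tang = np.roll(vertices, -1, axis=0) - np.roll(vertices, 1, axis=0)
    norm = np.linalg.norm(tang, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    tang = tang / norm
    # rotate tangent by 90°: for a CCW polygon (positive area in (x=col, y=row))
    # the inward normal is (t_col, -t_row) in (row, col) components
    inward = np.stack([tang[:, 1], -tang[:, 0]], axis=1)
    if not ccw:
        inward = -inward
    return inward


def _sample(field2d: np.ndarray, pts: np.ndarray) -> np.ndarray:
    return map_coordinates(field2d, [pts[:, 0], pts[:, 1]], order=1, mode="nearest")


def evolve_snake(init: Contour, fat_image: np.ndarray, params: SnakeParams) -> Contour:
    """Evolve a closed snake inward on a fat image until it locks on an edge.

    Returns the converged contour (the deep-fascia boundary when started from
    the skin contour).  Non-convergence at ``max_iter`` returns the last
    contour with ``converged=False``.
    """
    img = np.asarray(fat_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("fat_image must be 2-D")
    peak = img.max()
    norm_img = img / peak if peak > 0 else img
    smooth = gaussian_filter(norm_img, params.sigma)
    edge = np.hypot(*np.gradient(gaussian_filter(norm_img, params.sigma)))
    egy, egx = np.gradient(edge)
    gate_thr = params.balloon_gate * smooth.max()

    v = _resample_closed(np.asarray(init.vertices, dtype=float), params.n_vertices)
    ccw = Contour(v).signed_area() > 0
    Minv = _implicit_matrix(len(v), params)

    energies = []
    quiet = 0
    it = 0
    converged = False
    for it in range(1, params.max_iter + 1):
        normals = _inward_normals(v, ccw)
        ahead = v + params.lookahead * normals
        gate = _sample(smooth, ahead) >= gate_thr
        f_edge = params.edge_weight * np.stack([_sample(egy, v), _sample(egx, v)], axis=1)
        f_balloon = params.kappa * normals * gate[:, None]
        force = f_edge + f_balloon
        v_new = Minv @ (v + params.gamma * force)
        disp = float(np.mean(np.linalg.norm(v_new - v, axis=1)))
        v = _resample_closed(v_new, params.n_vertices)
        # collapse guard: stop before the polygon degenerates
        if abs(Contour(v).signed_area()) < 4.0:
            logger.warning("snake collapsed at iteration %d", it)
            break
        energies.append(_snake_energy(v, edge, params))
        if disp < params.tol:
            quiet += 1
            if quiet >= params.patience:
                converged = True
                break
        else:
            quiet = 0
    if not converged:
        logger.warning("snake did not converge after %d iterations", it)
    return Contour(
        v, init.slice_index, init.component_id, converged=converged, n_iterations=it,
        energy_history=np.asarray(energies),
    )


def _snake_energy(v: np.ndarray, edge: np.ndarray, params: SnakeParams) -> float:
    d1 = np.roll(v, -1, axis=0) - v
    d2 = np.roll(v, -1, axis=0) - 2 * v + np.roll(v, 1, axis=0)
    e_int = params.alpha * np.sum(d1**2) + params.beta * np.sum(d2**2)
    e_ext = -params.edge_weight * float(np.sum(_sample(edge, v)))
    return float(e_int + e_ext)


# ---------------------------------------------------------------------------
# compartment labeling


def label_compartments(
    ff_slice: np.ndarray,
    component: np.ndarray,
    inner: Contour,
    exclusion: np.ndarray | None = None,
    ff_threshold: float = 0.5,
) -> np.ndarray:
    """Label one component of one slice into SCAT / VAT / LTW / excluded.

    SCAT: fat-fraction ≥ threshold between the component boundary and the
    inner (fascia) contour; VAT: fatty voxels strictly inside the contour;
    LTW: water-dominant voxels anywhere in the component; exclusion-mask
    voxels get the excluded label and are removed from all compartments.
    """
    comp = np.asarray(component, dtype=bool)
    ff = np.asarray(ff_slice, dtype=float)
    labels = np.zeros(comp.shape, dtype=np.uint8)
    inside = polygon2mask(comp.shape, inner.vertices)
    if inside.sum() < 1 or abs(inner.signed_area()) < 1.0:
        logger.warning("degenerate inner contour; labeling all in-body fat as SCAT")
        inside = np.zeros(comp.shape, dtype=bool)
    fatty = ff >= ff_threshold
    labels[comp & fatty & ~inside] = LABEL_SCAT
    labels[comp & fatty & inside] = LABEL_VAT
    labels[comp & ~fatty] = LABEL_LTW
    if exclusion is not None:
        labels[comp & np.asarray(exclusion, dtype=bool)] = LABEL_EXCLUDED
    return labels


def segment_volume(
    fw: FatWaterResult,
    spacing: tuple[float, float, float],
    params: SnakeParams | None = None,
    exclusions: np.ndarray | None = None,
    slice_range: tuple[int, int] | None = None,
    min_area: int = 50,
    ff_threshold: float = 0.5,
) -> BodyCompartments:
    """Run the per-slice, per-component pipeline over a fat/water volume.

    Slices outside ``slice_range`` (half-open, caudal→cranial) are left
    unlabeled.  A failing slice is marked excluded rather than aborting the
    volume.
    """
    params = params or SnakeParams()
    total = fw.W + fw.F
    n_slices = total.shape[0]
    lo, hi = slice_range if slice_range is not None else (0, n_slices)
    lo, hi = max(0, lo), min(n_slices, hi)
    labels = np.zeros(total.shape, dtype=np.uint8)
    for s in range(lo, hi):
        try:
            mask = body_mask(total[s], min_area=min_area)
            if not mask.any():
                logger.info("slice %d: empty body mask, skipped", s)
                continue
            excl = exclusions[s] if exclusions is not None else None
            for cid, comp in enumerate(mask_components(mask)):
                init = outer_contour(comp, params.n_vertices, s, cid)
                inner = evolve_snake(init, fw.F[s], params)
                lab = label_compartments(fw.FF[s], comp, inner, excl, ff_threshold)
                labels[s][comp] = lab[comp]
        except Exception:  # pragma: no cover - defensive per-slice guard
            logger.exception("slice %d failed; marking as excluded", s)
            labels[s][body_mask(total[s], min_area=min_area)] = LABEL_EXCLUDED
    return BodyCompartments(labels=labels, spacing=spacing, slice_range=(lo, hi))


def apply_manual_override(
    compartments: BodyCompartments, correction: np.ndarray, new_label: int
) -> BodyCompartments:
    """Reassign correction-mask voxels to ``new_label``, recording an audit entry."""
    if new_label not in _VALID_LABELS:
        raise ValueError(f"invalid label code {new_label}")
    corr = np.asarray(correction, dtype=bool)
    if corr.shape != compartments.labels.shape:
        raise ValueError("correction mask shape does not match the label volume")
    labels = compartments.labels.copy()
    changed = int(np.count_nonzero(labels[corr] != new_label))
    labels[corr] = new_label
    entry = {
        "voxels_changed": changed,
        "new_label": int(new_label),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    return BodyCompartments(
        labels=labels,
        spacing=compartments.spacing,
        slice_range=compartments.slice_range,
        audit=[*compartments.audit, entry],
    )
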