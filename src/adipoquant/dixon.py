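"""Fat–water decomposition of multi-echo Dixon series.

Three-point path (flexible echo times)
--------------------------------------
Per voxel the signal model with real, non-negative water/fat amplitudes is

    s_k = (W + F·c_k) · exp(i·2π·ψ·TE_k),      c_k = exp(i·2π·Δf·TE_k),

with ψ the local off-resonance in Hz.  For a trial ψ the demodulated samples
d_k = s_k·exp(−i·2π·ψ·TE_k) are fitted by non-negative least squares over
(W, F), defining the residual profile

    R(ψ) = min_{W,F ≥ 0} Σ_k |d_k − W − F·c_k|².

R(ψ) has two relevant local minima over one aliasing window: the true field
value and a fat/water-swapped alias offset by roughly ±Δf.  The voxelwise
candidate pair is disambiguated by growing a spatially smooth field from a
high-magnitude water-likely seed (fat/water "swap" correction).

Two-point path (nominal in/opposed-phase)
-----------------------------------------
The dual-echo protocol treats echo 1 as opposed-phase (OP) and echo 2 as
in-phase (IP).  A smooth error-phasor field is estimated from the squared
first-echo phasor (squaring cancels the sign of W − F), the signals are
demodulated, and W = (IP + OP)/2, F = (IP − OP)/2 with clamping at zero.  A
magnitude-only fallback uses |s₂| and |s₁|, which cannot resolve fat-dominant
voxels (documented swap limitation).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .protocols import AcquisitionProtocol, EchoSeries

__all__ = [
    "FatWaterResult",
    "CandidateField",
    "residual_profile",
    "psi_search_window",
    "three_point_candidates",
    "resolve_phasor_field",
    "decompose_three_point",
    "decompose_two_point",
    "fat_fraction",
]


@dataclass
class FatWaterResult:
    """Water/fat maps with the derived fat fraction and diagnostics."""

    W: np.ndarray
    F: np.ndarray
    FF: np.ndarray
    psi_hz: np.ndarray | None
    residual: np.ndarray
    method: str
    mask: np.ndarray
    magnitude_only: bool = False

    def __post_init__(self) -> None:
        if np.any(self.W < 0) or np.any(self.F < 0):
            raise ValueError("W and F must be non-negative")
        if np.any(self.residual < -1e-9):
            raise ValueError("residual must be non-negative")
        self.residual = np.maximum(self.residual, 0.0)


@dataclass
class CandidateField:
    """Per-voxel pair of off-resonance candidates with conditional residuals.

    Arrays have shape (2,) + volume shape; candidate 0 has the lower residual.
    Voxels outside the mask hold NaN.  ``degenerate`` flags (near-)zero-signal
    voxels whose two candidates coincide at ψ = 0.
    """

    psi_hz: np.ndarray
    residual: np.ndarray
    magnitude: np.ndarray
    mask: np.ndarray
    protocol: AcquisitionProtocol
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# residual profile machinery


def _fat_phasor(protocol: AcquisitionProtocol) -> np.ndarray:
    return np.exp(2j * np.pi * protocol.fat_water_offset_hz * protocol.echo_times_s)


def _gram(protocol: AcquisitionProtocol) -> tuple[np.ndarray, np.ndarray]:
    """Gram matrix of the real-linear design [1, c] acting on stacked Re/Im data."""
    c = _fat_phasor(protocol)
    K = len(c)
    g12 = float(np.sum(c.real))
    G = np.array([[K, g12], [g12, K]], dtype=float)
    return G, c


def _clamped_fit(d: np.ndarray, protocol: AcquisitionProtocol):
    """Minimize Σ|d_k − W − F·c_k|² over W, F ≥ 0, vectorized over leading axes.

    Returns (W, F, residual).  The unconstrained 2×2 normal equations are
    solved first; if a coefficient is negative the two boundary fits (W = 0 or
    F = 0) are compared and the better one taken — exact for a 2-variable NNLS.
    """
    G, c = _gram(protocol)
    h1 = d.real.sum(axis=-1)
    h2 = np.einsum("...k,k->...", d, c.conj()).real
    det = G[0, 0] * G[1, 1] - G[0, 1] ** 2
    w = (G[1, 1] * h1 - G[0, 1] * h2) / det
    f = (G[0, 0] * h2 - G[0, 1] * h1) / det
    total = np.sum(np.abs(d) ** 2, axis=-1)

    def _res(wv, fv):
        return total - 2 * (wv * h1 + fv * h2) + (
            G[0, 0] * wv**2 + 2 * G[0, 1] * wv * fv + G[1, 1] * fv**2
        )

    neg = (w < 0) | (f < 0)
    if np.any(neg):
        w_b1 = np.maximum(h1 / G[0, 0], 0.0)
        f_b2 = np.maximum(h2 / G[1, 1], 0.0)
        r1 = _res(w_b1, 0.0)
        r2 = _res(0.0, f_b2)
        use1 = r1 <= r2
        w = np.where(neg, np.where(use1, w_b1, 0.0), w)
        f = np.where(neg, np.where(use1, 0.0, f_b2), f)
    res = np.maximum(_res(w, f), 0.0)
    return w, f, res


def _profile_grid(s: np.ndarray, protocol: AcquisitionProtocol, grid: np.ndarray):
    """Clamped residual R(ψ) on a ψ grid for many voxels at once.

    Exploits that only the demodulation phases depend on ψ: the normal-
    equation right-hand sides h₁(ψ), h₂(ψ) are two complex matmuls, after
    which the clamped 2-variable fit is elementwise.  Returns R with shape
    (n_voxels, n_grid).
    """
    G, c = _gram(protocol)
    te = protocol.echo_times_s
    P = np.exp(-2j * np.pi * te[:, None] * grid[None, :])  # (K, G)
    h1 = (s @ P).real  # (n, G)
    h2 = ((s * c.conj()[None, :]) @ P).real
    total = np.sum(np.abs(s) ** 2, axis=-1)[:, None]
    det = G[0, 0] * G[1, 1] - G[0, 1] ** 2
    w = (G[1, 1] * h1 - G[0, 1] * h2) / det
    f = (G[0, 0] * h2 - G[0, 1] * h1) / det
    # at each constrained optimum the residual is total − x·h, so only the
    # three candidate optima (interior, W-axis, F-axis) need evaluating
    r_int = total - (w * h1 + f * h2)
    r_w = total - np.maximum(h1, 0.0) * h1 / G[0, 0]
    r_f = total - np.maximum(h2, 0.0) * h2 / G[1, 1]
    R = np.where((w < 0) | (f < 0), np.minimum(r_w, r_f), r_int)
    return np.maximum(R, 0.0)


def residual_profile(
    signals: np.ndarray, protocol: AcquisitionProtocol, psi_hz: float
) -> tuple[float, float, float]:
    """Evaluate R(ψ) for one voxel: returns (residual, W, F) at the given ψ.

    ``signals`` is the complex per-echo vector s_1..s_K.
    """
    s = np.asarray(signals, dtype=complex)
    if s.ndim != 1 or s.size != protocol.n_echoes:
        raise ValueError("signals must be a 1-D vector with one sample per echo")
    d = s * np.exp(-2j * np.pi * psi_hz * protocol.echo_times_s)
    w, f, res = _clamped_fit(d[None, :], protocol)
    return float(res[0]), float(w[0]), float(f[0])


def psi_search_window(protocol: AcquisitionProtocol) -> tuple[float, float]:
    """Off-resonance search window [−1/(2ΔTE), +1/(2ΔTE)) from the first echo pair."""
    dte = protocol.echo_times_s[1] - protocol.echo_times_s[0]
    half = 1.0 / (2.0 * dte)
    return -half, half


# ---------------------------------------------------------------------------
# three-point candidates


def three_point_candidates(
    series: EchoSeries,
    mask: np.ndarray | None = None,
    grid_step_hz: float = 8.0,
    chunk: int = 8192,
) -> CandidateField:
    """Locate the two lowest local minima of R(ψ) per in-mask voxel.

    The residual profile is evaluated on a uniform ψ grid over one aliasing
    window and the two best local minima are refined by golden-section search
    within their brackets, matching a dense grid search to well below 1 Hz.
    """
    if series.protocol.n_echoes != 3:
        raise ValueError("three_point_candidates requires exactly 3 echoes")
    if series.magnitude_only:
        raise ValueError("three-point decomposition requires complex data")
    shape = series.data.shape[:-1]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")

    protocol = series.protocol
    lo, hi = psi_search_window(protocol)
    grid = np.arange(lo, hi, grid_step_hz)
    te = protocol.echo_times_s

    svox = series.data[mask]  # (N, K)
    n = svox.shape[0]
    mag = np.abs(svox).max(axis=-1)
    eps = 1e-9 * (mag.max() if mag.size else 1.0)
    psi_c = np.zeros((n, 2))
    res_c = np.zeros((n, 2))

    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        s = svox[sl]
        R = _profile_grid(s, protocol, grid)  # (n, G)
        # local minima on the (non-periodic) window, endpoints included
        interior = (R[:, 1:-1] <= R[:, :-2]) & (R[:, 1:-1] <= R[:, 2:])
        is_min = np.zeros_like(R, dtype=bool)
        is_min[:, 1:-1] = interior
        is_min[:, 0] = R[:, 0] <= R[:, 1]
        is_min[:, -1] = R[:, -1] <= R[:, -2]
        Rm = np.where(is_min, R, np.inf)
        # refine the three best coarse minima and keep the best two distinct
        # basins afterwards (plateaus can make coarse ordering unreliable)
        order = np.argsort(Rm, axis=1)[:, :3]
        rows = np.arange(R.shape[0])[:, None]
        idx = order
        best_res = Rm[rows, idx]
        for j in (1, 2):  # voxels with fewer local minima: duplicate the best
            missing = ~np.isfinite(best_res[:, j])
            idx[missing, j] = idx[missing, 0]
        def _exact(p):
            dref = s[:, None, :] * np.exp(-2j * np.pi * p[..., None] * te)
            return _clamped_fit(dref, protocol)[2]

        # golden-section refinement of each bracketed minimum, vectorized
        # over voxels (the bracket is one grid step to either side)
        lo_b = np.maximum(grid[idx] - grid_step_hz, lo)
        hi_b = np.minimum(grid[idx] + grid_step_hz, hi - 1e-9)
        invphi = (np.sqrt(5.0) - 1.0) / 2.0
        for _ in range(22):
            x1 = hi_b - invphi * (hi_b - lo_b)
            x2 = lo_b + invphi * (hi_b - lo_b)
            take_left = _exact(x1) < _exact(x2)
            hi_b = np.where(take_left, x2, hi_b)
            lo_b = np.where(take_left, lo_b, x1)
        psi = (lo_b + hi_b) / 2.0
        rref = _exact(psi)
        # never accept a refinement worse than the grid sample
        worse = rref > R[rows, idx]
        psi = np.where(worse, grid[idx], psi)
        rref = np.where(worse, R[rows, idx], rref)
        # best candidate, then the best one from a different basin (≥ 2 Hz away)
        ordr = np.argsort(rref, axis=1)
        psi_s = np.take_along_axis(psi, ordr, axis=1)
        res_s = np.take_along_axis(rref, ordr, axis=1)
        first_psi, first_res = psi_s[:, 0], res_s[:, 0]
        distinct = np.abs(psi_s - first_psi[:, None]) >= 2.0
        distinct[:, 0] = True
        pick = np.where(distinct[:, 1], 1, np.where(distinct[:, 2], 2, 1))
        second_psi = np.take_along_axis(psi_s, pick[:, None], axis=1)[:, 0]
        second_res = np.take_along_axis(res_s, pick[:, None], axis=1)[:, 0]
        psi_c[sl] = np.stack([first_psi, second_psi], axis=1)
        res_c[sl] = np.stack([first_res, second_res], axis=1)

    degen = mag < eps
    psi_c[degen] = 0.0
    res_c[degen] = 0.0

    full = np.full((2, *shape), np.nan)
    fres = np.full((2, *shape), np.nan)
    for j in range(2):
        tmp = np.full(shape, np.nan)
        tmp[mask] = psi_c[:, j]
        full[j] = tmp
        tmp = np.full(shape, np.nan)
        tmp[mask] = res_c[:, j]
        fres[j] = tmp
    mag_map = np.zeros(shape)
    mag_map[mask] = mag
    degen_map = np.zeros(shape, dtype=bool)
    degen_map[mask] = degen
    return CandidateField(
        psi_hz=full, residual=fres, magnitude=mag_map, mask=mask, protocol=protocol,
        degenerate=degen_map,
    )


# ---------------------------------------------------------------------------
# swap resolution by region growing


def resolve_phasor_field(
    cands: CandidateField,
    mask: np.ndarray | None = None,
    series: EchoSeries | None = None,
) -> np.ndarray:
    """Select one ψ candidate per voxel so the field is spatially smooth.

    Region growing runs per slice: starting from the highest-magnitude
    water-likely seed voxel (its lower-residual candidate, ties broken toward
    the water-dominant interpretation), voxels are visited in descending
    magnitude order and take the candidate whose phasor is closest to the mean
    phasor of already-resolved neighbors in a 3×3 window.
    """
    if mask is None:
        mask = cands.mask
    mask = np.asarray(mask, dtype=bool) & cands.mask
    shape = cands.magnitude.shape
    psi = np.full(shape, np.nan)
    if not mask.any():
        return psi

    dte = cands.protocol.echo_times_s[1] - cands.protocol.echo_times_s[0]
    # phasor representation: one aliasing window maps onto the unit circle
    ph = np.exp(2j * np.pi * cands.psi_hz * dte)  # (2, S, R, C)

    for sl in range(shape[0]):
        m2 = mask[sl]
        if not m2.any():
            continue
        seed_rc = _pick_seed(cands, series, sl, m2)
        resolved = np.zeros(m2.shape, dtype=bool)
        chosen = np.zeros(m2.shape, dtype=np.int8)
        heap: list[tuple[float, int, int]] = []
        r0, c0 = seed_rc
        chosen[r0, c0] = _seed_candidate(cands, series, sl, r0, c0)
        resolved[r0, c0] = True
        _push_neighbors(heap, cands.magnitude[sl], m2, resolved, r0, c0)
        while heap:
            negmag, r, c = heapq.heappop(heap)
            if resolved[r, c]:
                continue
            acc = 0j
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < m2.shape[0] and 0 <= cc < m2.shape[1] and resolved[rr, cc]:
                        acc += ph[chosen[rr, cc], sl, rr, cc]
            if acc == 0:
                pick = 0
            else:
                d0 = abs(np.angle(ph[0, sl, r, c] * np.conj(acc)))
                d1 = abs(np.angle(ph[1, sl, r, c] * np.conj(acc)))
                pick = 0 if d0 <= d1 else 1
            chosen[r, c] = pick
            resolved[r, c] = True
            _push_neighbors(heap, cands.magnitude[sl], m2, resolved, r, c)
        sel = np.where(chosen == 0, cands.psi_hz[0, sl], cands.psi_hz[1, sl])
        psi[sl] = np.where(resolved, sel, np.nan)
    return psi


def _push_neighbors(heap, mag2, mask2, resolved, r, c):
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < mask2.shape[0] and 0 <= cc < mask2.shape[1]:
                if mask2[rr, cc] and not resolved[rr, cc]:
                    heapq.heappush(heap, (-float(mag2[rr, cc]), rr, cc))


def _candidate_wf(cands: CandidateField, series: EchoSeries, sl: int, r: int, c: int, j: int):
    s = series.data[sl, r, c]
    te = cands.protocol.echo_times_s
    d = s * np.exp(-2j * np.pi * cands.psi_hz[j, sl, r, c] * te)
    w, f, _ = _clamped_fit(d[None, :], cands.protocol)
    return float(w[0]), float(f[0])


def _seed_candidate(cands: CandidateField, series: EchoSeries | None, sl: int, r: int, c: int) -> int:
    """Candidate index at the seed: lower residual, near-ties toward water."""
    res0, res1 = cands.residual[0, sl, r, c], cands.residual[1, sl, r, c]
    tol = 1e-6 * max(cands.magnitude[sl, r, c] ** 2, 1e-300)
    if series is not None and abs(res0 - res1) <= tol:
        w0, f0 = _candidate_wf(cands, series, sl, r, c, 0)
        w1, f1 = _candidate_wf(cands, series, sl, r, c, 1)
        return 0 if (w0 - f0) >= (w1 - f1) else 1
    return 0 if res0 <= res1 else 1


def _pick_seed(
    cands: CandidateField, series: EchoSeries | None, sl: int, m2: np.ndarray
) -> tuple[int, int]:
    mag = np.where(m2, cands.magnitude[sl], -np.inf)
    order = np.argsort(mag, axis=None)[::-1]
    fallback = None
    limit = min(500, int(m2.sum()))
    for flat in order[:limit]:
        r, c = np.unravel_index(flat, mag.shape)
        if not np.isfinite(mag[r, c]):
            break
        if fallback is None:
            fallback = (r, c)
        if series is None:
            return r, c
        j = _seed_candidate(cands, series, sl, r, c)
        w, f = _candidate_wf(cands, series, sl, r, c, j)
        if w >= f:
            return r, c
    if fallback is None:
        raise ValueError("empty slice mask")
    return fallback


# ---------------------------------------------------------------------------
# full decompositions


def _default_mask(series: EchoSeries) -> np.ndarray:
    mag = np.abs(series.data).max(axis=-1)
    return mag > 1e-6 * mag.max()


def decompose_three_point(
    series: EchoSeries,
    mask: np.ndarray | None = None,
    grid_step_hz: float = 8.0,
) -> FatWaterResult:
    """Three-point decomposition: candidates → swap resolution → amplitude fit."""
    if series.protocol.n_echoes != 3:
        raise ValueError("decompose_three_point requires exactly 3 echoes")
    if mask is None:
        mask = _default_mask(series)
    cands = three_point_candidates(series, mask, grid_step_hz=grid_step_hz)
    psi = resolve_phasor_field(cands, mask, series=series)
    te = series.protocol.echo_times_s
    shape = series.data.shape[:-1]
    W = np.zeros(shape)
    F = np.zeros(shape)
    res = np.zeros(shape)
    psi_filled = np.where(np.isfinite(psi), psi, 0.0)
    d = series.data * np.exp(-2j * np.pi * psi_filled[..., None] * te)
    w, f, r = _clamped_fit(d, series.protocol)
    W[mask], F[mask], res[mask] = w[mask], f[mask], r[mask]
    return FatWaterResult(
        W=W, F=F, FF=fat_fraction(W, F), psi_hz=psi, residual=res,
        method="three_point", mask=mask,
    )


def decompose_two_point(
    series: EchoSeries,
    mask: np.ndarray | None = None,
    smooth_sigma: float = 5.0,
) -> FatWaterResult:
    """Two-point in/opposed-phase decomposition for the dual-echo protocol.

    Complex input: the smooth phase-error field is estimated from the squared
    opposed-phase echo (squaring cancels the W − F sign), halved and used to
    demodulate both echoes; then W = (IP + OP)/2 and F = (IP − OP)/2, clamped
    at zero.  The halving limits the resolvable off-resonance to
    |ψ| < 1/(4·TE₁) (≈ 189 Hz for TE₁ = 1.32 ms).

    Magnitude input: OP = |s₁|, IP = |s₂|; fat-dominant voxels come out
    swapped (W and F exchanged) — flagged via ``magnitude_only``.
    """
    if series.protocol.n_echoes != 2:
        raise ValueError("decompose_two_point requires exactly 2 echoes")
    if mask is None:
        mask = _default_mask(series)
    te = series.protocol.echo_times_s
    s1 = series.data[..., 0]
    s2 = series.data[..., 1]
    psi_map: np.ndarray | None

    if series.magnitude_only or not np.iscomplexobj(series.data):
        op = np.abs(s1)
        ip = np.abs(s2)
        psi_map = None
        magnitude_only = True
    else:
        q = s1 * s1  # phase 2·(2π ψ TE1), sign of (W−F) squared away
        qs = np.empty_like(q)
        for sl in range(q.shape[0]):
            qs[sl] = gaussian_filter(q[sl].real, smooth_sigma) + 1j * gaussian_filter(
                q[sl].imag, smooth_sigma
            )
        half = np.angle(qs) / 2.0  # ∈ (−π/2, π/2]
        psi_map = half / (2.0 * np.pi * te[0])
        op = (s1 * np.exp(-1j * half)).real
        ip = (s2 * np.exp(-2j * np.pi * psi_map * te[1])).real
        magnitude_only = False

    W = np.maximum((ip + op) / 2.0, 0.0)
    F = np.maximum((ip - op) / 2.0, 0.0)
    model_op = W - F
    model_ip = W + F
    res = (op - model_op) ** 2 + (ip - model_ip) ** 2
    W = np.where(mask, W, 0.0)
    F = np.where(mask, F, 0.0)
    res = np.where(mask, res, 0.0)
    if psi_map is not None:
        psi_map = np.where(mask, psi_map, np.nan)
    return FatWaterResult(
        W=W, F=F, FF=fat_fraction(W, F), psi_hz=psi_map, residual=res,
        method="two_point", mask=mask, magnitude_only=magnitude_only,
    )


def fat_fraction(W: np.ndarray, F: np.ndarray) -> np.ndarray:
    """FF = F/(W+F) where W+F exceeds ε = 1e−6 × global max, else 0."""
    W = np.asarray(W, dtype=float)
    F = np.asarray(F, dtype=float)
    if W.shape != F.shape:
        raise ValueError("W and F must have the same shape")
    if np.any(W < 0) or np.any(F < 0):
        raise ValueError("W and F must be non-negative")
    total = W + F
    eps = 1e-6 * (total.max() if total.size else 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ff = np.where(total > eps, F / np.where(total > eps, total, 1.0), 0.0)
    return ff
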