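"""Scalar descriptors of a landmark curve: size, length, number of turns.

Cochlear length is the summed chord length from the round window to the
apex. The number of turns is the total winding of the curve about its
coiling axis (the modiolus), in revolutions. Neither the axis nor the
center is part of the data, and both must be estimated precisely, which is
the delicate part: a tall cylindrical cochlea winds about its first
principal axis, a flat conical one about its third, and tapered spirals
have principal axes tilted away from the true modiolus.

The estimator proceeds in three stages:

1. *Axis seeding*: the three principal axes of the canonical frame are
   scored by the total turning of the projected chord directions — which
   needs no center and equals the swept angle exactly for a logarithmic
   spiral; the line through the per-full-turn centroids of the curve adds
   a fourth seed (those centroids sit on, or at a turn-decaying offset
   from, the true axis).
2. *Model fit*: from every seed, a helico-spiral model
   ``p = c + e^{alpha + beta th} (cos(th - delta) u + sin(th - delta) v)
   + gamma th a`` is least-squares fitted to the reliable stretch of the
   curve and iterated (a better axis yields better angle estimates and
   vice versa); each iteration's fit is kept as a candidate and the one
   with the smallest per-point residual wins.
3. *Winding*: point angles about the fitted center are unwrapped; windings
   whose radius falls below the reliability floor set by a robust
   digitization-noise estimate (the innermost turns of strongly tapered
   curves, where noise swamps the geometry) are truncated and
   extrapolated from the angular rate of the trailing reliable stretch,
   and a noise-limited apex endpoint is replaced by the same fitted
   endpoint.

All computation happens in a canonical frame (centered, unit scale,
principal axes with deterministic signs), so the count is bit-stable under
rigid motion and uniform scaling of the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .io_formats import LandmarkConfiguration

__all__ = [
    "SpiralMetrics",
    "centroid_size",
    "curve_length",
    "count_turns",
    "UnwrapError",
]

_SOFT = 0.9 * np.pi  # turn increment above which an unwrap step is distrusted
_NOISE_TO_RADIUS = 6.0  # minimum reliable radius in noise-sd units


class UnwrapError(ValueError):
    """Angle increments too large to unwrap; resample the curve more densely."""


@dataclass
class SpiralMetrics:
    centroid_size: float
    cochlear_length: float
    n_turns: float
    coiling_axis: np.ndarray  # unit 3-vector
    axis_center: np.ndarray  # 3D point on the axis


def _points(config: LandmarkConfiguration | np.ndarray) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return config.points
    pts = np.asarray(config, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("expected a (k, 3) coordinate array")
    return pts


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Square root of the summed squared distances to the centroid."""
    pts = _points(config)
    if pts.shape[0] < 2:
        raise ValueError("centroid size needs at least 2 points")
    centered = pts - pts.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered**2)))
    if cs == 0.0:
        raise ValueError("all points identical; centroid size undefined")
    return cs


def curve_length(config: LandmarkConfiguration | np.ndarray) -> float:
    """Summed distances between consecutive landmarks, base to apex."""
    pts = _points(config)
    if pts.shape[0] < 2:
        raise ValueError("curve length needs at least 2 points")
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


# ---------------------------------------------------------------------------
# turn counting machinery
# ---------------------------------------------------------------------------

def _plane_basis(axis: np.ndarray) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return np.column_stack([u, v])


def _axial_noise_sd(centered: np.ndarray, axis: np.ndarray) -> float:
    """Robust per-coordinate noise estimate from axial second differences.

    The axial coordinate of a coiled curve is nearly linear between
    neighbouring samples, so its second differences are noise-dominated
    (the second difference of i.i.d. noise has sd sqrt(6) sigma).
    """
    z = centered @ (axis / np.linalg.norm(axis))
    if len(z) < 5:
        return 0.0
    d2 = np.diff(z, n=2)
    mad = np.median(np.abs(d2 - np.median(d2)))
    return float(mad / 0.6745 / np.sqrt(6.0))


def _unwrap(angles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    inc = np.diff(angles)
    inc = (inc + np.pi) % (2.0 * np.pi) - np.pi
    return angles[0] + np.concatenate([[0.0], np.cumsum(inc)]), inc


def _trailing_cut(low: np.ndarray) -> int:
    """Start index of the trailing mostly-low run (len(low) if none).

    The noise-dominated apex region is identified as the longest suffix in
    which at least 60% of entries are low; isolated dips elsewhere, or an
    isolated non-low fluke at the very end, do not affect the cut.
    """
    n = len(low)
    if not low.any():
        return n
    suffix_mean = np.cumsum(low[::-1]) / np.arange(1, n + 1)
    good = np.nonzero(suffix_mean >= 0.6)[0]
    if len(good) == 0:
        return n
    start = n - (int(good.max()) + 1)
    while start < n and not low[start]:
        start += 1
    return start


def _smooth_median(x: np.ndarray, win: int = 7) -> np.ndarray:
    win = min(win, len(x)) | 1
    pad = win // 2
    padded = np.pad(x, pad, mode="edge")
    return np.array([np.median(padded[i : i + win]) for i in range(len(x))])


def _chord_turning(centered: np.ndarray, axis: np.ndarray, sigma: float = 0.0):
    """Center-free winding score: unwrapped turning of projected chords.

    When digitization noise is comparable to the single-step chord length,
    chords are taken over a span of ``g`` points (direction noise falls as
    1/g). Chords still shorter than the wrap-safety floor (4 sigma:
    direction noise on such a chord can flip its apparent turning) form a
    trailing apex run excluded from the turning score — ``cut`` marks its
    start. ``theta`` maps the unwrapped chord directions back onto a
    per-point angular coordinate for the reliable stretch.
    """
    n = len(centered)
    P = centered @ _plane_basis(axis)
    step = np.linalg.norm(np.diff(P, axis=0), axis=1)
    if np.all(step < 1e-300):
        return None
    g = 1
    med = float(np.median(step))
    if sigma > 0 and med > 0:
        g = int(np.clip(np.ceil(6.0 * sigma / med), 1, max(1, n // 20)))
    chords = P[g:] - P[:-g]
    lengths = np.linalg.norm(chords, axis=1)
    if np.all(lengths < 1e-300):
        return None
    phi, inc = _unwrap(np.arctan2(chords[:, 1], chords[:, 0]))
    m = len(phi)
    cut = m
    if sigma > 0:
        cut = _trailing_cut(_smooth_median(lengths) < 4.0 * sigma)
    if cut < 2:
        return None
    seg = inc[: cut - 1]
    bad = float(np.mean(np.abs(seg) > _SOFT)) if len(seg) else 1.0
    # winding about the true axis is monotone: its increments share a sign,
    # while an in-plane projection oscillates and cancels
    denom = float(np.sum(np.abs(seg)))
    ratio = float(abs(np.sum(seg)) / denom) if denom > 0 else 0.0

    # per-point angle for the reliable stretch: chord j sits at index j+g/2
    pos = np.arange(cut) + g / 2.0
    pphi = phi[:cut]
    idx = np.arange(n, dtype=float)
    theta = np.interp(idx, pos, pphi)
    if cut > 1:  # linear extrapolation beyond the chord midpoints
        s0 = (pphi[1] - pphi[0]) / (pos[1] - pos[0])
        s1 = (pphi[-1] - pphi[-2]) / (pos[-1] - pos[-2])
        lo, hi = idx < pos[0], idx > pos[-1]
        theta[lo] = pphi[0] + (idx[lo] - pos[0]) * s0
        theta[hi] = pphi[-1] + (idx[hi] - pos[-1]) * s1
    point_cut = min(n, int(np.floor(pos[-1])) + 1)
    return {"P": P, "phi": phi, "lengths": lengths, "cut": cut, "g": g,
            "theta": theta, "point_cut": point_cut, "ratio": ratio,
            "turning": float(phi[cut - 1] - phi[0]), "bad_frac": bad}


def _turn_centroid_axis(centered: np.ndarray, theta: np.ndarray) -> np.ndarray | None:
    """Axis direction from the line through per-full-turn 3D centroids."""
    t = np.abs(theta - theta[0])
    bins = np.floor(t / (2.0 * np.pi)).astype(int)
    # only bins covering a full revolution; a partial apex turn would bias
    complete = [b for b in np.unique(bins) if b + 1 <= t.max() / (2.0 * np.pi) + 1e-9]
    cents = np.array([centered[bins == b].mean(axis=0) for b in complete])
    if len(cents) < 2:
        return None
    spread = cents - cents.mean(axis=0)
    if np.linalg.norm(spread) < 1e-12 * max(np.linalg.norm(centered), 1e-300):
        return None
    _, _, Vt = np.linalg.svd(spread, full_matrices=False)
    return Vt[0] / np.linalg.norm(Vt[0])


def _fit_spiral(centered: np.ndarray, axis0: np.ndarray, theta: np.ndarray,
                reliable: np.ndarray, sigma: float):
    """Least-squares fit of a helico-spiral to the landmark curve.

    Model: p_i = c + e^{alpha + beta th_i} (cos(th_i - delta) u +
    sin(th_i - delta) v) + gamma th_i a, where (u, v, a) is an orthonormal
    frame whose axis a is parametrized as a rotation of ``axis0``. Exact
    for a logarithmic helico-spiral; for general coiled curves it is an
    approximation used only to locate the coiling axis and center.

    Returns (axis, center3d, per_point_residuals) or None.
    """
    B0 = _plane_basis(axis0)
    u0, v0 = B0[:, 0], B0[:, 1]
    a0 = np.asarray(axis0) / np.linalg.norm(axis0)

    pts = centered[reliable]
    th = theta[reliable]
    if len(pts) < 12:
        return None

    # initial values from the projection on axis0
    P = pts @ B0
    z = pts @ a0
    span = np.abs(th - th[0])
    if span.max() >= 2.0 * np.pi:
        inner = span >= span.max() - 2.0 * np.pi
        c0_2d = P[inner].mean(axis=0)
    else:
        m = max(2, int(0.1 * len(P)))
        c0_2d = P[-m:].mean(axis=0)
    rel = P - c0_2d
    r0 = np.maximum(np.linalg.norm(rel, axis=1), 1e-12)
    raw = np.arctan2(rel[:, 1], rel[:, 0])
    dlt = th - raw
    delta0 = float(np.arctan2(np.mean(np.sin(dlt)), np.mean(np.cos(dlt))))
    beta0, alpha0 = (float(x) for x in np.polyfit(th, np.log(r0), 1))
    gamma0, z0 = (float(x) for x in np.polyfit(th, z, 1))
    scale = float(np.max(np.linalg.norm(centered, axis=1)))

    def frame(tu, tv):
        a = a0 + tu * u0 + tv * v0
        a = a / np.linalg.norm(a)
        B = _plane_basis(a)
        return a, B[:, 0], B[:, 1]

    def resid(params):
        cx, cy, cz, tu, tv, delta, alpha, beta, gamma = params
        a, u, v = frame(tu, tv)
        r = np.exp(np.clip(alpha + beta * th, -60.0, 60.0))
        model = (
            np.array([cx, cy, cz])
            + r[:, None] * (np.cos(th - delta)[:, None] * u
                            + np.sin(th - delta)[:, None] * v)
            + (gamma * th)[:, None] * a
        )
        return (pts - model).ravel()

    x0 = [*(c0_2d[0] * u0 + c0_2d[1] * v0 + z0 * a0),
          0.0, 0.0, delta0, alpha0, beta0, gamma0]
    try:
        sol = least_squares(
            resid, x0=x0, loss="soft_l1",
            f_scale=max(sigma, 1e-3 * scale, 1e-12), max_nfev=400,
        )
    except Exception:
        return None
    cx, cy, cz, tu, tv = sol.x[:5]
    axis, _, _ = frame(tu, tv)
    per_point = np.linalg.norm(resid(sol.x).reshape(-1, 3), axis=1)
    return axis, np.array([cx, cy, cz]), per_point


def _position_winding(P: np.ndarray, center: np.ndarray, sigma: float):
    """Unwrapped winding of points about ``center`` with apex handling.

    Returns (total, max_reliable_step, sign_consistency) or None. Points
    whose radius falls below the noise floor form a trailing run whose
    winding is extrapolated from a polynomial fit of angle against index
    over the trailing reliable stretch (linear, or quadratic when the rate
    clearly drifts); a noise-limited apex endpoint is replaced by the same
    fitted value even without truncation.
    """
    rel = P - center
    radii = np.linalg.norm(rel, axis=1)
    if np.all(radii < 1e-300):
        return None
    psi, inc = _unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
    n = len(psi)
    floor = max(_NOISE_TO_RADIUS * sigma, 1e-12 * float(radii.max()))
    smoothed = _smooth_median(radii)
    low = smoothed < floor

    cut = _trailing_cut(low)
    if cut < 6:
        return None

    def _ratio(increments):
        denom = float(np.sum(np.abs(increments)))
        return float(abs(np.sum(increments)) / denom) if denom > 0 else 0.0

    # even above the truncation floor, the literal apex endpoint angle is
    # noise-limited when its radius is small; a fitted endpoint then beats
    # the raw one
    apex_noisy = sigma > 0 and smoothed[-1] < 5.0 * _NOISE_TO_RADIUS * sigma
    if cut == n and not apex_noisy:
        total = float(psi[-1] - psi[0])
        mstep = float(np.max(np.abs(inc))) if len(inc) else 0.0
        return total, mstep, _ratio(inc)

    # fit over the trailing reliable stretch; spanning full turns averages
    # out the 2*pi-periodic angle wobble a residual center offset induces
    prog = np.abs(psi - psi[0])
    lo = int(np.searchsorted(prog[:cut], prog[cut - 1] - 4.0 * np.pi))
    lo = min(lo, max(0, cut - 30))
    if cut - lo < 6:
        return None
    idx = np.arange(lo, cut, dtype=float)
    seg = psi[lo:cut]
    wts = radii[lo:cut]  # angle noise scales as 1/radius
    fit = np.polyfit(idx, seg, 1, w=wts)

    def wstd(resid):
        return float(np.sqrt(np.sum((wts * resid) ** 2) / np.sum(wts**2)))

    if cut - lo >= 10:
        quad = np.polyfit(idx, seg, 2, w=wts)
        if wstd(seg - np.polyval(quad, idx)) < 0.5 * wstd(seg - np.polyval(fit, idx)):
            fit = quad
    total = float(np.polyval(fit, n - 1) - psi[0])
    mstep = float(np.max(np.abs(inc[: max(cut - 1, 1)])))
    return total, mstep, _ratio(inc[: max(cut - 1, 1)])


def count_turns(config: LandmarkConfiguration | np.ndarray) -> SpiralMetrics:
    """Number of revolutions of a landmark curve about its coiling axis.

    Turns are reported unsigned, so a curve and its mirror image give the
    same count, and the estimate is invariant under rigid motion and
    uniform scaling of the curve.
    """
    pts = _points(config)
    if pts.shape[0] < 10:
        raise ValueError("turn counting needs at least 10 points")
    centroid = pts.mean(axis=0)
    raw_centered = pts - centroid
    size = float(np.sqrt(np.sum(raw_centered**2)))
    if size <= 0:
        raise ValueError("all points identical")
    # canonical frame: principal axes with deterministic signs, so the
    # estimate is bit-stable under rigid motion and uniform scaling
    _, _, Vt0 = np.linalg.svd(raw_centered / size, full_matrices=False)
    basis = Vt0.T.copy()
    normed = raw_centered / size
    for j in range(2):
        proj = normed @ basis[:, j]
        ref = proj[int(np.argmax(np.abs(proj)))]
        if ref < 0:
            basis[:, j] = -basis[:, j]
    basis[:, 2] = np.cross(basis[:, 0], basis[:, 1])
    centered = normed @ basis
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)

    candidates = []
    for axis in Vt:
        axis = np.asarray(axis)
        res = _chord_turning(centered, axis, _axial_noise_sd(centered, axis))
        if res is not None:
            candidates.append((axis, res))
    if not candidates:
        raise UnwrapError("projection degenerate on all principal axes")

    def pick(cands):
        clean = [c for c in cands if c[1]["bad_frac"] == 0.0 and c[1]["ratio"] > 0.9]
        if clean:
            return max(clean, key=lambda c: abs(c[1]["turning"]))
        # sign-consistency discounts the spurious random-walk winding that
        # an in-plane projection accumulates under noise
        return max(cands, key=lambda c: c[1]["ratio"] * abs(c[1]["turning"]))

    best_axis, best_info = pick(candidates)
    if best_info["bad_frac"] > 0.2 and best_info["ratio"] < 0.5:
        raise UnwrapError(
            "chord directions reverse on every candidate axis; the "
            "sampling is too sparse for this curve — resample more densely"
        )

    # every principal axis seeds a model fit: the best-scoring projection
    # can still sit far from the true coiling axis on flat spirals
    seeds = list(candidates)
    # extra seed: the line through per-full-turn centroids is often a far
    # better axis guess than any (possibly tilted) principal axis
    if abs(best_info["turning"]) > 2.0 * np.pi:
        pc = best_info["point_cut"]
        axis2 = _turn_centroid_axis(centered[:pc], best_info["theta"][:pc])
        if axis2 is not None:
            res2 = _chord_turning(centered, axis2, _axial_noise_sd(centered, axis2))
            if res2 is not None:
                seeds.append((axis2, res2))

    def winding_outcome(axis, sigma, center3d, per_point):
        B = _plane_basis(axis)
        center2d = center3d @ B
        wind = _position_winding(centered @ B, center2d, sigma)
        if wind is None:
            return None
        total, mstep, pratio = wind
        if mstep >= np.pi - 1e-9:
            return None
        # score: model misfit per reliable point; digitization noise is
        # isotropic, so rms values over different reliable stretches are
        # directly comparable (with a small-sample guard)
        if per_point is None or len(per_point) < 30:
            score = np.inf
        else:
            score = float(np.sqrt(np.mean(per_point**2)))
        return (axis, B @ center2d, total, pratio, score)

    # from each seed, iterate the helico-spiral model fit; every
    # iteration's fit is kept as a candidate outcome because the iteration
    # can drift away from a good optimum
    outcomes = []
    for axis, info in seeds:
        sigma = _axial_noise_sd(centered, axis)
        for _ in range(4):
            reliable = np.zeros(len(info["theta"]), dtype=bool)
            reliable[: info["point_cut"]] = True
            fit = _fit_spiral(centered, axis, info["theta"], reliable, sigma)
            if fit is None:
                break
            new_axis, center3d, per_point = fit
            if new_axis @ axis < 0:
                new_axis = -new_axis
            converged = abs(new_axis @ axis) > 1.0 - 1e-12
            new_sigma = _axial_noise_sd(centered, new_axis)
            out = winding_outcome(new_axis, new_sigma, center3d, per_point)
            if out is not None:
                outcomes.append(out)
            new_info = _chord_turning(centered, new_axis, new_sigma)
            if new_info is None:
                break
            axis, info, sigma = new_axis, new_info, new_sigma
            if converged:
                break

    if not outcomes:
        raise UnwrapError(
            "too few windings above the noise floor to count turns; "
            "resample the curve more densely or reduce noise"
        )
    # the fit with the smallest per-point residual is the one that reached
    # the spiral model's global optimum (the sign consistency of the
    # winding is too noisy a criterion when per-step angles are small, so
    # it does not gate outcomes)
    best = min(outcomes, key=lambda o: o[4])
    if not np.isfinite(best[4]):
        best = max(outcomes, key=lambda o: o[3] * abs(o[2]))

    # final refinement: refit using position angles about the fitted
    # center as the angular coordinate. Chord directions lose signal at a
    # far larger radius than position angles do (chord length ~ r dθ), so
    # this pass recovers the inner windings for the fit and shrinks the
    # center error that would otherwise corrupt them.
    for _ in range(4):
        axis_b, center3d_b = best[0], best[1]
        sigma_b = _axial_noise_sd(centered, axis_b)
        B = _plane_basis(axis_b)
        relp = centered @ B - center3d_b @ B
        radii = np.linalg.norm(relp, axis=1)
        psi, _ = _unwrap(np.arctan2(relp[:, 1], relp[:, 0]))
        # angles are trustworthy only where the radius clears both the
        # noise floor and the current center uncertainty (~ the fit rms)
        floor_b = max(_NOISE_TO_RADIUS * sigma_b,
                      2.0 * (best[4] if np.isfinite(best[4]) else 0.0),
                      1e-12 * float(radii.max()))
        low = _smooth_median(radii) < floor_b
        cutp = _trailing_cut(low)
        reliable = np.zeros(len(psi), dtype=bool)
        reliable[:cutp] = True
        fit = _fit_spiral(centered, axis_b, psi, reliable, sigma_b)
        if fit is None:
            break
        new_axis, new_center, per_point = fit
        if new_axis @ axis_b < 0:
            new_axis = -new_axis
        out = winding_outcome(new_axis, _axial_noise_sd(centered, new_axis),
                              new_center, per_point)
        if out is None or out[4] >= best[4]:
            break
        best = out

    axis, center3d, total = best[0], best[1], best[2]
    axis = axis / np.linalg.norm(axis)
    return SpiralMetrics(
        centroid_size=centroid_size(pts),
        cochlear_length=curve_length(pts),
        n_turns=float(abs(total) / (2.0 * np.pi)),
        coiling_axis=basis @ axis,
        axis_center=centroid + size * (basis @ center3d),
    )
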