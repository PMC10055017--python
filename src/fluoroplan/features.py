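"""2D feature primitives and semi-automatic raster feature extraction.

The reconstruction pipeline consumes three kinds of 2D evidence per image:
the projected opening centers of the marker's cylindrical holes, the
opening *ellipses* (projections of the hole opening circles), and a circle
approximating the humeral-head silhouette.  This module provides the conic
fitting primitives shared with the simulator, plus the optional image path:
seed-point-driven hole detection and head segmentation that mirror an
operator-in-the-loop touchscreen step without a GUI.

All operations are deterministic given their inputs and an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import gaussian, sobel, threshold_multiotsu, threshold_otsu
from skimage.morphology import closing, disk
from skimage.measure import EllipseModel, find_contours, label as cc_label, regionprops

from .errors import DegenerateInput, HoleNotFound, NoCandidate


@dataclass(frozen=True)
class Ellipse:
    """center (px), semi-axes a >= b (px), tilt (radians), fit RMS (px)."""

    center: np.ndarray
    a: float
    b: float
    theta: float
    rms: float = 0.0

    def boundary_points(self, n: int = 64) -> np.ndarray:
        phi = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        ct, st = np.cos(self.theta), np.sin(self.theta)
        x = self.a * np.cos(phi)
        y = self.b * np.sin(phi)
        return np.stack([self.center[0] + ct * x - st * y, self.center[1] + st * x + ct * y], axis=-1)


@dataclass(frozen=True)
class CircleCandidate:
    """Circle hypothesis with an inlier-fraction score in [0, 1]."""

    center: np.ndarray
    radius: float
    score: float = 1.0


def fit_ellipse(points: np.ndarray) -> Ellipse:
    """Least-squares conic fit constrained to ellipses.

    Requires >= 5 non-degenerate (non-collinear) points; reports the RMS of
    geometric residuals.  Raises :class:`DegenerateInput` otherwise.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 5:
        raise DegenerateInput(f"ellipse fit needs >= 5 points, got {len(pts)}")
    centered = pts - pts.mean(axis=0)
    # collinearity: smallest singular value of the scatter ~ 0
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateInput("ellipse fit input points are collinear")
    params = None
    try:  # scikit-image >= 0.26 class-constructor API
        model = EllipseModel.from_estimate(pts)
        if model:
            params = (*model.center, *model.axis_lengths, model.theta)
    except AttributeError:
        model = EllipseModel()
        if model.estimate(pts):
            params = tuple(model.params)
    except Exception:
        params = None  # numeric edge cases inside skimage; use direct fit
    if params is None or not np.all(np.isfinite(params)):
        params = _direct_conic_ellipse(pts)
    xc, yc, a, b, theta = params
    if b > a:
        a, b = b, a
        theta += np.pi / 2
    theta = float(np.mod(theta, np.pi))
    e = Ellipse(center=np.array([xc, yc]), a=float(a), b=float(b), theta=theta)
    rms = float(
        np.sqrt(np.mean((np.linalg.norm(pts - e.center, axis=1) - _radius_at(e, pts)) ** 2))
    )
    return Ellipse(center=e.center, a=e.a, b=e.b, theta=e.theta, rms=rms)


def _direct_conic_ellipse(pts: np.ndarray):
    """Direct algebraic conic fit reduced to ellipse parameters.

    Least-squares null vector of the conic design matrix on normalized
    coordinates; used when the library estimator fails numerically.
    """
    mean = pts.mean(axis=0)
    scale = max(np.abs(pts - mean).max(), 1e-12)
    x, y = ((pts - mean) / scale).T
    D = np.column_stack([x**2, x * y, y**2, x, y, np.ones_like(x)])
    _, _, vt = np.linalg.svd(D, full_matrices=False)
    A, B, C, Dc, E, F = vt[-1]
    if B * B - 4 * A * C >= 0:
        raise DegenerateInput("conic fit is not an ellipse")
    M = np.array([[A, B / 2], [B / 2, C]])
    center_n = np.linalg.solve(2 * M, [-Dc, -E])
    Fc = F + 0.5 * (Dc * center_n[0] + E * center_n[1])
    evals, evecs = np.linalg.eigh(M)
    axes2 = -Fc / evals
    if np.any(axes2 <= 0):
        raise DegenerateInput("conic fit is not an ellipse")
    lengths = np.sqrt(axes2)
    order = np.argsort(lengths)[::-1]
    a, b = lengths[order] * scale
    v = evecs[:, order[0]]
    theta = float(np.arctan2(v[1], v[0]))
    cx, cy = center_n * scale + mean
    return cx, cy, a, b, theta


def fit_circle(points: np.ndarray) -> CircleCandidate:
    """Algebraic (Kasa) least-squares circle through >= 3 points."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        raise DegenerateInput("circle fit needs >= 3 points")
    A = np.column_stack([2 * pts[:, 0], 2 * pts[:, 1], np.ones(len(pts))])
    rhs = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    cx, cy, k = sol
    r2 = k + cx**2 + cy**2
    if not np.isfinite(r2) or r2 <= 0:
        raise DegenerateInput("circle fit degenerate (non-positive radius)")
    return CircleCandidate(center=np.array([cx, cy]), radius=float(np.sqrt(r2)), score=1.0)


# --------------------------------------------------------------------------
# raster path


@dataclass(frozen=True)
class ExtractedHole:
    """Two opening ellipses of one hole, larger (more magnified) first."""

    centers: tuple[np.ndarray, np.ndarray]
    ellipses: tuple[Ellipse, Ellipse]


def _resample_closed(contour: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline (x, y) to n equally spaced vertices."""
    closed = np.vstack([contour, contour[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    ti = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(ti, s, closed[:, 0])
    y = np.interp(ti, s, closed[:, 1])
    return np.stack([x, y], axis=-1)


def _turning_angles(poly: np.ndarray, step: int) -> np.ndarray:
    """Exterior angle at each vertex of a closed polyline, over +-step vertices."""
    prev = np.roll(poly, step, axis=0)
    nxt = np.roll(poly, -step, axis=0)
    v1 = poly - prev
    v2 = nxt - poly
    ang = np.arctan2(
        v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0], (v1 * v2).sum(axis=1)
    )
    return np.abs(ang)


def _split_lens_boundary(poly: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
    """Split a closed boundary at its two cusp points (turning-angle maxima).

    Returns the two arcs, or None when no clear cusp pair exists (near-axial
    view: the two openings project almost concentrically).
    """
    n = len(poly)
    ang = _turning_angles(poly, step=max(2, n // 50))
    i0 = int(np.argmax(ang))
    # second cusp: at least a quarter perimeter away from the first
    idx = np.arange(n)
    sep = np.minimum((idx - i0) % n, (i0 - idx) % n)
    masked = np.where(sep >= n // 4, ang, -np.inf)
    i1 = int(np.argmax(masked))
    if ang[i1] < 0.05 or ang[i0] < 0.1:  # no corner-like turning: single conic
        return None
    lo, hi = sorted((i0, i1))
    arc1 = poly[lo : hi + 1]
    arc2 = np.vstack([poly[hi:], poly[: lo + 1]])
    return arc1, arc2


def _fit_two_ellipse_lens(poly: np.ndarray) -> tuple[Ellipse, Ellipse]:
    """Decompose a hole-projection boundary into its two opening ellipses.

    The two openings of one cylindrical hole are congruent circles at
    nearly the same depth, so their projections are near-identical
    ellipses displaced along the hole axis.  Fitting the constrained model
    (shared semi-axes and tilt, two centers) to the whole outline is far
    more stable than fitting each split arc freely.  The split at the
    outline cusps seeds the initial center offset; the arc fits themselves
    only initialize the shape.
    """
    from scipy.optimize import least_squares

    e0 = fit_ellipse(poly)
    split = _split_lens_boundary(poly)
    if split is None:
        return e0, e0
    # initial offset along the elongation axis: union of two congruent
    # ellipses offset by delta has semi-major ~ b + delta/2
    delta = max(2.0 * (e0.a - e0.b), 0.5)
    ux = np.array([np.cos(e0.theta), np.sin(e0.theta)])
    x0 = np.concatenate(
        [e0.center - 0.5 * delta * ux, e0.center + 0.5 * delta * ux, [e0.b, e0.b, e0.theta]]
    )

    def ellipse_pair(x):
        a, b = max(x[4], 1e-3), max(x[5], 1e-3)
        if b > a:
            a, b = b, a
        th = float(np.mod(x[6], np.pi))
        return (
            Ellipse(center=x[0:2], a=a, b=b, theta=th),
            Ellipse(center=x[2:4], a=a, b=b, theta=th),
        )

    def resid(x):
        e1, e2 = ellipse_pair(x)
        d1 = np.abs(np.linalg.norm(poly - e1.center, axis=1) - _radius_at(e1, poly))
        d2 = np.abs(np.linalg.norm(poly - e2.center, axis=1) - _radius_at(e2, poly))
        return np.minimum(d1, d2)

    try:
        res = least_squares(resid, x0, method="trf", max_nfev=300)
        if np.all(np.isfinite(res.x)):
            e1, e2 = ellipse_pair(res.x)
            rms = float(np.sqrt(np.mean(resid(res.x) ** 2)))
            e1 = Ellipse(e1.center, e1.a, e1.b, e1.theta, rms)
            e2 = Ellipse(e2.center, e2.a, e2.b, e2.theta, rms)
            # deterministic order: lexicographic by (x, y)
            if (e2.center[0], e2.center[1]) < (e1.center[0], e1.center[1]):
                e1, e2 = e2, e1
            return e1, e2
    except Exception:
        pass
    return e0, e0


def _radius_at(e: Ellipse, pts: np.ndarray) -> np.ndarray:
    """Ellipse boundary radius in the direction of each point (from center)."""
    d = pts - e.center
    phi = np.arctan2(d[:, 1], d[:, 0]) - e.theta
    return (e.a * e.b) / np.sqrt((e.b * np.cos(phi)) ** 2 + (e.a * np.sin(phi)) ** 2)


def _ellipse_coverage(xx: np.ndarray, yy: np.ndarray, e: Ellipse) -> np.ndarray:
    """Anti-aliased inside-coverage of an ellipse over a pixel grid."""
    ct, st = np.cos(e.theta), np.sin(e.theta)
    dx = xx - e.center[0]
    dy = yy - e.center[1]
    xr = (ct * dx + st * dy) / e.a
    yr = (-st * dx + ct * dy) / e.b
    dist = (np.sqrt(xr**2 + yr**2) - 1.0) * min(e.a, e.b)
    return np.clip(0.5 - dist, 0.0, 1.0)


def _refine_lens_on_image(
    win: np.ndarray, background: np.ndarray, e1: Ellipse, e2: Ellipse
) -> tuple[Ellipse, Ellipse]:
    """Photometric polish of the two-opening model on the raw window.

    The iso-contour a threshold picks is offset from the true half-coverage
    boundary wherever the local background varies, which biases a purely
    contour-based fit.  Re-fitting the attenuation template (two congruent
    soft-edged ellipses multiplying the closed-background estimate, with a
    free attenuation factor) against the pixels themselves removes that
    bias by using the full edge profile.
    """
    from scipy.optimize import least_squares

    yy, xx = np.mgrid[0 : win.shape[0], 0 : win.shape[1]].astype(float)

    def pair(x):
        a, b = max(x[4], 1.0), max(x[5], 1.0)
        if b > a:
            a, b = b, a
        th = float(np.mod(x[6], np.pi))
        return (
            Ellipse(center=x[0:2], a=a, b=b, theta=th),
            Ellipse(center=x[2:4], a=a, b=b, theta=th),
        )

    def resid(x):
        p1, p2 = pair(x)
        att = np.clip(x[7], 0.05, 0.95)
        model = (
            background
            * (1.0 - att * _ellipse_coverage(xx, yy, p1))
            * (1.0 - att * _ellipse_coverage(xx, yy, p2))
        )
        return (model - win).ravel()

    x0 = np.concatenate([e1.center, e2.center, [e1.a, e1.b, e1.theta, 0.4]])
    try:
        res = least_squares(resid, x0, method="trf", max_nfev=120)
        if np.all(np.isfinite(res.x)):
            p1, p2 = pair(res.x)
            if (p2.center[0], p2.center[1]) < (p1.center[0], p1.center[1]):
                p1, p2 = p2, p1
            return p1, p2
    except Exception:
        pass
    return e1, e2


def _candidate_thresholds(win: np.ndarray) -> list[float]:
    """Plausible local thresholds, brightest first.

    A hole window may also contain the humeral-head border, so a single
    Otsu split can latch onto the (much larger) head region; multi-level
    Otsu thresholds provide the fallback splits between hole, head and
    background intensity classes.
    """
    cands: list[float] = []
    try:
        cands.append(float(threshold_otsu(win)))
    except Exception:
        pass
    for classes in (3, 4):
        try:
            cands.extend(float(t) for t in threshold_multiotsu(win, classes=classes))
        except Exception:
            pass
    return sorted(set(cands), reverse=True)


def _hole_component(win: np.ndarray, hint_local: np.ndarray, max_area: int):
    """Component + threshold of the hole projection near the local hint."""
    for thr in _candidate_thresholds(win):
        labels = cc_label(win < thr)
        best = None
        for p in regionprops(labels):
            cy, cx = p.centroid
            d = np.hypot(cx - hint_local[0], cy - hint_local[1])
            if 60 <= p.area <= max_area and d <= 25 and (best is None or d < best[0]):
                best = (d, p)
        if best is not None:
            return best[1], thr
    return None, None


def detect_hole_features(
    image: np.ndarray, hints: np.ndarray, window: int = 64
) -> list[ExtractedHole]:
    """Detect the lens-shaped projections of the three marker holes.

    ``hints`` are three approximate (x, y) positions (within ~20 px of the
    true projections, e.g. tapped by the operator).  Per hole, local
    intensity thresholds (Otsu and multi-level Otsu, to cope with the head
    border crossing the window) are scanned for a hole-sized dark component
    near the hint; its subpixel iso-contour is split at the two cusps of
    the outline and one ellipse is fitted per arc.  Fails per hole with
    :class:`HoleNotFound`.
    """
    img = np.asarray(image, dtype=float)
    out: list[ExtractedHole] = []
    half = window // 2
    for i, hint in enumerate(np.asarray(hints, dtype=float).reshape(-1, 2)):
        x0 = int(np.clip(round(hint[0]) - half, 0, max(img.shape[1] - window, 0)))
        y0 = int(np.clip(round(hint[1]) - half, 0, max(img.shape[0] - window, 0)))
        win = img[y0 : y0 + window, x0 : x0 + window]
        if win.size == 0 or win.max() - win.min() < 1e-6:
            raise HoleNotFound(i)
        # flatten the anatomy: a grayscale closing with a footprint larger
        # than the hole projection removes the hole but keeps the head/
        # background structure, so the ratio isolates the hole attenuation
        # even where the head silhouette edge crosses the window
        background = closing(win, footprint=disk(window // 4))
        ratio = win / np.maximum(background, 1e-6)
        target, thr = _hole_component(
            ratio, np.array([hint[0] - x0, hint[1] - y0]), max_area=window * window // 4
        )
        if target is None:
            raise HoleNotFound(i)
        contours = [c for c in find_contours(ratio, level=thr) if len(c) >= 20]
        if not contours:
            raise HoleNotFound(i)
        cy, cx = target.centroid
        contour = min(
            contours,
            key=lambda c: np.hypot(c[:, 1].mean() - cx, c[:, 0].mean() - cy),
        )
        # (row, col) -> global (x, y)
        poly = np.stack([contour[:, 1] + x0, contour[:, 0] + y0], axis=-1)
        poly = _resample_closed(poly, 240)
        e1, e2 = _fit_two_ellipse_lens(poly)
        # photometric polish in local window coordinates
        shift = np.array([x0, y0], dtype=float)
        l1 = Ellipse(e1.center - shift, e1.a, e1.b, e1.theta, e1.rms)
        l2 = Ellipse(e2.center - shift, e2.a, e2.b, e2.theta, e2.rms)
        l1, l2 = _refine_lens_on_image(win, background, l1, l2)
        e1 = Ellipse(l1.center + shift, l1.a, l1.b, l1.theta, l1.rms)
        e2 = Ellipse(l2.center + shift, l2.a, l2.b, l2.theta, l2.rms)
        out.append(ExtractedHole(centers=(e1.center, e2.center), ellipses=(e1, e2)))
    return out


def _refine_circle_on_image(img: np.ndarray, cand: CircleCandidate) -> CircleCandidate:
    """Subpixel polish of a circle candidate against the edge profile.

    RANSAC + algebraic refit work on integer edge pixels (~0.3 px floor);
    fitting a soft-edged disk step (free inside/outside levels) to the
    pixels of an annulus around the candidate recovers the boundary to
    subpixel precision.
    """
    from scipy.optimize import least_squares

    r0 = cand.radius
    x0i = int(np.clip(cand.center[0] - r0 - 8, 0, img.shape[1]))
    x1i = int(np.clip(cand.center[0] + r0 + 8, 0, img.shape[1]))
    y0i = int(np.clip(cand.center[1] - r0 - 8, 0, img.shape[0]))
    y1i = int(np.clip(cand.center[1] + r0 + 8, 0, img.shape[0]))
    win = img[y0i:y1i, x0i:x1i]
    if win.size < 64:
        return cand
    yy, xx = np.mgrid[y0i:y1i, x0i:x1i].astype(float)
    band0 = np.abs(np.hypot(xx - cand.center[0], yy - cand.center[1]) - r0) <= 6.0
    if band0.sum() < 32:
        return cand
    px, py, pv = xx[band0], yy[band0], win[band0]
    inner0 = float(np.median(img[int(cand.center[1]), int(cand.center[0])]))
    outer0 = float(np.percentile(pv, 90))

    def resid(x):
        cx, cy, r, inner, outer = x
        d = np.hypot(px - cx, py - cy)
        cov = np.clip(0.5 - (d - r), 0.0, 1.0)
        return outer + (inner - outer) * cov - pv

    try:
        res = least_squares(
            resid, [cand.center[0], cand.center[1], r0, inner0, outer0], method="lm", max_nfev=100
        )
        cx, cy, r = res.x[:3]
        if np.isfinite(r) and abs(r - r0) < 5.0 and np.hypot(cx - cand.center[0], cy - cand.center[1]) < 5.0:
            return CircleCandidate(center=np.array([cx, cy]), radius=float(r), score=cand.score)
    except Exception:
        pass
    return cand


def _circumcircle(p: np.ndarray) -> tuple[np.ndarray, float] | None:
    a, b, c = p
    A = 2 * np.array([b - a, c - a])
    rhs = np.array([b @ b - a @ a, c @ c - a @ a])
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    if abs(det) < 1e-9:
        return None
    center = np.linalg.solve(A, rhs)
    return center, float(np.linalg.norm(center - a))


def segment_head(
    image: np.ndarray,
    seed_point,
    k: int = 3,
    r_max: float = 150.0,
    r_min: float = 25.0,
    seed: int = 0,
    n_iter: int = 500,
    inlier_band: float = 2.0,
) -> list[CircleCandidate]:
    """Semi-automatic head segmentation: ranked circle candidates.

    Starting from an operator seed point inside the head region, an edge
    map (gradient magnitude above its 90th percentile within a 4*r_max
    window) feeds a seeded RANSAC circle search (3-point minimal sets,
    +-2 px inlier band, 500 iterations), followed by non-maximum
    suppression of near-duplicate circles (center within 5 px and radius
    within 5 px).  The top-k candidates are returned score-descending so
    the operator (or the CLI in headless mode) can pick one.
    """
    img = np.asarray(image, dtype=float)
    sx, sy = float(seed_point[0]), float(seed_point[1])
    half = int(2 * r_max)
    x0 = int(np.clip(round(sx) - half, 0, img.shape[1]))
    y0 = int(np.clip(round(sy) - half, 0, img.shape[0]))
    win = img[y0 : y0 + 2 * half, x0 : x0 + 2 * half]
    if win.size == 0:
        raise NoCandidate("seed point outside the image")
    # denoise before differentiating; the subpixel polish at the end works
    # on the raw pixels, so the blur does not limit the final accuracy
    grad = sobel(gaussian(win, sigma=1.5))
    floor = 0.05 * (img.max() - img.min())
    if grad.max() <= max(floor, 1e-12):
        raise NoCandidate("no edges near the seed point")
    thr = max(np.percentile(grad[grad > 0], 90.0) if np.any(grad > 0) else np.inf, floor)
    ys, xs = np.nonzero(grad >= thr)
    pts = np.stack([xs + x0, ys + y0], axis=-1).astype(float)
    if len(pts) < 3:
        raise NoCandidate("too few edge points")
    rng = np.random.default_rng(seed)
    if len(pts) > 4000:
        pts = pts[rng.choice(len(pts), 4000, replace=False)]
    hypotheses: list[CircleCandidate] = []
    n = len(pts)
    for _ in range(n_iter):
        sample = pts[rng.choice(n, 3, replace=False)]
        res = _circumcircle(sample)
        if res is None:
            continue
        center, r = res
        if not (r_min <= r <= r_max):
            continue
        if np.hypot(center[0] - sx, center[1] - sy) > r:  # seed must be inside
            continue
        d = np.abs(np.linalg.norm(pts - center, axis=1) - r)
        inliers = d <= inlier_band
        frac = float(inliers.mean())
        if frac <= 0:
            continue
        refined = fit_circle(pts[inliers]) if inliers.sum() >= 10 else None
        if refined is not None and r_min <= refined.radius <= r_max:
            d = np.abs(np.linalg.norm(pts - refined.center, axis=1) - refined.radius)
            frac = float((d <= inlier_band).mean())
            center, r = refined.center, refined.radius
        hypotheses.append(CircleCandidate(center=center, radius=r, score=frac))
    hypotheses.sort(key=lambda c: -c.score)
    kept: list[CircleCandidate] = []
    for h in hypotheses:
        if any(
            np.linalg.norm(h.center - kk.center) < 5.0 and abs(h.radius - kk.radius) < 5.0
            for kk in kept
        ):
            continue
        kept.append(h)
        if len(kept) >= k:
            break
    if not kept or kept[0].score < 0.2:
        raise NoCandidate("best circle candidate below score floor 0.2")
    return [_refine_circle_on_image(img, c) for c in kept]
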