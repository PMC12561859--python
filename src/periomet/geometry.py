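"""Mask-to-landmark geometry.

Converts binary iris and eyebrow masks into seven calibrated periocular
measurements: MRD1, MRD2 (margin reflex distances) and the vertical eyebrow
heights above the pupil center at five landmark columns — medial eyebrow end
(MBE), medial limbus (ML), pupil center (PC), lateral limbus (LL) and lateral
eyebrow end (LBE).

The pupil center is approximated by the center of the minimum enclosing
circle of the visible iris: under eyelid occlusion the iris mask is a
chord-bounded region, but as long as the horizontal diameter remains visible
the minimum enclosing circle recovers the full corneal outline.  The circle
diameter is calibrated against a standard horizontal corneal diameter of
11 mm, giving every image its own mm/px scale.

Conventions: 0-based pixel coordinates, origin top-left, x along columns,
y along rows growing downward; heights are ``pupil_center_y - row`` so
"above" is positive.  Points are pixel centers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import EmptyMaskError, GeometryError, InputError

#: Standard adult horizontal corneal (visible iris) diameter used as the
#: per-image scale bar.
CORNEAL_DIAMETER_MM = 11.0

#: Canonical landmark order used throughout reports.
LANDMARK_NAMES = ("MRD1", "MRD2", "MBE", "ML", "PC", "LL", "LBE")
BROW_LANDMARKS = ("MBE", "ML", "PC", "LL", "LBE")

_EPS = 1e-10


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class BinaryMask:
    """Single-class pixel mask tied to an image frame.

    Most functions in this module accept either a plain boolean array or a
    ``BinaryMask``; the wrapper exists to carry the class label through IO.
    """

    grid: np.ndarray
    class_label: str = "iris"  # 'iris' | 'eyebrow'

    def __post_init__(self):
        self.grid = as_mask_array(self.grid)

    @property
    def frame(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass(frozen=True)
class Circle:
    """A circle in pixel coordinates; ``center`` is (x, y), sub-pixel."""

    center: tuple[float, float]
    radius: float

    def contains(self, point, tol: float = 1e-7) -> bool:
        dx = point[0] - self.center[0]
        dy = point[1] - self.center[1]
        return math.hypot(dx, dy) <= self.radius + tol


@dataclass(frozen=True)
class CalibratedScale:
    """Millimetres per pixel derived from the corneal-diameter scale bar."""

    mm_per_px: float
    reference_diameter_mm: float = CORNEAL_DIAMETER_MM


@dataclass
class LandmarkSet:
    """The seven calibrated measurements for one periocular image.

    ``brow_heights_mm`` maps the five brow landmark names to vertical
    distances (mm) from the pupil center to the top of the eyebrow at that
    column; missing landmarks are NaN with the matching ``occlusion_flags``
    entry set.  ``occlusion_flags['MRD1']`` means the upper lid covers the
    corneal apex, so the measured MRD1 is the lid margin rather than the
    circle top (the clinical definition; flagged because a mask-based
    measure cannot go negative).
    """

    mrd1_mm: float
    mrd2_mm: float
    brow_heights_mm: dict[str, float]
    landmark_columns: dict[str, int]
    pupil_center: tuple[float, float]
    mm_per_px: float
    occlusion_flags: dict[str, bool] = field(default_factory=dict)

    def values(self) -> dict[str, float]:
        """All seven measurements keyed by canonical landmark name."""
        out = {"MRD1": self.mrd1_mm, "MRD2": self.mrd2_mm}
        out.update({k: self.brow_heights_mm[k] for k in BROW_LANDMARKS})
        return out

    def to_record(self) -> dict:
        """Flat dict suitable for a CSV row."""
        rec = {
            "mrd1_mm": self.mrd1_mm,
            "mrd2_mm": self.mrd2_mm,
            "mbe_mm": self.brow_heights_mm["MBE"],
            "ml_mm": self.brow_heights_mm["ML"],
            "pc_mm": self.brow_heights_mm["PC"],
            "ll_mm": self.brow_heights_mm["LL"],
            "lbe_mm": self.brow_heights_mm["LBE"],
            "mm_per_px": self.mm_per_px,
            "occluded_top": bool(self.occlusion_flags.get("MRD1", False)),
            "occluded_bottom": bool(self.occlusion_flags.get("MRD2", False)),
        }
        return rec


def as_mask_array(mask) -> np.ndarray:
    """Coerce input to a 2-D boolean array; values must be binary."""
    grid = getattr(mask, "grid", mask)
    arr = np.asarray(grid)
    if arr.ndim != 2:
        raise InputError(f"mask must be 2-D, got shape {arr.shape}")
    if arr.dtype != bool:
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1, 255))):
            raise InputError("mask values must be binary (0/1 or 0/255)")
        arr = arr != 0
    return arr


# ---------------------------------------------------------------------------
# Connected components and boundary extraction
# ---------------------------------------------------------------------------

_STRUCT8 = np.ones((3, 3), dtype=bool)


def largest_component(mask) -> np.ndarray:
    """Keep only the largest 8-connected foreground component.

    Ties in size are broken by the component whose first foreground pixel in
    row-major scan order (smallest row, then column) comes first.
    """
    arr = as_mask_array(mask)
    if not arr.any():
        raise EmptyMaskError("cannot extract components from an empty mask")
    labels, n = ndimage.label(arr, structure=_STRUCT8)
    if n == 1:
        return arr
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best = sizes.max()
    candidates = np.flatnonzero(sizes == best)
    if len(candidates) == 1:
        winner = candidates[0]
    else:
        flat = labels.ravel()
        winner = min(candidates, key=lambda c: np.flatnonzero(flat == c)[0])
    return labels == winner


def boundary_points(mask) -> np.ndarray:
    """Foreground pixels with at least one background 4-neighbor.

    The frame border counts as background.  Returns an (n, 2) float array of
    (x, y) pixel centers.  The minimum enclosing circle of these points
    equals that of the full foreground: every convex-hull vertex of the
    foreground has an exposed axis neighbor and is therefore included.
    """
    arr = as_mask_array(mask)
    if not arr.any():
        raise EmptyMaskError("cannot extract boundary of an empty mask")
    padded = np.pad(arr, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    border = arr & ~interior
    rows, cols = np.nonzero(border)
    return np.column_stack((cols, rows)).astype(float)


# ---------------------------------------------------------------------------
# Minimum enclosing circle (randomized incremental, Welzl-type)
# ---------------------------------------------------------------------------

def _circle_two(p, q) -> Circle:
    cx = (p[0] + q[0]) / 2.0
    cy = (p[1] + q[1]) / 2.0
    r = math.hypot(p[0] - q[0], p[1] - q[1]) / 2.0
    return Circle((cx, cy), r)


def _circumcircle(a, b, c) -> Circle | None:
    """Circle through three points; None when (near-)collinear."""
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    scale = max(abs(ax - cx), abs(ay - cy), abs(bx - cx), abs(by - cy), 1.0)
    if abs(d) < 1e-12 * scale * scale:
        return None
    a2 = ax * ax + ay * ay
    b2 = bx * bx + by * by
    c2 = cx * cx + cy * cy
    ux = (a2 * (by - cy) + b2 * (cy - ay) + c2 * (ay - by)) / d
    uy = (a2 * (cx - bx) + b2 * (ax - cx) + c2 * (bx - ax)) / d
    r = math.hypot(ax - ux, ay - uy)
    return Circle((ux, uy), r)


def _outside(c: Circle, p, tol: float) -> bool:
    return math.hypot(p[0] - c.center[0], p[1] - c.center[1]) > c.radius + tol


def min_enclosing_circle(points) -> Circle:
    """Smallest circle containing all points.

    Randomized incremental construction with expected linear time; the
    internal shuffle uses a fixed stream so the (unique) result does not
    depend on input order.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise InputError("min_enclosing_circle requires at least one point")
    if pts.shape[1] != 2:
        raise InputError("points must be (n, 2)")
    rng = np.random.default_rng(0x6E5C)
    pts = pts[rng.permutation(len(pts))]
    span = max(float(np.ptp(pts[:, 0])), float(np.ptp(pts[:, 1])), 1.0)
    tol = _EPS * span

    circ = Circle((float(pts[0, 0]), float(pts[0, 1])), 0.0)
    for i in range(1, len(pts)):
        if _outside(circ, pts[i], tol):
            circ = _mec_one_boundary(pts[:i], pts[i], tol)
    return circ


def _mec_one_boundary(pts, q, tol) -> Circle:
    circ = Circle((float(q[0]), float(q[1])), 0.0)
    for j in range(len(pts)):
        if _outside(circ, pts[j], tol):
            circ = _mec_two_boundary(pts[:j], pts[j], q, tol)
    return circ


def _mec_two_boundary(pts, q1, q2, tol) -> Circle:
    circ = _circle_two(q1, q2)
    for k in range(len(pts)):
        if _outside(circ, pts[k], tol):
            cc = _circumcircle(pts[k], q1, q2)
            if cc is None:
                # collinear support: widest two of the three determine it
                trio = [tuple(pts[k]), tuple(q1), tuple(q2)]
                best = circ
                for a in range(3):
                    for b in range(a + 1, 3):
                        cand = _circle_two(trio[a], trio[b])
                        if cand.radius > best.radius:
                            best = cand
                circ = best
            else:
                circ = cc
    return circ


def min_enclosing_circle_bruteforce(points) -> Circle:
    """Exhaustive O(n^4) minimum enclosing circle; independent test oracle.

    Checks every pair (diameter circle) and triple (circumcircle), keeping
    the smallest circle that contains all points.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise InputError("requires at least one point")
    n = len(pts)
    if n > 50:
        raise InputError("brute-force solver is limited to n <= 50")
    if n == 1:
        return Circle((float(pts[0, 0]), float(pts[0, 1])), 0.0)
    span = max(float(np.ptp(pts[:, 0])), float(np.ptp(pts[:, 1])), 1.0)
    tol = 1e-9 * span

    def contains_all(c: Circle) -> bool:
        d = np.hypot(pts[:, 0] - c.center[0], pts[:, 1] - c.center[1])
        return bool(np.all(d <= c.radius + tol))

    best: Circle | None = None
    for i in range(n):
        for j in range(i + 1, n):
            c = _circle_two(pts[i], pts[j])
            if contains_all(c) and (best is None or c.radius < best.radius):
                best = c
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                c = _circumcircle(pts[i], pts[j], pts[k])
                if c is not None and contains_all(c) and (
                    best is None or c.radius < best.radius
                ):
                    best = c
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Sub-pixel circle refinement
# ---------------------------------------------------------------------------

def _kasa_circle(points: np.ndarray) -> Circle | None:
    """Algebraic least-squares circle fit (Kasa); None when ill-conditioned."""
    x, y = points[:, 0], points[:, 1]
    a = np.column_stack([2 * x, 2 * y, np.ones(len(x))])
    sol, _, rank, _ = np.linalg.lstsq(a, x * x + y * y, rcond=None)
    if rank < 3:
        return None
    cx, cy = float(sol[0]), float(sol[1])
    r2 = float(sol[2]) + cx * cx + cy * cy
    if r2 <= 0:
        return None
    return Circle((cx, cy), math.sqrt(r2))


def _horizontally_exposed(arr: np.ndarray) -> np.ndarray:
    """Foreground pixels with a background neighbor to the left or right."""
    padded = np.pad(arr, 1, constant_values=False)
    return arr & ~(padded[1:-1, :-2] & padded[1:-1, 2:])


def refine_iris_circle(mask, circle: Circle,
                       bands: tuple[float, ...] = (1.5, 1.0, 0.75),
                       radius_offset: float = 0.5) -> Circle:
    """Sub-pixel refinement of the iris circle from its limbus arcs.

    The discrete minimum enclosing circle is supported by a handful of
    extreme pixels, and when both the corneal apex and base are hidden by
    the lids its vertical position is conditioned on half-pixel chord
    quantization, which can shift it by several pixels in heavy ptosis.
    The visible limbus arcs carry far more information, so the estimate is
    polished by an iteratively trimmed least-squares circle fit restricted
    to horizontally exposed boundary pixels (the left/right limbus, not the
    lid margins) within a shrinking distance band of the current circle.

    ``radius_offset`` compensates the half-pixel inward bias of boundary
    pixel centers relative to the true region edge.  Falls back to the
    input circle whenever the fit is ill-conditioned or drifts more than
    15% in radius (degenerate or heavily fragmented masks).
    """
    arr = as_mask_array(mask)
    pts = boundary_points(arr)
    exposed = _horizontally_exposed(arr)
    keep = exposed[pts[:, 1].astype(int), pts[:, 0].astype(int)]
    arc = pts[keep] if keep.sum() >= 6 else pts

    fitted = circle
    for band in bands:
        d = np.hypot(arc[:, 0] - fitted.center[0], arc[:, 1] - fitted.center[1])
        sel = np.abs(d - fitted.radius) <= band
        if sel.sum() < 6:
            break
        cand = _kasa_circle(arc[sel])
        if cand is None or not (
            0.85 * circle.radius <= cand.radius <= 1.15 * circle.radius
        ):
            break
        fitted = cand
    if fitted is not circle:
        fitted = Circle(fitted.center, fitted.radius + radius_offset)
    return _raster_run_polish(arr, fitted)


def _raster_run_polish(arr: np.ndarray, c0: Circle,
                       min_run: int = 8) -> Circle:
    """Exact-rasterization maximum-likelihood polish of the iris circle.

    For the true circle, every eyelid-unclipped row of the mask reproduces
    the rasterized chord exactly: leftmost column ceil(cx - h(y)), rightmost
    floor(cx + h(y)).  Clipped rows (above/below the lid-limbus corners)
    violate this, but they are contiguous at the top and bottom of the
    visible band.  The fit therefore searches a local grid around ``c0``
    for circles maximizing the longest contiguous run of exactly matching
    rows; the centroid of the top-scoring parameter set (its largest
    connected cluster) is the estimate.  This exploits the full quantization
    information in the mask instead of treating edges as +/-0.5 px noise and
    roughly halves the center error of a least-squares arc fit.

    Masks that do not behave like 1-px-quantized circle rasterizations
    (e.g. block-upscaled network predictions) produce runs shorter than
    ``min_run`` and fall back to ``c0`` untouched.
    """
    rows = np.flatnonzero(arr.any(axis=1))
    if len(rows) < min_run:
        return c0
    xl = np.empty(len(rows))
    xr = np.empty(len(rows))
    for k, y in enumerate(rows):
        rr = np.flatnonzero(arr[y])
        xl[k], xr[k] = rr[0], rr[-1]
    ys = rows.astype(float)
    cx1, cy1, r1 = c0.center[0], c0.center[1], c0.radius

    dcxs = np.arange(-0.4, 0.401, 0.04)
    dys = np.arange(-1.8, 1.801, 0.03)
    drs = np.arange(-0.7, 0.701, 0.03)
    cy_grid = (cy1 + dys)[:, None, None]
    r_grid = (r1 + drs)[None, :, None]
    h2 = r_grid ** 2 - (ys[None, None, :] - cy_grid) ** 2
    valid = h2 > 4.0
    h = np.sqrt(np.where(valid, h2, 1.0))
    left = cx1 - h
    right = cx1 + h

    best_len = -1
    cands: list[np.ndarray] = []
    for dcx in dcxs:
        match = valid & (np.ceil(left + dcx) == xl) & (np.floor(right + dcx) == xr)
        acc = np.zeros(match.shape[:2], np.int32)
        run = np.zeros(match.shape[:2], np.int32)
        for j in range(match.shape[2]):
            acc = (acc + 1) * match[:, :, j]
            np.maximum(run, acc, out=run)
        top = int(run.max())
        if top > best_len:
            best_len = top
            cands = []
        if top == best_len:
            ai, bi = np.nonzero(run == top)
            cands.append(np.column_stack(
                [cy1 + dys[ai], r1 + drs[bi], np.full(len(ai), cx1 + dcx)]))
    if best_len < min_run:
        return c0
    cand = np.vstack(cands)
    cand = cand[np.argsort(cand[:, 0])]
    gaps = np.flatnonzero(np.diff(cand[:, 0]) > 0.15)
    cluster = max(np.split(cand, gaps + 1), key=len)
    return Circle((float(cluster[:, 2].mean()), float(cluster[:, 0].mean())),
                  float(cluster[:, 1].mean()))


# ---------------------------------------------------------------------------
# Calibration and landmark measurement
# ---------------------------------------------------------------------------

def calibrate_scale(circle: Circle) -> CalibratedScale:
    """mm/px from the corneal scale bar: 11 mm / (2 * radius_px)."""
    if circle.radius <= 0:
        raise GeometryError("calibration requires a circle with radius > 0")
    return CalibratedScale(mm_per_px=CORNEAL_DIAMETER_MM / (2.0 * circle.radius))


def landmark_columns(circle: Circle, brow, medial: str = "left") -> dict[str, int]:
    """x positions of the five brow landmark columns.

    PC is the pupil-center column; ML/LL sit one iris radius toward the
    medial/lateral side; MBE/LBE are the extreme eyebrow columns on the
    medial/lateral side.  ``medial`` names the image side of the nose
    ('left' under left-periocular framing).
    """
    if medial not in ("left", "right"):
        raise InputError(f"medial side must be 'left' or 'right', got {medial!r}")
    arr = as_mask_array(brow)
    if not arr.any():
        raise EmptyMaskError("brow mask is empty")
    cols = np.flatnonzero(arr.any(axis=0))
    cx, r = circle.center[0], circle.radius
    pc = round(cx)
    if medial == "left":
        ml, ll = round(cx - r), round(cx + r)
        mbe, lbe = int(cols[0]), int(cols[-1])
    else:
        ml, ll = round(cx + r), round(cx - r)
        mbe, lbe = int(cols[-1]), int(cols[0])
    return {"MBE": mbe, "ML": ml, "PC": pc, "LL": ll, "LBE": lbe}


def brow_height_at(brow, column: int, pupil_center, scale: CalibratedScale,
                   band: int = 2) -> float:
    """Vertical distance (mm) from pupil center to the brow top at a column.

    The brow top is the smallest foreground row among columns within
    ``column +/- band``.  Returns NaN when no brow pixel falls in the band
    (missing landmark; callers record it in occlusion flags).
    """
    arr = as_mask_array(brow)
    if not arr.any():
        raise EmptyMaskError("brow mask is empty")
    lo = max(0, int(column) - band)
    hi = min(arr.shape[1], int(column) + band + 1)
    if lo >= hi:
        return float("nan")
    strip = arr[:, lo:hi]
    rows = np.flatnonzero(strip.any(axis=1))
    if rows.size == 0:
        return float("nan")
    top = int(rows[0])
    return (pupil_center[1] - top) * scale.mm_per_px


def measure_mrd(iris, circle: Circle, scale: CalibratedScale):
    """MRD1/MRD2 (mm) from the visible iris in a 3-px band at the PC column.

    MRD1 is the distance from the pupil center up to the highest visible
    iris pixel; MRD2 down to the lowest.  Negative raw values clip to 0.
    ``occluded_top``/``occluded_bottom`` flag lids covering the circle apex
    or base by more than 1 px.
    """
    arr = as_mask_array(iris)
    if not arr.any():
        raise EmptyMaskError("iris mask is empty")
    cx, cy = circle.center
    lo = max(0, round(cx) - 1)
    hi = min(arr.shape[1], round(cx) + 2)
    strip = arr[:, lo:hi]
    rows = np.flatnonzero(strip.any(axis=1))
    if rows.size == 0:
        raise GeometryError("no iris pixels at the pupil-center column")
    top, bottom = int(rows[0]), int(rows[-1])
    mrd1 = max(0.0, (cy - top)) * scale.mm_per_px
    mrd2 = max(0.0, (bottom - cy)) * scale.mm_per_px
    occluded_top = (cy - top) < circle.radius - 1.0
    occluded_bottom = (bottom - cy) < circle.radius - 1.0
    return mrd1, mrd2, occluded_top, occluded_bottom


def measure_all(iris, brow, medial: str = "left", band: int = 2) -> LandmarkSet:
    """Full measurement pipeline from two binary masks to a LandmarkSet.

    Stages: largest component -> boundary points -> minimum enclosing
    circle -> scale calibration -> landmark columns -> brow heights -> MRD.
    Errors from a stage are re-raised with the stage named.
    """
    stage = "largest_component(iris)"
    try:
        iris_cc = largest_component(iris)
        stage = "largest_component(brow)"
        brow_cc = largest_component(brow)
        stage = "boundary_points"
        pts = boundary_points(iris_cc)
        stage = "min_enclosing_circle"
        circle = min_enclosing_circle(pts)
        stage = "refine_iris_circle"
        circle = refine_iris_circle(iris_cc, circle)
        stage = "calibrate_scale"
        scale = calibrate_scale(circle)
        stage = "landmark_columns"
        columns = landmark_columns(circle, brow_cc, medial=medial)
        stage = "brow_height_at"
        heights = {
            name: brow_height_at(brow_cc, col, circle.center, scale, band=band)
            for name, col in columns.items()
        }
        stage = "measure_mrd"
        mrd1, mrd2, occ_top, occ_bot = measure_mrd(iris_cc, circle, scale)
    except (EmptyMaskError, GeometryError, InputError) as exc:
        raise type(exc)(f"[{stage}] {exc}") from exc

    flags = {"MRD1": occ_top, "MRD2": occ_bot}
    flags.update({name: bool(math.isnan(heights[name])) for name in BROW_LANDMARKS})
    return LandmarkSet(
        mrd1_mm=mrd1,
        mrd2_mm=mrd2,
        brow_heights_mm=heights,
        landmark_columns=columns,
        pupil_center=circle.center,
        mm_per_px=scale.mm_per_px,
        occlusion_flags=flags,
    )
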