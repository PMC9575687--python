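"""Equal-area partitioning of a CM subspace into ordered conformational bins.

The Cartesian product of cosines traverses its parabola at a nonuniform
rate, so each CM eigenvector is first passed through an inverse-cosine
(arccos) map, which linearizes the rate of change.  The resulting
Lambda-shaped point cloud is outlined by an alpha-shape polygon, an anchor
point is placed on the cloud's symmetry axis beyond its vertex, and rays
swept from the anchor cut the polygon into contiguous sub-polygons of
equal area — one bin per conformational state.  Occupancies are the
point counts per bin; averaging the raw images of each bin yields a 2D
movie of the motion, optionally SVD-filtered.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import unary_union

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# arccos transform
# --------------------------------------------------------------------------

def arccos_transform(psi: np.ndarray, quantile: float = 0.0) -> np.ndarray:
    """Map an eigenvector column to [0, pi] via arccos of its min-max
    rescaling to [-1, 1] (a monotone decreasing map).

    ``quantile`` > 0 rescales by the (q, 1-q) quantile range instead of the
    min-max, for robustness against stray points.
    """
    psi = np.asarray(psi, dtype=float)
    lo, hi = np.quantile(psi, [quantile, 1.0 - quantile])
    if hi - lo < 1e-30:
        raise ValueError("constant eigenvector column cannot be transformed")
    rescaled = np.clip((psi - lo) / (hi - lo) * 2.0 - 1.0, -1.0, 1.0)
    return np.arccos(rescaled)


@dataclass
class TransformedSubspace:
    phi: np.ndarray              # (N, 2) arccos coordinates
    subspace: tuple[int, int]
    cm_id: int

    def __post_init__(self):
        if ((self.phi < -1e-9) | (self.phi > math.pi + 1e-9)).any():
            raise ValueError("Phi coordinates must lie in [0, pi]")


def transform_subspace(emb, subspace: tuple[int, int], cm_id: int = 1,
                       quantile: float = 0.0) -> TransformedSubspace:
    i, j = subspace
    phi = np.stack([arccos_transform(emb.column(i), quantile),
                    arccos_transform(emb.column(j), quantile)], axis=1)
    return TransformedSubspace(phi=phi, subspace=subspace, cm_id=cm_id)


# --------------------------------------------------------------------------
# alpha shape
# --------------------------------------------------------------------------

def _triangle_polygons(points: np.ndarray, tri: Delaunay):
    p = points[tri.simplices]
    a = np.linalg.norm(p[:, 0] - p[:, 1], axis=1)
    b = np.linalg.norm(p[:, 1] - p[:, 2], axis=1)
    c = np.linalg.norm(p[:, 2] - p[:, 0], axis=1)
    s = 0.5 * (a + b + c)
    area = np.sqrt(np.clip(s * (s - a) * (s - b) * (s - c), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        circumradius = np.where(area > 1e-14, a * b * c / (4.0 * area), np.inf)
    return p, circumradius


def _union_at(p, circumradius, r):
    keep = circumradius <= r
    if not keep.any():
        return None
    polys = shapely.polygons(p[keep])
    return unary_union(polys)


def alpha_polygon(points: np.ndarray, min_coverage: float = 0.99) -> Polygon:
    """Alpha-shape outline of a 2D point cloud as a single simple polygon.

    Triangles of the Delaunay triangulation with circumradius below 1/alpha
    are kept; the largest alpha (smallest radius) whose union is one
    connected polygon without holes covering >= ``min_coverage`` of the
    points is found by binary search over the sorted circumradii.  Falls
    back to the convex hull if no alpha qualifies.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 10:
        raise ValueError("need at least 10 points")
    try:
        tri = Delaunay(points)
    except QhullError:
        raise ValueError("degenerate point cloud (collinear?)")
    p, circ = _triangle_polygons(points, tri)
    radii = np.unique(circ[np.isfinite(circ)])

    def ok(r):
        u = _union_at(p, circ, r)
        if u is None or not isinstance(u, Polygon) or u.interiors:
            return False
        shapely.prepare(u)
        covered = shapely.dwithin(u, shapely.points(points), 1e-9)
        return covered.mean() >= min_coverage

    # Sparse, near-1D clouds (few points along a thin curve) only connect at
    # radii where the triangle union already fills concavities; a union of
    # point discs hugs the curve instead.  Prefer whichever qualifying
    # polygon has the smaller area (tighter outline).
    candidates = []
    lo, hi = 0, len(radii) - 1
    if ok(radii[hi]):
        while lo < hi:      # smallest radius index that qualifies
            mid = (lo + hi) // 2
            if ok(radii[mid]):
                hi = mid
            else:
                lo = mid + 1
        candidates.append(_union_at(p, circ, radii[lo]))

    # Sparse, near-1D clouds only connect at radii where the triangle union
    # has already filled the concavities.  A union of point discs hugs the
    # curve instead; it is tried whenever it outlines the cloud more tightly.
    from scipy.spatial import cKDTree
    nn = cKDTree(points).query(points, k=2)[0][:, 1]
    if not candidates or np.median(nn) > 0.02 * math.hypot(
            *(points.max(axis=0) - points.min(axis=0))):
        def disc_union(r):
            return unary_union(shapely.buffer(shapely.points(points), r, quad_segs=6))

        for r in np.geomspace(max(0.3 * float(np.median(nn)), 1e-9),
                              max(nn.max() * 3.0, 1e-8), 32):
            u = disc_union(r)
            if isinstance(u, Polygon) and not u.interiors:
                candidates.append(u)
                break

    if not candidates:
        logger.warning("alpha shape fragmented at all alphas; using convex hull")
        hull = shapely.convex_hull(shapely.multipoints(points))
        return hull if isinstance(hull, Polygon) else hull.buffer(1e-9)
    return min(candidates, key=lambda g: g.area)


# --------------------------------------------------------------------------
# anchor placement
# --------------------------------------------------------------------------

def _fit_absolute_value(points: np.ndarray):
    """Least-squares fit of y = a |x - h| + k over a deterministic h grid."""
    x, y = points[:, 0], points[:, 1]
    best = None
    for h in np.linspace(np.quantile(x, 0.2), np.quantile(x, 0.8), 121):
        u = np.abs(x - h)
        X = np.stack([u, np.ones_like(u)], axis=1)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(((y - X @ coef) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, h, coef[0], coef[1])
    _, h, a, k = best
    return a, h, k


def smooth_polygon(polygon: Polygon, closing_frac: float = 0.04,
                   simplify_frac: float = 0.01) -> Polygon:
    """Morphological closing plus simplification of a ragged alpha shape.

    Noisy point clouds give alpha polygons with many small notches that
    defeat ray visibility without changing the area partition materially;
    closing (outward then inward buffer) fills notches and simplification
    removes sliver vertices.  Fractions are of the bounding-box diagonal.
    """
    minx, miny, maxx, maxy = polygon.bounds
    diag = math.hypot(maxx - minx, maxy - miny)
    closed = polygon.buffer(closing_frac * diag).buffer(-closing_frac * diag)
    if not isinstance(closed, Polygon) or closed.is_empty:
        closed = polygon
    out = closed.simplify(simplify_frac * diag)
    if not isinstance(out, Polygon) or out.is_empty:
        out = closed
    if out.interiors:
        out = Polygon(out.exterior)
    return out


def _ray_crossings_ok(polygon: Polygon, anchor: np.ndarray,
                      clip_tol: float = 0.15, vertex_tol: float = 0.88) -> bool:
    """True if (almost) every polygon vertex is reachable by a ray from the
    anchor crossing the boundary exactly twice.

    The inside portion of each ray must be a single segment; secondary
    clips totalling under ``clip_tol`` of the main segment are tolerated
    (ragged boundaries graze rays), as is a ``1 - vertex_tol`` fraction of
    failing vertices."""
    minx, miny, maxx, maxy = polygon.bounds
    span = math.hypot(maxx - minx, maxy - miny)
    coords = np.asarray(polygon.exterior.coords)[:-1]
    ok = 0
    for vx, vy in coords:
        d = np.array([vx, vy]) - anchor
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            continue
        far = anchor + d / norm * (norm + 3 * span)
        inside = LineString([anchor, far]).intersection(polygon)
        if inside.is_empty:
            continue
        if inside.geom_type in ("LineString", "Point"):
            ok += 1
            continue
        if inside.geom_type == "MultiLineString":
            lengths = sorted((g.length for g in inside.geoms), reverse=True)
            if sum(lengths[1:]) <= clip_tol * lengths[0]:
                ok += 1
    return ok >= vertex_tol * len(coords)


def place_anchor(polygon: Polygon, points: np.ndarray,
                 offset_frac: float = 0.1) -> np.ndarray:
    """Place the ray anchor on the cloud's symmetry axis, beyond its vertex.

    A preliminary absolute-value fit y = a|x - h| + k locates the symmetry
    axis (x = h) and vertex (h, k).  The cloud is a thick V- or
    Lambda-shaped band, star-shaped only from its concave side (the central
    alcove between the arms), so the anchor sits on the axis offset from
    the vertex into the alcove by ``offset_frac`` of the bounding-box
    height, doubled (up to 3 times) until the polygon's vertices are
    visible through a double boundary crossing.
    """
    points = np.asarray(points, dtype=float)
    a, h, k = _fit_absolute_value(points)
    height = points[:, 1].max() - points[:, 1].min()
    # the anchor needs the polygon star-shaped around it: for a thick band
    # the alcove between the arms is open space (anchor inside it); for a
    # sparse cloud the alpha polygon fills the notch, and the star point is
    # on the apex side instead.  A probe at the vertex distinguishes them.
    alcove = 1.0 if a > 0 else -1.0   # the side the arms open to
    probe = Point(h, k + alcove * 0.5 * height)
    sign = -alcove if polygon.contains(probe) else alcove
    off = offset_frac * height
    for _ in range(5):
        anchor = np.array([h, k + sign * off])
        # the polygon must not wrap (almost) all the way around the anchor,
        # or the sweep ordering degenerates
        _, _, span = _angular_window(polygon, anchor)
        if span < 0.93 * 2 * math.pi and _ray_crossings_ok(polygon, anchor):
            return anchor
        off *= 2.0
    raise ValueError(
        "no visible anchor found; consider a general-conic partition fallback")


# --------------------------------------------------------------------------
# equal-area ray sweep
# --------------------------------------------------------------------------

@dataclass
class BinSet:
    B: int
    sub_polygons: list[Polygon]
    alpha_polygon: Polygon
    anchor: np.ndarray
    sweep_angles: np.ndarray     # B+1 cut angles, increasing
    bin_of_image: np.ndarray | None = None
    occupancy: np.ndarray | None = None
    outside: np.ndarray | None = None


def _angular_window(polygon: Polygon, anchor: np.ndarray):
    """Contiguous angular window of the polygon as seen from the anchor.

    The window is the complement of the largest angular gap between
    boundary samples, which keeps the sweep ordering contiguous even when
    the polygon wraps far around the anchor (e.g. arch legs reaching below
    an alcove anchor).  The boundary is densified first so that long
    straight edges cannot masquerade as angular gaps."""
    dense = polygon.segmentize(max(polygon.exterior.length / 512.0, 1e-9))
    coords = np.asarray(dense.exterior.coords)[:-1]
    ang = np.sort(np.arctan2(coords[:, 1] - anchor[1], coords[:, 0] - anchor[0]))
    gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * math.pi]]))
    i = int(np.argmax(gaps))
    ref = ang[(i + 1) % len(ang)] if i + 1 < len(ang) else ang[0]
    span = 2 * math.pi - gaps[i]
    return float(ref), 0.0, float(span)


def _wedge(anchor, ref, a0, a1, radius):
    n_arc = max(8, int(math.ceil((a1 - a0) / 0.01)))
    angles = ref + np.linspace(a0, a1, n_arc)
    arc = np.stack([anchor[0] + radius * np.cos(angles),
                    anchor[1] + radius * np.sin(angles)], axis=1)
    return Polygon(np.vstack([anchor, arc]))


def equal_area_bins(polygon: Polygon, anchor: np.ndarray, B: int,
                    area_tol: float = 1e-3) -> BinSet:
    """Sweep a ray from the anchor across the polygon and cut at angles of
    equal swept area (bisection per cut to ``area_tol`` of total area)."""
    if B < 2:
        raise ValueError("B must be >= 2")
    anchor = np.asarray(anchor, dtype=float)
    ref, a_lo, a_hi = _angular_window(polygon, anchor)
    minx, miny, maxx, maxy = polygon.bounds
    radius = 3.0 * math.hypot(maxx - minx, maxy - miny) + \
        math.hypot(maxx - anchor[0], maxy - anchor[1])
    total = polygon.area
    pad = 1e-6 * (a_hi - a_lo)

    def swept(a):
        return _wedge(anchor, ref, a_lo - pad, a, radius).intersection(polygon).area

    # monotonicity check on a coarse grid
    probe = np.linspace(a_lo, a_hi, 41)
    areas = np.array([swept(a) for a in probe])
    if (np.diff(areas) < -1e-3 * total).any():
        raise ValueError("swept area is non-monotone: polygon is not "
                         "star-shaped from the anchor")
    cuts = [a_lo - pad]
    for m in range(1, B):
        target = m * total / B
        lo, hi = cuts[-1], a_hi + pad
        cut = None
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            s = swept(mid)
            if abs(s - target) <= 0.1 * area_tol * total:
                cut = mid
                break
            if s < target:
                lo = mid
            else:
                hi = mid
        cuts.append(cut if cut is not None else 0.5 * (lo + hi))
    cuts.append(a_hi + pad)
    subs = []
    for m in range(B):
        w = _wedge(anchor, ref, cuts[m], cuts[m + 1], radius)
        piece = w.intersection(polygon)
        if piece.geom_type == "GeometryCollection" or piece.geom_type.startswith("Multi"):
            parts = [g for g in getattr(piece, "geoms", []) if isinstance(g, Polygon)]
            piece = max(parts, key=lambda g: g.area) if parts else Polygon()
        subs.append(piece)
    return BinSet(B=B, sub_polygons=subs, alpha_polygon=polygon, anchor=anchor,
                  sweep_angles=np.asarray(cuts))


def assign_bins(points: np.ndarray, bin_set: BinSet):
    """Assign each point to its sub-polygon (boundary ties to the lower
    index; points outside the alpha polygon go to the nearest bin by
    polygon distance and are flagged).  Returns (bin_of_image, occupancy).
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    bin_of = np.full(n, -1, dtype=int)
    for b, poly in enumerate(bin_set.sub_polygons):
        if poly.is_empty:
            continue
        unassigned = bin_of < 0
        if not unassigned.any():
            break
        hit = shapely.intersects_xy(poly, points[unassigned, 0], points[unassigned, 1])
        idx = np.nonzero(unassigned)[0][hit]
        bin_of[idx] = b
    outside = bin_of < 0
    if outside.any():
        pts = shapely.points(points[outside])
        dists = np.stack([
            shapely.distance(poly, pts) if not poly.is_empty else np.full(outside.sum(), np.inf)
            for poly in bin_set.sub_polygons
        ])
        bin_of[outside] = dists.argmin(axis=0)
    occupancy = np.bincount(bin_of, minlength=bin_set.B)
    bin_set.bin_of_image = bin_of
    bin_set.occupancy = occupancy
    bin_set.outside = outside
    return bin_of, occupancy


# --------------------------------------------------------------------------
# movies
# --------------------------------------------------------------------------

@dataclass
class Movie2D:
    frames: np.ndarray           # (B, P, P)
    cm_id: int = 1
    pd_id: int = -1
    sense: int = 1
    empty_frames: np.ndarray | None = None


def make_movie(images: np.ndarray, bin_of_image: np.ndarray, B: int,
               cm_id: int = 1, pd_id: int = -1) -> Movie2D:
    """Average the raw images of each bin into one frame per state."""
    images = np.asarray(images)
    P = images.shape[1]
    frames = np.zeros((B, P, images.shape[2]))
    empty = np.zeros(B, dtype=bool)
    for b in range(B):
        sel = bin_of_image == b
        if sel.any():
            frames[b] = images[sel].mean(axis=0)
        else:
            empty[b] = True
            logger.warning("bin %d is empty: zero frame emitted", b)
    return Movie2D(frames=frames, cm_id=cm_id, pd_id=pd_id, empty_frames=empty)


def svd_filter(movie: Movie2D, k: int) -> Movie2D:
    """Keep the top-k singular triplets of the (frames x pixels) matrix."""
    B, P, Q = movie.frames.shape
    if k > min(B, P * Q):
        raise ValueError("k exceeds movie rank")
    M = movie.frames.reshape(B, -1)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    filtered = (U[:, :k] * s[:k]) @ Vt[:k]
    return Movie2D(frames=filtered.reshape(B, P, Q), cm_id=movie.cm_id,
                   pd_id=movie.pd_id, sense=movie.sense,
                   empty_frames=movie.empty_frames)


def partition_subspace(emb, subspace: tuple[int, int], B: int, cm_id: int = 1,
                       quantile: float = 0.0, halve: bool = False) -> BinSet:
    """Full partition of one CM subspace: arccos map, alpha shape, anchor,
    equal-area ray sweep, point-in-bin assignment.

    ``halve`` splits the cloud at its symmetry axis and partitions the
    mirrored half (the figure-style variant); the default partitions the
    full cloud.
    """
    ts = transform_subspace(emb, subspace, cm_id=cm_id, quantile=quantile)
    phi = ts.phi
    if halve:
        a, h, k = _fit_absolute_value(phi)
        folded = phi.copy()
        folded[:, 0] = h + np.abs(folded[:, 0] - h)
        phi = folded
    # points clamped to the frame by the quantile rescaling would smear the
    # outline along the boundary; the polygon is built from the interior
    # cloud and clamped points fall to their nearest bin at assignment
    shape_pts = phi
    if quantile > 0:
        eps = 1e-9
        interior = ((phi > eps) & (phi < math.pi - eps)).all(axis=1)
        if interior.sum() >= max(10, len(phi) // 4):
            shape_pts = phi[interior]
    poly = smooth_polygon(alpha_polygon(shape_pts))
    anchor = place_anchor(poly, shape_pts)
    bins = equal_area_bins(poly, anchor, B)
    assign_bins(phi, bins)
    return bins
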