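"""Conformational-motion subspace identification and eigenfunction realignment.

Each conformational motion (CM) is housed in one 2D eigenvector subspace
{Psi_i x Psi_j} as a parabolic point cloud, hidden among harmonics
(higher-order Lissajous parabolas that repeat the motion within one span)
and mixed subspaces.  Subspaces are found by ranked least-squares conic
fits with two exclusion rules: a candidate sharing an eigenvector index
with an accepted CM is a harmonic, and so is a candidate whose opening
coordinate is functionally dependent on an accepted CM's ordering (the
index-disjoint {Psi_3 x Psi_6}-type repeats).

Projection-direction disparity mixes canonical eigenfunctions across
eigenvectors:  Psi_i = cos(t) psi_v + sin(t) psi_w.  The mixing is undone
by composed planar (Givens) rotations; each angle is found by minimizing
the number of occupied 2D-histogram bins of the affected CM subspaces as
the plane is swept (aligned parabolas are thin; mixed ones smear).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .embedding import Embedding

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# conic fitting
# --------------------------------------------------------------------------

@dataclass
class ConicFit:
    """General-conic coefficients (a, b, c, d, e, f) of
    ax^2 + bxy + cy^2 + dx + ey + f = 0, unit-norm, with goodness of fit.

    For parabola-mode fits ``poly`` additionally holds (a, b, c) of
    y = a x^2 + b x + c and R^2 is the ordinary functional coefficient of
    determination.  General mode keeps the flexible implicit-conic
    coefficients (needed for trajectories with inward-curled ends) but
    reports the same functional R^2 as its score, so the one acceptance
    gate stays discriminative in both modes.
    """

    coefficients: np.ndarray
    r2: float
    subspace: tuple[int, int]
    kind: str = "parabola"          # parabola | general
    degenerate: bool = False
    poly: np.ndarray | None = None


def fit_conic(points: np.ndarray, constraint: str = "parabola",
              subspace: tuple[int, int] = (0, 0)) -> ConicFit:
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be N x 2")
    x, y = points[:, 0], points[:, 1]
    n = len(points)

    if constraint == "parabola":
        if n < 3:
            raise ValueError("parabola fit needs >= 3 points")
        X = np.stack([x ** 2, x, np.ones(n)], axis=1)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else (1.0 if resid @ resid < 1e-18 else -np.inf)
        a, b, c = coef
        conic = np.array([a, 0.0, 0.0, b, -1.0, c])
        conic /= np.linalg.norm(conic)
        return ConicFit(conic, float(r2), subspace, kind="parabola", poly=coef)

    if constraint == "general":
        if n < 6:
            raise ValueError("general conic fit needs >= 6 points")
        M = np.stack([x ** 2, x * y, y ** 2, x, y, np.ones(n)], axis=1)
        _, _, vt = np.linalg.svd(M, full_matrices=False)
        coef = vt[-1]
        L = np.stack([x, y, np.ones(n)], axis=1)
        _, _, vt_l = np.linalg.svd(L, full_matrices=False)
        msd_line = float(((L @ vt_l[-1]) ** 2).mean())
        if np.linalg.norm(coef[:3]) < 1e-8 or msd_line < 1e-14:
            # collinear/degenerate: report the line's functional R^2
            slope, icpt = np.polyfit(x, y, 1) if x.var() > 0 else (0.0, y.mean())
            resid = y - (slope * x + icpt)
            ss_tot = ((y - y.mean()) ** 2).sum()
            r2_line = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 1.0
            return ConicFit(coef, float(r2_line), subspace, kind="general",
                            degenerate=True)
        functional = fit_conic(points, "parabola", subspace)
        return ConicFit(coef, functional.r2, subspace, kind="general",
                        poly=functional.poly)

    raise ValueError(f"unknown constraint {constraint!r}")


# --------------------------------------------------------------------------
# CM catalog (eigenfunction determination)
# --------------------------------------------------------------------------

@dataclass
class CMCatalog:
    """Ordered CM -> 2D subspace assignment plus excluded harmonics.

    Subspace indices are 1-based eigenvector labels (Psi_1 = first
    nontrivial eigenvector).  ``harmonics`` holds rejected subspaces whose
    parabola fit passed the threshold but that repeat an accepted CM
    (sharing an index, or functionally dependent on its ordering).
    """

    cms: dict[int, tuple[int, int]] = field(default_factory=dict)
    harmonics: set[tuple[int, int]] = field(default_factory=set)
    fits: dict[tuple[int, int], ConicFit] = field(default_factory=dict)
    r2_min: float = 0.7

    @property
    def n_found(self) -> int:
        return len(self.cms)

    def cm_fit(self, cm: int) -> ConicFit:
        return self.fits[self.cms[cm]]


def dependence_score(candidate: np.ndarray, ordering: np.ndarray) -> float:
    """0 if ``candidate`` is a function of the coordinate ranked by
    ``ordering``; ~1 if statistically independent of it.

    One minus the correlation ratio estimated from adjacent pairs along the
    ordering (unbiased within-pair variance over total variance).  A
    harmonic of a CM is a smooth function of that CM's coordinate, so
    adjacent pairs vary little and the score is near 0; an independent
    coordinate's values are exchangeable within pairs and the score is near
    1.  Ties in the ordering (duplicated states) are broken by a fixed
    pseudo-random shuffle so duplicates are treated as exchangeable.
    """
    n = len(candidate)
    rng = np.random.default_rng(0)
    order = np.argsort(ordering, kind="stable")
    vals = ordering[order]
    c = candidate[order].copy()
    # Duplicated states produce tight value clusters separated by wide gaps;
    # within a cluster the ordering is noise (possibly systematic), so it is
    # scrambled before pairing.  Without clusters, rank-adjacent pairs stand.
    gaps = np.diff(vals)
    if gaps.size and vals[-1] > vals[0]:
        # exact duplicates drive the median gap to zero, so every positive
        # gap marks a cluster boundary, as intended
        thr = max(20.0 * float(np.median(gaps)), 1e-9 * float(vals[-1] - vals[0]))
        splits = np.nonzero(gaps > thr)[0]
        if 1 <= splits.size <= n // 2:
            start = 0
            for s in list(splits + 1) + [n]:
                seg = slice(start, s)
                c[seg] = c[seg][rng.permutation(s - start)]
                start = s
    m = (n // 2) * 2
    pairs = c[:m].reshape(-1, 2)
    within = float((np.diff(pairs, axis=1) ** 2 / 2.0).mean())
    total = float(candidate.var())
    if total < 1e-30:
        return 0.0
    return float(np.clip(within / total, 0.0, 1.0))


def determine_cm_subspaces(emb: Embedding, n_max: int = 3, r2_min: float = 0.7,
                           constraint: str = "parabola",
                           dependence_min: float = 0.5) -> CMCatalog:
    """Scan all {Psi_i x Psi_j}, i < j, rank parabolic fits, and greedily
    accept index-disjoint, non-harmonic subspaces as CMs.

    Returns an empty catalog (globular embedding) if no subspace reaches
    ``r2_min``.
    """
    if emb.d < 4:
        raise ValueError("embedding needs at least 4 eigenvectors")
    cat = CMCatalog(r2_min=r2_min)
    for i in range(1, emb.d + 1):
        for j in range(i + 1, emb.d + 1):
            pts = np.stack([emb.column(i), emb.column(j)], axis=1)
            cat.fits[(i, j)] = fit_conic(pts, constraint=constraint, subspace=(i, j))
    ranked = sorted(cat.fits.values(), key=lambda f: (-f.r2, f.subspace))
    for f in ranked:
        if f.r2 < r2_min or f.degenerate:
            break
        if cat.n_found >= n_max:
            break
        i, j = f.subspace
        used = {k for s in cat.cms.values() for k in s}
        if used & {i, j}:
            cat.harmonics.add((i, j))
            continue
        is_harm = False
        for cm, (a, _b) in cat.cms.items():
            score = dependence_score(emb.column(i), emb.column(a))
            if score < dependence_min:
                logger.debug("subspace %s dependent on CM_%d (score %.3f): harmonic",
                             (i, j), cm, score)
                is_harm = True
                break
        if is_harm:
            cat.harmonics.add((i, j))
            continue
        cat.cms[cat.n_found + 1] = (i, j)
    if cat.n_found == 0:
        logger.warning("no subspace reached R^2 >= %.2f: globular embedding", r2_min)
    return cat


# --------------------------------------------------------------------------
# rotation operators
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RotationOperator:
    plane: tuple[int, int]    # 1-based eigenvector indices, i < j
    angle_deg: float

    def __post_init__(self):
        i, j = self.plane
        if not i < j:
            raise ValueError("plane must have i < j")
        if not (-90.0 <= self.angle_deg < 90.0):
            raise ValueError("angle must lie in [-90, 90)")


@dataclass
class RotationPlan:
    operators: list[RotationOperator] = field(default_factory=list)
    d: int = 15


def count_rotation_submatrices(d: int) -> int:
    """Number of planar rotation sub-matrices composing a d-dim rotation."""
    if d < 2:
        raise ValueError("d must be >= 2")
    return d * (d - 1) // 2


def essential_operators(catalog: CMCatalog, d: int, mode: str = "adjacent") -> list[tuple[int, int]]:
    """Planes to search: one per pair of CMs (C(n, 2) in total).

    Mixing couples eigenvectors that are close in the spectrum, so the
    default picks, for each CM pair, the cross pair of indices with minimal
    separation.  ``mode='all_cross'`` searches all four cross planes per CM
    pair for harder cases.
    """
    cms = list(catalog.cms.values())
    planes: list[tuple[int, int]] = []
    for a in range(len(cms)):
        for b in range(a + 1, len(cms)):
            cross = sorted(
                (tuple(sorted((i, j))) for i in cms[a] for j in cms[b]),
                key=lambda p: (p[1] - p[0], p))
            if mode == "adjacent":
                planes.append(cross[0])
            elif mode == "all_cross":
                planes.extend(p for p in cross if p not in planes)
            else:
                raise ValueError(f"unknown mode {mode!r}")
    return planes


def _rotate_columns(eigvecs: np.ndarray, i: int, j: int, theta_deg: float) -> np.ndarray:
    out = eigvecs.copy()
    t = np.deg2rad(theta_deg)
    ci, cj = eigvecs[:, i - 1], eigvecs[:, j - 1]
    out[:, i - 1] = np.cos(t) * ci - np.sin(t) * cj
    out[:, j - 1] = np.sin(t) * ci + np.cos(t) * cj
    return out


@dataclass
class AngleSearchResult:
    theta_deg: float
    counts: np.ndarray
    theta_grid: np.ndarray
    flat: bool = False


def histogram_angle_search(emb: Embedding, plane: tuple[int, int],
                           catalog: CMCatalog,
                           theta_grid: np.ndarray | None = None,
                           bins: int = 40) -> AngleSearchResult:
    """Find the angle whose rotation of ``plane`` minimizes the summed
    number of nonzero 2D-histogram bins over all affected CM subspaces.

    Histogram bounding boxes are frozen at theta = 0 so counts are
    comparable across angles; ties break toward the smallest |theta|.  A
    flat count profile (variation < 1 bin) returns 0 with ``flat=True``.
    """
    if theta_grid is None:
        theta_grid = np.arange(-90.0, 90.0, 1.0)
    if bins < 20:
        raise ValueError("bins must be >= 20 per axis")
    i, j = plane
    affected = [s for s in catalog.cms.values() if i in s or j in s]
    if not affected:
        affected = [plane]
    boxes = {}
    for (a, b) in affected:
        pa, pb = emb.column(a), emb.column(b)
        boxes[(a, b)] = [[pa.min(), pa.max()], [pb.min(), pb.max()]]
    counts = np.empty(len(theta_grid))
    for t_idx, theta in enumerate(theta_grid):
        rot = _rotate_columns(emb.eigvecs, i, j, theta)
        total = 0
        for (a, b) in affected:
            H, _, _ = np.histogram2d(rot[:, a - 1], rot[:, b - 1],
                                     bins=bins, range=boxes[(a, b)])
            total += int((H > 0).sum())
        counts[t_idx] = total
    if counts.max() - counts.min() < 1.0:
        return AngleSearchResult(0.0, counts, theta_grid, flat=True)
    best = counts == counts.min()
    cand = theta_grid[best]
    theta = float(cand[np.lexsort((cand, np.abs(cand)))[0]])
    return AngleSearchResult(theta, counts, theta_grid)


def apply_rotation_plan(emb: Embedding, plan: RotationPlan) -> Embedding:
    """Apply the ordered product of planar rotations to the eigenbasis;
    only the named columns change and column norms are preserved."""
    out = emb.copy()
    for op in plan.operators:
        if max(op.plane) > emb.d:
            raise ValueError(f"plane {op.plane} outside embedding dimension {emb.d}")
        out.eigvecs = _rotate_columns(out.eigvecs, *op.plane, op.angle_deg)
    return out


def realign(emb: Embedding, catalog: CMCatalog,
            mode: str = "adjacent", bins: int = 40,
            theta_grid: np.ndarray | None = None,
            constraint: str = "parabola",
            tolerance: float = 0.01) -> tuple[Embedding, RotationPlan, CMCatalog]:
    """Search and apply the counter-rotation for each essential operator.

    Any operator that worsens a CM subspace fit by more than ``tolerance``
    in R^2 is reverted.  Returns the rotated embedding, the plan actually
    applied, and a catalog with refreshed fits.
    """
    if catalog.n_found == 0:
        raise ValueError("empty CM catalog: nothing to realign")

    def cm_r2s(e: Embedding) -> dict[int, float]:
        out = {}
        for cm, (a, b) in catalog.cms.items():
            pts = np.stack([e.column(a), e.column(b)], axis=1)
            out[cm] = fit_conic(pts, constraint=constraint, subspace=(a, b)).r2
        return out

    current = emb.copy()
    plan = RotationPlan(d=emb.d)
    for plane in essential_operators(catalog, emb.d, mode=mode):
        res = histogram_angle_search(current, plane, catalog,
                                     theta_grid=theta_grid, bins=bins)
        if res.flat or res.theta_deg == 0.0:
            plan.operators.append(RotationOperator(plane, 0.0))
            continue
        before = cm_r2s(current)
        trial = apply_rotation_plan(
            current, RotationPlan([RotationOperator(plane, res.theta_deg)], d=emb.d))
        after = cm_r2s(trial)
        if any(after[cm] < before[cm] - tolerance for cm in before):
            logger.warning("reverting R_%s(%g deg): fit degraded", plane, res.theta_deg)
            plan.operators.append(RotationOperator(plane, 0.0))
            continue
        current = trial
        plan.operators.append(RotationOperator(plane, res.theta_deg))
    new_cat = CMCatalog(cms=dict(catalog.cms), harmonics=set(catalog.harmonics),
                        r2_min=catalog.r2_min)
    for (a, b) in new_cat.cms.values():
        pts = np.stack([current.column(a), current.column(b)], axis=1)
        new_cat.fits[(a, b)] = fit_conic(pts, constraint=constraint, subspace=(a, b))
    return current, plan, new_cat
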