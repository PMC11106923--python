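"""Cardiac-axis and cardiothoracic-ratio measurement from label maps.

The two biometrics follow the standard mask-based post-processing used when a
segmentation network replaces manual calipers on the four-chamber view:

* **Cardiac axis (CAx)** — the interventricular septum mask is thinned to a
  1-pixel skeleton, side branches are pruned by keeping the longest geodesic
  path, and a total-least-squares line gives the septal long axis.  The
  thoracic anteroposterior (AP) axis is the line through the mass centers of
  the spine and thorax masks, oriented spine -> anterior.  The CAx is the
  acute angle between the two lines.

* **Cardiothoracic ratio (CTR)** — the outer contours of the heart and thorax
  masks are traced and an ellipse is fitted to each by direct least squares
  (E_c = F(m_c), E_t = F(m_t)); the CTR is the ratio of the two ellipse areas
  A(E_c)/A(E_t).

All coordinates are 0-based ``(row, col)`` with pixel centers on the integer
lattice.  Angles are computed in physical units (pixel spacing applied), since
angles are not invariant under anisotropic scaling; the area ratio is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import skeletonize as _skimage_skeletonize

from .label_io import BinaryMask, CaseBundle, LabelMap, extract_mask, largest_component

__all__ = [
    "Line2D",
    "Ellipse",
    "CAxResult",
    "CTRResult",
    "DegenerateGeometryError",
    "skeletonize",
    "prune_to_longest_path",
    "fit_line_tls",
    "mass_center",
    "thoracic_ap_axis",
    "angle_between",
    "measure_cax",
    "extract_contour",
    "fit_ellipse",
    "ellipse_area",
    "measure_ctr",
    "HEART_STRUCTURE_LABELS",
]

# fallback composition when the dedicated area outlines are absent
HEART_STRUCTURE_LABELS: tuple[str, ...] = (
    "Left Atrium",
    "Left Ventricle",
    "Right Atrium",
    "Right Ventricle",
    "Interventricular Septum",
    "Interatrial Septum",
    "Left Ventricular Wall",
    "Right Ventricular Wall",
)


class DegenerateGeometryError(ValueError):
    """A geometric fit could not be performed (too few/degenerate points)."""


@dataclass(frozen=True)
class Line2D:
    """Infinite line: a point on it and a unit direction, in (row, col)."""

    point: tuple[float, float]
    direction: tuple[float, float]

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, float)
        n = float(np.hypot(*d))
        if abs(n - 1.0) > 1e-9:
            if n == 0:
                raise ValueError("line direction must be non-zero")
            object.__setattr__(self, "direction", (float(d[0] / n), float(d[1] / n)))


@dataclass(frozen=True)
class Ellipse:
    """Center, full axis lengths (major >= minor) and rotation in [0, 180).

    ``rotation_deg`` is the angle of the major axis measured from the column
    (horizontal) axis toward the row (downward) axis.
    """

    center: tuple[float, float]
    major_axis: float
    minor_axis: float
    rotation_deg: float

    def __post_init__(self) -> None:
        if not (self.major_axis >= self.minor_axis > 0):
            raise ValueError("require major_axis >= minor_axis > 0")
        object.__setattr__(self, "rotation_deg", float(self.rotation_deg) % 180.0)


@dataclass(frozen=True)
class CAxResult:
    angle_deg: float
    septal_line: Line2D
    ap_line: Line2D
    n_skeleton_points: int
    warnings: tuple[str, ...] = ()
    signed_angle_deg: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.angle_deg <= 90.0):
            raise ValueError("CAx must lie in [0, 90] degrees")


@dataclass(frozen=True)
class CTRResult:
    ratio: float
    heart_ellipse: Ellipse
    thorax_ellipse: Ellipse


# ---------------------------------------------------------------------------
# primitives

def skeletonize(mask: BinaryMask) -> np.ndarray:
    """Medial-axis point set of the largest component, as an (n, 2) array.

    Every returned (row, col) lies inside the input mask.
    """
    if mask.is_empty():
        raise ValueError("cannot skeletonize an empty mask")
    comp = largest_component(mask, connectivity=8)
    sk = _skimage_skeletonize(comp.grid)
    pts = np.argwhere(sk)
    if pts.size == 0:  # pathological: thinning removed everything
        pts = np.argwhere(comp.grid)
    return pts


def prune_to_longest_path(points: np.ndarray) -> np.ndarray:
    """Prune skeleton side branches: keep the longest geodesic path.

    The skeleton pixels are treated as an 8-connected graph; two breadth-first
    sweeps find (approximately, exactly on trees) the graph diameter, and the
    pixels on one such longest path are returned.  This removes short spurs
    that would otherwise bias the line fit.
    """
    points = np.asarray(points)
    if len(points) <= 2:
        return points
    index = {tuple(p): i for i, p in enumerate(map(tuple, points))}
    neighbors: list[list[int]] = [[] for _ in points]
    offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    for (r, c), i in index.items():
        for dr, dc in offsets:
            j = index.get((r + dr, c + dc))
            if j is not None:
                neighbors[i].append(j)

    def bfs(start: int) -> tuple[np.ndarray, np.ndarray]:
        dist = np.full(len(points), -1, dtype=np.int64)
        parent = np.full(len(points), -1, dtype=np.int64)
        dist[start] = 0
        queue = [start]
        while queue:
            nxt = []
            for u in queue:
                for v in neighbors[u]:
                    if dist[v] < 0:
                        dist[v] = dist[u] + 1
                        parent[v] = u
                        nxt.append(v)
            queue = nxt
        return dist, parent

    d0, _ = bfs(0)
    a = int(np.argmax(d0))
    d1, parent = bfs(a)
    b = int(np.argmax(d1))
    path = [b]
    while parent[path[-1]] >= 0:
        path.append(int(parent[path[-1]]))
    return points[path[::-1]]


def fit_line_tls(points: np.ndarray) -> Line2D:
    """Total-least-squares (orthogonal) line through a point set.

    The line passes through the centroid with direction the principal
    eigenvector of the coordinate covariance; unlike ordinary regression it is
    well-defined for vertical point clouds.  Isotropic clouds (equal
    eigenvalues) are degenerate and raise.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of (row, col) points")
    if len(np.unique(pts, axis=0)) < 2:
        raise DegenerateGeometryError("need at least 2 distinct points for a line fit")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    if np.isclose(evals[0], evals[1], rtol=1e-12, atol=1e-12):
        raise DegenerateGeometryError("isotropic point cloud: line direction undefined")
    d = evecs[:, np.argmax(evals)]
    # canonical orientation: first non-zero component positive
    if d[0] < 0 or (d[0] == 0 and d[1] < 0):
        d = -d
    return Line2D(point=(float(centroid[0]), float(centroid[1])),
                  direction=(float(d[0]), float(d[1])))


def mass_center(mask: BinaryMask) -> tuple[float, float]:
    """Arithmetic mean of foreground pixel coordinates, (row, col)."""
    if mask.is_empty():
        raise ValueError("cannot take the mass center of an empty mask")
    rows, cols = np.nonzero(mask.grid)
    return float(rows.mean()), float(cols.mean())


def thoracic_ap_axis(thorax: BinaryMask, spine: BinaryMask) -> Line2D:
    """Anteroposterior axis: the line spine centroid -> thorax centroid.

    The direction points from posterior (spine) to anterior, so the optional
    signed cardiac axis is well-defined.  Spacing is applied so the axis is
    correct on anisotropic rasters.
    """
    ct = np.asarray(mass_center(thorax)) * np.asarray(thorax.spacing)
    cs = np.asarray(mass_center(spine)) * np.asarray(spine.spacing)
    d = ct - cs
    if np.hypot(*d) < max(thorax.spacing):
        raise DegenerateGeometryError(
            "thorax and spine centroids coincide; AP axis undefined"
        )
    d = d / np.hypot(*d)
    return Line2D(point=(float(ct[0]), float(ct[1])), direction=(float(d[0]), float(d[1])))


def angle_between(a: Line2D, b: Line2D) -> float:
    """Acute angle between two lines in degrees, in [0, 90]."""
    dot = abs(
        a.direction[0] * b.direction[0] + a.direction[1] * b.direction[1]
    )
    return float(np.degrees(np.arccos(min(dot, 1.0))))


def ellipse_area(e: Ellipse) -> float:
    """Area of an ellipse from its full axis lengths: pi * (M/2) * (m/2)."""
    return float(np.pi * (e.major_axis / 2.0) * (e.minor_axis / 2.0))


# ---------------------------------------------------------------------------
# contours and ellipse fitting

_MOORE_OFFSETS = (
    (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1),
)


def extract_contour(mask: BinaryMask) -> np.ndarray:
    """Ordered outer boundary of the largest component, as (n, 2) pixels.

    Moore-neighbor tracing with 8-connectivity, started at the top-left
    boundary pixel and traced clockwise in image coordinates.  Every returned
    point is a foreground pixel that is 4-adjacent to background (or to the
    image edge).
    """
    if mask.is_empty():
        raise ValueError("cannot extract the contour of an empty mask")
    comp = largest_component(mask, connectivity=8).grid
    rows, cols = np.nonzero(comp)
    start = (int(rows[0]), int(cols[0]))  # raster order: top-left foreground

    h, w = comp.shape

    def fg(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and bool(comp[r, c])

    if comp.sum() == 1:
        return np.array([start])

    contour = [start]
    # enter from the pixel above the start (background by construction)
    prev_dir = 2  # offset index pointing up
    cur = start
    max_steps = 4 * h * w  # safety bound; tracing visits each pixel few times
    for _ in range(max_steps):
        # scan Moore neighborhood clockwise starting after the backtrack pixel
        found = False
        for k in range(1, 9):
            idx = (prev_dir + k) % 8
            dr, dc = _MOORE_OFFSETS[idx]
            nr, nc = cur[0] + dr, cur[1] + dc
            if fg(nr, nc):
                # next backtrack direction: opposite of the step just taken,
                # advanced by one so the scan resumes past the previous pixel
                prev_dir = (idx + 4) % 8
                cur = (nr, nc)
                found = True
                break
        if not found:  # isolated pixel (cannot happen: handled above)
            break
        if cur == start:
            break
        contour.append(cur)
    return np.array(contour)


def _direct_conic_fit(xy: np.ndarray) -> np.ndarray:
    """Ellipse-constrained direct least-squares conic fit (Halir & Flusser).

    Returns conic coefficients (a, b, c, d, e, f) of
    a·x² + b·xy + c·y² + d·x + e·y + f = 0 satisfying 4ac − b² > 0.
    """
    x, y = xy[:, 0], xy[:, 1]
    d1 = np.column_stack([x * x, x * y, y * y])
    d2 = np.column_stack([x, y, np.ones_like(x)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise DegenerateGeometryError("degenerate point configuration") from exc
    m = s1 + s2 @ t
    # premultiply by inv(C1) where C1 encodes the constraint 4ac - b^2 = 1
    m = np.array([m[2] / 2.0, -m[1], m[0] / 2.0])
    evals, evecs = np.linalg.eig(m)
    # exactly one eigenvector satisfies the ellipse constraint
    cond = 4.0 * evecs[0] * evecs[2] - evecs[1] ** 2
    ok = np.isreal(evals) & (np.real(cond) > 0)
    if not ok.any():
        raise DegenerateGeometryError("ellipse fit degenerated to a non-ellipse conic")
    a1 = np.real(evecs[:, np.argmax(ok)])
    return np.concatenate([a1, t @ a1])


def _conic_to_ellipse(coeffs: np.ndarray) -> tuple[np.ndarray, float, float, float]:
    """Geometric parameters of an elliptical conic.

    Returns (center_xy, semi_major, semi_minor, theta) with theta the
    major-axis angle from +x toward +y.
    """
    a, b, c, d, e, f = coeffs
    q = np.array([[a, b / 2.0], [b / 2.0, c]])
    try:
        center = np.linalg.solve(2.0 * q, -np.array([d, e]))
    except np.linalg.LinAlgError as exc:
        raise DegenerateGeometryError("degenerate conic") from exc
    k = f + 0.5 * (d * center[0] + e * center[1])
    evals, evecs = np.linalg.eigh(q)
    with np.errstate(divide="ignore", invalid="ignore"):
        semi = np.sqrt(-k / evals)
    if not np.isfinite(semi).all() or (semi <= 0).any():
        raise DegenerateGeometryError("conic is not an ellipse")
    order = np.argsort(semi)[::-1]
    semi_major, semi_minor = float(semi[order[0]]), float(semi[order[1]])
    major_vec = evecs[:, order[0]]
    theta = float(np.arctan2(major_vec[1], major_vec[0]))
    return center, semi_major, semi_minor, theta


def fit_ellipse(points: np.ndarray) -> Ellipse:
    """Direct algebraic least-squares ellipse fit to boundary points.

    The numerically stable direct conic fit with the built-in ellipse
    constraint (the formulation behind OpenCV's ``fitEllipse``): recovery is
    exact to machine precision when the points lie on an ellipse.  Points are
    centered and scaled before fitting for conditioning; ellipse parameters
    transform simply under that similarity, so the result is de-normalized.
    Fewer than 5 distinct points, collinear points, or a non-elliptical conic
    raise :class:`DegenerateGeometryError`.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of (row, col) points")
    if len(np.unique(pts, axis=0)) < 5:
        raise DegenerateGeometryError("need at least 5 distinct points to fit an ellipse")
    mu = pts.mean(axis=0)
    centered = pts - mu
    if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        raise DegenerateGeometryError("collinear points cannot define an ellipse")
    scale = float(np.sqrt((centered**2).sum(axis=1).mean()))
    norm = centered[:, ::-1] / scale  # work in (x, y) = (col, row)
    coeffs = _direct_conic_fit(norm)
    center_xy, semi_major, semi_minor, theta = _conic_to_ellipse(coeffs)
    return Ellipse(
        center=(mu[0] + scale * center_xy[1], mu[1] + scale * center_xy[0]),
        major_axis=2.0 * scale * semi_major,
        minor_axis=2.0 * scale * semi_minor,
        rotation_deg=np.degrees(theta) % 180.0,
    )


# ---------------------------------------------------------------------------
# biometric pipelines

def _structure_mask(
    source: LabelMap | CaseBundle, name: str, *, allow_fallback_union: bool = False
) -> BinaryMask:
    """Mask for ``name``; HA/TA fall back to label unions when not annotated."""
    if isinstance(source, CaseBundle):
        m = extract_mask(source.anatomy, name)
        if m.is_empty() and source.area is not None:
            m = extract_mask(source.area, name)
        base = source.anatomy
    else:
        m = extract_mask(source, name)
        base = source
    if not m.is_empty() or not allow_fallback_union:
        return m
    if name == "Heart Area":
        union = np.zeros(base.shape, bool)
        for lab in HEART_STRUCTURE_LABELS:
            union |= extract_mask(base, lab).grid
        return BinaryMask(grid=union, spacing=base.spacing)
    if name == "Thorax Area":
        return BinaryMask(grid=base.grid > 0, spacing=base.spacing)
    return m


def measure_cax(source: LabelMap | CaseBundle) -> CAxResult:
    """Cardiac axis of a labeled four-chamber view.

    Septal axis: largest interventricular-septum component -> skeleton ->
    longest-path pruning -> orthogonal least-squares line.  AP axis: spine
    centroid to thorax centroid.  The reported angle is the acute angle in
    [0, 90] degrees; a signed variant (positive when the apex points to the
    fetal left of the AP axis) is attached as ``signed_angle_deg``.
    """
    spacing = (
        source.anatomy.spacing if isinstance(source, CaseBundle) else source.spacing
    )
    ivs = _structure_mask(source, "Interventricular Septum")
    spine = _structure_mask(source, "Spine")
    thorax = _structure_mask(source, "Thorax Area", allow_fallback_union=True)
    for label, m in (("Interventricular Septum", ivs), ("Spine", spine),
                     ("Thorax Area", thorax)):
        if m.is_empty():
            raise ValueError(f"required label is empty: {label!r}")

    warns: list[str] = []
    skeleton = skeletonize(ivs)
    path = prune_to_longest_path(skeleton)
    if len(path) < 10:
        warns.append(f"septal skeleton has only {len(path)} points")
    if abs(spacing[0] - spacing[1]) > 1e-12:
        warns.append("anisotropic pixel spacing: angles computed in physical units")
    septal = fit_line_tls(path * np.asarray(spacing))
    ap = thoracic_ap_axis(thorax, spine)
    angle = angle_between(septal, ap)
    # signed convention: cross(ap, septal) > 0 => apex toward the fetal left
    s = np.asarray(septal.direction)
    if np.dot(s, ap.direction) < 0:
        s = -s  # orient the septal axis toward anterior before signing
    cross = ap.direction[0] * s[1] - ap.direction[1] * s[0]
    signed = float(np.copysign(angle, cross)) if angle > 0 else 0.0
    return CAxResult(
        angle_deg=angle,
        septal_line=septal,
        ap_line=ap,
        n_skeleton_points=int(len(path)),
        warnings=tuple(warns),
        signed_angle_deg=signed,
    )


def measure_ctr(source: LabelMap | CaseBundle) -> CTRResult:
    """Cardiothoracic ratio: area ratio of ellipses fitted to heart and thorax.

    Uses the dedicated "Heart Area"/"Thorax Area" labels when present; when a
    prediction omits them, the heart falls back to the union of the eight
    cardiac structural labels and the thorax to the union of all foreground.
    """
    ellipses = {}
    for name in ("Heart Area", "Thorax Area"):
        m = _structure_mask(source, name, allow_fallback_union=True)
        if m.is_empty():
            raise ValueError(f"required label is empty: {name!r}")
        contour = extract_contour(m)
        ellipses[name] = fit_ellipse(contour)
    heart, thorax = ellipses["Heart Area"], ellipses["Thorax Area"]
    return CTRResult(
        ratio=ellipse_area(heart) / ellipse_area(thorax),
        heart_ellipse=heart,
        thorax_ellipse=thorax,
    )
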