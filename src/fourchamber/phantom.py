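"""Synthetic fetal-thorax phantoms with known cardiac axis and CTR.

The phantom emulates the geometry that drives the two biometrics on a real
four-chamber view, not ultrasound appearance: a thorax ellipse with a
posterior spine disc on the midline (anterior is "up", i.e. decreasing row),
a heart ellipse whose long axis makes a prescribed angle with the
spine→anterior axis, a septal band along that long axis (interventricular in
the ventricular half, interatrial in the atrial half), four chamber
quadrants, thin ventricular-wall shells on the heart boundary, lungs filling
the remaining thorax, a descending-aorta disc beside the spine, and short rib
arcs on the thorax boundary.

Because the heart/thorax *area* outlines overlap the structural labels, each
phantom is emitted as a :class:`~fourchamber.label_io.CaseBundle`: an anatomy
map (13 structural labels) plus an aligned area map (Heart Area, Thorax
Area).  Ground truth is exact by construction:

    true CTR = (heart_major · heart_minor) / (thorax_major · thorax_minor)

and the true cardiac axis is the prescribed septal angle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.draw import polygon as _draw_polygon

from .label_io import BinaryMask, CaseBundle, LabelMap
from .scheme import LabelScheme, default_scheme

__all__ = ["PhantomSpec", "PhantomOutput", "generate_phantom", "degrade_prediction"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one synthetic thorax.

    Axis lengths are *full* lengths in pixels.  ``true_cax_deg`` is the angle
    of the heart long axis relative to the anteroposterior axis, in [0, 90].
    """

    image_size: tuple[int, int] = (512, 512)
    thorax_axes: tuple[float, float] = (380.0, 300.0)
    heart_axes: tuple[float, float] = (228.0, 152.0)
    true_cax_deg: float = 30.0
    heart_center_offset: tuple[float, float] = (0.0, 0.0)
    septum_thickness: float = 10.0
    spine_radius: float = 13.0
    rib_arcs: int = 6
    boundary_jitter_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.true_cax_deg <= 90.0):
            raise ValueError("true_cax_deg must be in [0, 90]")
        if self.septum_thickness <= 0 or self.septum_thickness >= self.heart_axes[1]:
            raise ValueError("septum thickness must be positive and thinner than the heart")
        if self.rib_arcs < 0 or self.boundary_jitter_px < 0:
            raise ValueError("rib_arcs and boundary_jitter_px must be non-negative")
        if not self._heart_inside_thorax():
            raise ValueError("heart ellipse must lie fully inside the thorax ellipse")

    @property
    def true_ctr(self) -> float:
        """Ellipse-area ratio implied by the axis lengths."""
        return (self.heart_axes[0] * self.heart_axes[1]) / (
            self.thorax_axes[0] * self.thorax_axes[1]
        )

    def _heart_inside_thorax(self) -> bool:
        t = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        u, v = _heart_axes_vectors(self.true_cax_deg)
        boundary = (
            np.asarray(self.heart_center_offset)[None, :]
            + np.outer(np.cos(t) * self.heart_axes[0] / 2, u)
            + np.outer(np.sin(t) * self.heart_axes[1] / 2, v)
        )
        a_col, a_row = self.thorax_axes[0] / 2, self.thorax_axes[1] / 2
        val = (boundary[:, 0] / a_row) ** 2 + (boundary[:, 1] / a_col) ** 2
        return bool(np.all(val <= 1.0))

    @classmethod
    def from_targets(
        cls,
        true_cax_deg: float,
        true_ctr: float,
        image_size: tuple[int, int] = (512, 512),
        aspect: float = 1.5,
        seed: int = 0,
        **kwargs,
    ) -> "PhantomSpec":
        """Build a feasible spec hitting a prescribed CAx and CTR.

        The heart axis product is set by the CTR; the aspect ratio defaults to
        1.5 but is capped so the heart clears the posterior spine for any
        rotation, which makes every point of the standard recovery grid
        (CAx 10–80°, CTR 0.15–0.45) geometrically valid at 512².
        """
        scale = min(image_size) / 512.0
        thorax = (380.0 * scale, 300.0 * scale)
        product = true_ctr * thorax[0] * thorax[1]
        spine_radius = kwargs.get("spine_radius", 13.0 * scale)
        cap = thorax[1] - 2 * (2 * spine_radius + 6.0 * scale)  # clear the spine disc
        major = min(float(np.sqrt(product * aspect)), cap)
        minor = product / major
        if minor > major:
            major = minor = float(np.sqrt(product))
        return cls(
            image_size=image_size,
            thorax_axes=thorax,
            heart_axes=(major, minor),
            true_cax_deg=true_cax_deg,
            seed=seed,
            **kwargs,
        )


@dataclass(frozen=True)
class PhantomOutput:
    """A generated case bundle plus its exact ground truth."""

    bundle: CaseBundle
    true_cax_deg: float
    true_ctr: float

    @property
    def anatomy_map(self) -> LabelMap:
        return self.bundle.anatomy

    @property
    def area_map(self) -> LabelMap:
        assert self.bundle.area is not None
        return self.bundle.area


def _heart_axes_vectors(cax_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors (row, col) of the heart long axis u and short axis v.

    At 0° the long axis is the AP axis (pointing anterior = up); positive
    angles rotate the apex toward the fetal left (increasing column).
    """
    th = np.deg2rad(cax_deg)
    u = np.array([-np.cos(th), np.sin(th)])  # anterior at angle cax
    v = np.array([np.sin(th), np.cos(th)])  # perpendicular
    return u, v


def _ellipse_mask(
    shape: tuple[int, int],
    center: np.ndarray,
    semi_u: float,
    semi_v: float,
    u: np.ndarray,
    v: np.ndarray,
    jitter_px: float,
    rng: np.random.Generator,
    scale: float = 1.0,
) -> np.ndarray:
    """Rasterize a (possibly jittered) filled ellipse with axes along u, v."""
    if jitter_px <= 0:
        rr, cc = np.indices(shape)
        dr, dc = rr - center[0], cc - center[1]
        su = dr * u[0] + dc * u[1]
        sv = dr * v[0] + dc * v[1]
        return (su / (scale * semi_u)) ** 2 + (sv / (scale * semi_v)) ** 2 <= 1.0
    t = np.linspace(0, 2 * np.pi, 360, endpoint=False)
    radial = 1.0 + rng.normal(0.0, jitter_px, t.size) / max(semi_u, semi_v)
    pts = (
        center[None, :]
        + np.outer(radial * np.cos(t) * scale * semi_u, u)
        + np.outer(radial * np.sin(t) * scale * semi_v, v)
    )
    mask = np.zeros(shape, bool)
    rr, cc = _draw_polygon(pts[:, 0], pts[:, 1], shape)
    mask[rr, cc] = True
    return mask


def generate_phantom(spec: PhantomSpec, scheme: LabelScheme | None = None) -> PhantomOutput:
    """Render a phantom deterministically from its spec (seeded jitter only)."""
    scheme = scheme or default_scheme()
    h, w = spec.image_size
    rng = np.random.default_rng(spec.seed)
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    t_semi_col, t_semi_row = spec.thorax_axes[0] / 2.0, spec.thorax_axes[1] / 2.0
    row_axis = np.array([1.0, 0.0])
    col_axis = np.array([0.0, 1.0])

    thorax = _ellipse_mask(
        (h, w), center, t_semi_row, t_semi_col, row_axis, col_axis,
        spec.boundary_jitter_px, rng,
    )

    heart_center = center + np.asarray(spec.heart_center_offset, float)
    u, v = _heart_axes_vectors(spec.true_cax_deg)
    h_semi_major, h_semi_minor = spec.heart_axes[0] / 2.0, spec.heart_axes[1] / 2.0
    heart = _ellipse_mask(
        (h, w), heart_center, h_semi_major, h_semi_minor, u, v,
        spec.boundary_jitter_px, rng,
    )
    heart_inner = _ellipse_mask(
        (h, w), heart_center, h_semi_major, h_semi_minor, u, v, 0.0, rng, scale=0.92
    )

    rr, cc = np.indices((h, w))
    dr, dc = rr - heart_center[0], cc - heart_center[1]
    s = dr * u[0] + dc * u[1]  # along long axis, positive toward anterior/apex
    t = dr * v[0] + dc * v[1]  # across the septum, positive to the fetal left

    grid = np.zeros((h, w), dtype=np.int32)

    def paint(mask: np.ndarray, name: str) -> None:
        grid[mask] = scheme.id_of(name)

    # lungs fill the thorax; later structures overwrite
    paint(thorax & (cc >= center[1]), "Left Lung")
    paint(thorax & (cc < center[1]), "Right Lung")

    # heart interior: chambers + septal bands inside, wall shells on the rim
    septal_band = np.abs(t) <= spec.septum_thickness / 2.0
    atrial = s <= -0.1 * spec.heart_axes[0]  # atria: posterior 40% of long axis
    shell = heart & ~heart_inner
    paint(heart_inner & ~septal_band & ~atrial & (t > 0), "Left Ventricle")
    paint(heart_inner & ~septal_band & ~atrial & (t <= 0), "Right Ventricle")
    paint(heart_inner & ~septal_band & atrial & (t > 0), "Left Atrium")
    paint(heart_inner & ~septal_band & atrial & (t <= 0), "Right Atrium")
    paint(heart_inner & septal_band & ~atrial, "Interventricular Septum")
    paint(heart_inner & septal_band & atrial, "Interatrial Septum")
    paint(shell & (t > 0), "Left Ventricular Wall")
    paint(shell & (t <= 0), "Right Ventricular Wall")

    # rib arcs: thin bands hugging the thorax boundary, away from the spine
    if spec.rib_arcs > 0:
        r_norm = np.sqrt(
            ((rr - center[0]) / t_semi_row) ** 2 + ((cc - center[1]) / t_semi_col) ** 2
        )
        phi = np.arctan2(rr - center[0], cc - center[1])  # +pi/2 points posterior
        band = thorax & (r_norm >= 0.93)
        angles = np.linspace(-np.pi, np.pi, spec.rib_arcs, endpoint=False) + 0.1
        rib = np.zeros((h, w), bool)
        for a in angles:
            if abs(((a - np.pi / 2) + np.pi) % (2 * np.pi) - np.pi) < 0.55:
                continue  # keep the posterior pole free for the spine
            dphi = np.abs(((phi - a) + np.pi) % (2 * np.pi) - np.pi)
            rib |= band & (dphi < 0.13)
        paint(rib & ~heart, "RIB")

    # descending aorta: small disc posterior-left, clipped away from the heart
    dao_center = center + np.array([0.80 * t_semi_row, -0.30 * t_semi_col])
    dao = ((rr - dao_center[0]) ** 2 + (cc - dao_center[1]) ** 2) <= (8.0 * min(h, w) / 512.0) ** 2
    paint(dao & thorax & ~heart, "Descending Aorta")

    # spine: posterior midline disc, painted last so its centroid is exact
    spine_center = center + np.array([t_semi_row - spec.spine_radius - 4.0, 0.0])
    spine = ((rr - spine_center[0]) ** 2 + (cc - spine_center[1]) ** 2) <= spec.spine_radius**2
    paint(spine & thorax, "Spine")

    anatomy = LabelMap(grid=grid, scheme=scheme)

    area_grid = np.zeros((h, w), dtype=np.int32)
    area_grid[thorax] = scheme.id_of("Thorax Area")
    area_grid[heart] = scheme.id_of("Heart Area")
    area = LabelMap(grid=area_grid, scheme=scheme)

    bundle = CaseBundle(anatomy=anatomy, area=area, case_id=f"phantom_{spec.seed}")
    return PhantomOutput(
        bundle=bundle, true_cax_deg=spec.true_cax_deg, true_ctr=spec.true_ctr
    )


def degrade_prediction(
    lmap: LabelMap,
    dilation_px: int = 0,
    dropout_labels: list[str] | None = None,
    seed: int = 0,
) -> LabelMap:
    """Produce an imperfect "prediction" from a ground-truth map.

    Each label is alternately dilated or eroded by ``dilation_px`` (seeded
    choice per label), then the named labels are dropped entirely.  Dilated
    labels only grow into background so the result stays a valid map.
    """
    from scipy import ndimage

    if dilation_px < 0:
        raise ValueError("dilation_px must be non-negative")
    dropout = list(dropout_labels or [])
    for name in dropout:
        lmap.scheme.id_of(name)  # raises on unknown labels
    rng = np.random.default_rng(seed)
    grid = lmap.grid.copy()
    if dilation_px > 0:
        struct = ndimage.generate_binary_structure(2, 2)
        present = [i for i in lmap.scheme.ids if (lmap.grid == i).any()]
        for lid in present:
            mask = lmap.grid == lid
            if rng.random() < 0.5:
                new = ndimage.binary_erosion(mask, struct, iterations=dilation_px)
                grid[mask & ~new] = 0
            else:
                new = ndimage.binary_dilation(mask, struct, iterations=dilation_px)
                grid[new & (grid == 0)] = lid
    for name in dropout:
        grid[grid == lmap.scheme.id_of(name)] = 0
    return LabelMap(grid=grid, spacing=lmap.spacing, scheme=lmap.scheme)
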