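"""Reading, writing and basic manipulation of 2-D label maps.

Label maps are integer rasters over a :class:`~fourchamber.scheme.LabelScheme`.
Two on-disk formats are supported: single-channel indexed PNG (8/16-bit;
spacing metadata is not representable and defaults to 1 mm isotropic on read)
and NIfTI (.nii/.nii.gz, 2-D or 3-D with a singleton third dimension; pixel
spacing round-trips through the header).

Because the "Heart Area"/"Thorax Area" outlines spatially overlap the chamber
labels, a case is stored as a *bundle* of two aligned maps sharing a case id:
``<case>_anatomy`` (13 structural labels) and ``<case>_area`` (HA/TA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image
from skimage.measure import label as _cc_label

from .scheme import LabelScheme, default_scheme

__all__ = [
    "LabelMap",
    "BinaryMask",
    "CaseBundle",
    "read_label_map",
    "write_label_map",
    "read_bundle",
    "write_bundle",
    "find_bundles",
    "extract_mask",
    "largest_component",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


@dataclass
class LabelMap:
    """H×W integer grid whose values are 0 (background) or ids of ``scheme``."""

    grid: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    scheme: LabelScheme = field(default_factory=default_scheme)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError(f"label grid must be 2-D, got shape {self.grid.shape}")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("label grid must have an integer dtype")
        h, w = self.grid.shape
        if h < 8 or w < 8:
            raise ValueError(f"label map must be at least 8x8, got {h}x{w}")
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValueError("pixel spacing must be positive")
        bad = np.setdiff1d(np.unique(self.grid), (0, *self.scheme.ids))
        if bad.size:
            raise ValueError(
                f"label values not in scheme: {sorted(int(b) for b in bad)}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]


@dataclass
class BinaryMask:
    """Boolean foreground mask with the pixel spacing of its source map."""

    grid: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.grid.sum())

    def is_empty(self) -> bool:
        return not self.grid.any()


@dataclass
class CaseBundle:
    """Aligned pair of maps for one case: structural anatomy + HA/TA areas."""

    anatomy: LabelMap
    area: LabelMap | None = None
    case_id: str = ""

    def __post_init__(self) -> None:
        if self.area is not None and self.area.shape != self.anatomy.shape:
            raise ValueError("anatomy and area maps must share a shape")


def read_label_map(path: str | Path, scheme: LabelScheme | None = None) -> LabelMap:
    """Read an indexed PNG or single-slice NIfTI label map.

    Values absent from ``scheme`` raise a ``ValueError`` naming the offending
    ids.  Multi-channel PNGs and volumes with more than one slice are rejected.
    """
    path = Path(path)
    scheme = scheme or default_scheme()
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim == 3:
            if data.shape[2] != 1:
                raise ValueError(
                    f"only single-slice volumes are supported, got shape {data.shape}"
                )
            data = data[:, :, 0]
        elif data.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {data.shape}")
        zooms = img.header.get_zooms()[:2]
        spacing = (float(zooms[0]), float(zooms[1]))
        grid = np.rint(data).astype(np.int32)
    else:
        with Image.open(path) as im:
            if im.mode not in ("L", "I", "I;16", "P"):
                raise ValueError(
                    f"expected a single-channel indexed image, got mode {im.mode!r}"
                )
            grid = np.asarray(im, dtype=np.int32)
        if grid.ndim != 2:
            raise ValueError("expected a single-channel image")
        spacing = (1.0, 1.0)
    return LabelMap(grid=grid, spacing=spacing, scheme=scheme)


def write_label_map(lmap: LabelMap, path: str | Path) -> None:
    """Write a label map losslessly; format chosen from the file suffix."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if _is_nifti(path):
        affine = np.diag([lmap.spacing[0], lmap.spacing[1], 1.0, 1.0])
        img = nib.Nifti1Image(lmap.grid.astype(np.int16), affine)
        img.header.set_zooms((lmap.spacing[0], lmap.spacing[1]))
        nib.save(img, str(path))
    else:
        vmax = int(lmap.grid.max(initial=0))
        if vmax > 65535:
            raise ValueError("label ids exceed 16-bit PNG range")
        if vmax <= 255:
            im = Image.fromarray(lmap.grid.astype(np.uint8), mode="L")
        else:
            im = Image.fromarray(lmap.grid.astype(np.int32), mode="I")
        im.save(path)


def write_bundle(bundle: CaseBundle, directory: str | Path, fmt: str = "png") -> list[Path]:
    """Write ``<case>_anatomy.<fmt>`` (+ ``<case>_area.<fmt>``) into a directory."""
    directory = Path(directory)
    if not bundle.case_id:
        raise ValueError("bundle needs a case_id to be written")
    suffix = {"png": ".png", "nii": ".nii", "nii.gz": ".nii.gz"}[fmt]
    paths = []
    out = directory / f"{bundle.case_id}_anatomy{suffix}"
    write_label_map(bundle.anatomy, out)
    paths.append(out)
    if bundle.area is not None:
        out = directory / f"{bundle.case_id}_area{suffix}"
        write_label_map(bundle.area, out)
        paths.append(out)
    return paths


def read_bundle(
    directory: str | Path, case_id: str, scheme: LabelScheme | None = None
) -> CaseBundle:
    """Read a case bundle written by :func:`write_bundle` (area map optional)."""
    directory = Path(directory)
    anatomy = area = None
    for suffix in (".png", ".nii", ".nii.gz"):
        p = directory / f"{case_id}_anatomy{suffix}"
        if p.exists():
            anatomy = read_label_map(p, scheme)
            q = directory / f"{case_id}_area{suffix}"
            if q.exists():
                area = read_label_map(q, scheme)
            break
    if anatomy is None:
        raise FileNotFoundError(f"no anatomy map for case {case_id!r} in {directory}")
    return CaseBundle(anatomy=anatomy, area=area, case_id=case_id)


def find_bundles(directory: str | Path) -> list[str]:
    """Case ids of all bundles in a directory, sorted for determinism."""
    directory = Path(directory)
    ids = set()
    for p in directory.iterdir():
        name = p.name
        for suffix in ("_anatomy.png", "_anatomy.nii", "_anatomy.nii.gz"):
            if name.endswith(suffix):
                ids.add(name[: -len(suffix)])
    return sorted(ids)


def extract_mask(lmap: LabelMap, label_name: str) -> BinaryMask:
    """Binary mask of one named label (all-false if absent from the image)."""
    lid = lmap.scheme.id_of(label_name)
    return BinaryMask(grid=lmap.grid == lid, spacing=lmap.spacing)


def largest_component(mask: BinaryMask, connectivity: int = 8) -> BinaryMask:
    """Keep only the largest connected foreground component.

    ``connectivity`` is 4 or 8 (edge- vs edge+corner-adjacency).  Ties are
    broken by the smallest top-left foreground coordinate (raster order), so
    the result is deterministic.  An empty mask passes through unchanged.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if mask.is_empty():
        return BinaryMask(grid=np.zeros(mask.shape, bool), spacing=mask.spacing)
    lab = _cc_label(mask.grid, connectivity=1 if connectivity == 4 else 2)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    best = counts.max()
    # skimage labels components in raster order of first pixel, so the first
    # argmax already honors the top-left tie-break
    keep = int(np.argmax(counts == best))
    return BinaryMask(grid=lab == keep, spacing=mask.spacing)
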