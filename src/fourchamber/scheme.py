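"""Label scheme for the fetal four-chamber view.

The standard annotation protocol for this plane names 15 anatomical
structures: the four chambers, the two septa, the two ventricular walls,
both lungs, the descending aorta, the spine, ribs, and two region-of-interest
outlines (heart area, thorax area).  Numeric ids are not standardized, so this
package fixes them at 1..15 in protocol order and allows overriding from a
JSON file of ``{"name": id}`` pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = ["LabelScheme", "DEFAULT_LABEL_NAMES", "default_scheme"]

DEFAULT_LABEL_NAMES: tuple[str, ...] = (
    "Left Atrium",
    "Left Ventricle",
    "Right Atrium",
    "Right Ventricle",
    "Interventricular Septum",
    "Interatrial Septum",
    "Left Ventricular Wall",
    "Right Ventricular Wall",
    "Left Lung",
    "Right Lung",
    "Descending Aorta",
    "Spine",
    "RIB",
    "Heart Area",
    "Thorax Area",
)


@dataclass(frozen=True)
class LabelScheme:
    """Ordered mapping of label name -> positive integer id (0 = background).

    Name lookup is case-insensitive; ids must be unique and positive.
    """

    entries: dict[str, int] = field(
        default_factory=lambda: {n: i + 1 for i, n in enumerate(DEFAULT_LABEL_NAMES)}
    )

    def __post_init__(self) -> None:
        ids = list(self.entries.values())
        if len(self.entries) != 15:
            raise ValueError(
                f"expected exactly 15 non-background labels, got {len(self.entries)}"
            )
        if len(set(ids)) != len(ids):
            raise ValueError("label ids must be unique")
        if any(i <= 0 for i in ids):
            raise ValueError("label ids must be positive (0 is background)")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.entries)

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(self.entries.values())

    def id_of(self, name: str) -> int:
        """Return the id for ``name`` (case-insensitive)."""
        key = name.strip().lower()
        for n, i in self.entries.items():
            if n.lower() == key:
                return i
        raise KeyError(f"unknown label name: {name!r}")

    def name_of(self, label_id: int) -> str:
        for n, i in self.entries.items():
            if i == label_id:
                return n
        raise KeyError(f"no label with id {label_id}")

    def __contains__(self, name: object) -> bool:
        if not isinstance(name, str):
            return False
        try:
            self.id_of(name)
            return True
        except KeyError:
            return False

    @classmethod
    def from_json(cls, path: str | Path) -> "LabelScheme":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        return cls(entries={str(k): int(v) for k, v in raw.items()})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.entries, indent=2) + "\n", encoding="utf-8")


def default_scheme() -> LabelScheme:
    """The shipped 15-label scheme with ids 1..15 in protocol order."""
    with resources.files("fourchamber.data").joinpath("default_scheme.json").open(
        encoding="utf-8"
    ) as fh:
        raw = json.load(fh)
    return LabelScheme(entries={str(k): int(v) for k, v in raw.items()})
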