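"""Class legend for the six-class mangrove land-cover scheme.

The scheme distinguishes three mangrove classes — *Avicennia alba*,
*Rhizophora apiculata* and mixed mangrove stands — plus aquaculture ponds,
buildings and open water (sea/river). Display colors follow the conventional
map rendering: dark blue, navy blue, light blue, green, orange and brown,
in class order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass(frozen=True)
class ClassLegend:
    """Ordered mapping of class index -> (name, display RGB)."""

    names: tuple[str, ...]
    colors: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.colors):
            raise ValueError("legend names and colors must have equal length")
        for c in self.colors:
            if len(c) != 3 or any(not (0 <= v <= 255) for v in c):
                raise ValueError(f"invalid RGB color {c!r}")
        if len(set(self.colors)) != len(self.colors):
            raise ValueError("legend colors must be unique")

    @property
    def num_classes(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def to_json(self, path: str | Path) -> None:
        entries = [
            {"index": i, "name": n, "rgb": list(c)}
            for i, (n, c) in enumerate(zip(self.names, self.colors))
        ]
        Path(path).write_text(json.dumps(entries, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassLegend":
        entries = json.loads(Path(path).read_text())
        entries = sorted(entries, key=lambda e: e["index"])
        return cls(
            names=tuple(e["name"] for e in entries),
            colors=tuple(tuple(e["rgb"]) for e in entries),
        )


#: Default six-class legend; mangrove classes occupy indices 0-2.
DEFAULT_LEGEND = ClassLegend(
    names=(
        "Avicennia alba",
        "Rhizophora apiculata",
        "Mixed mangroves",
        "Aquaculture",
        "Buildings",
        "Sea/River",
    ),
    colors=(
        (0, 0, 139),     # dark blue
        (0, 0, 205),     # navy blue
        (135, 206, 235), # light blue
        (34, 139, 34),   # green
        (255, 140, 0),   # orange
        (139, 69, 19),   # brown
    ),
)

#: Indices of the three mangrove classes within the default legend.
MANGROVE_CLASSES = (0, 1, 2)
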