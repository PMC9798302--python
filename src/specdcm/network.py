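"""The eight-node resting-state visual network and its connection taxonomy.

The network spans the visual hierarchy from the lateral geniculate nucleus
(LGN) through primary visual cortex (V1), hippocampus and medial thalamus up
to dorsolateral prefrontal cortex (PFC).  Every directed pair of regions
(including self pairs) is a connection: 56 extrinsic (between-region,
in Hz) plus 8 intrinsic (within-region, log-scaled) couplings.  Each
extrinsic connection is classified by its direction relative to the
hierarchy (bottom-up, top-down or lateral) and by laterality (intra- vs
inter-hemispheric); these labels drive the factorial model space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Region",
    "NetworkSpec",
    "ConnectionLabel",
    "build_visual_network",
    "classify_connection",
]

#: hierarchy ranks, lower = earlier in the visual stream
HIERARCHY = {"LGN": 1, "V1": 2, "HC": 3, "medThal": 4, "PFC": 5}

#: bilateral region groups used by the regional-involvement factor
BILATERAL_GROUPS = ("LGN", "medThal", "V1", "HC", "PFC")


@dataclass(frozen=True)
class Region:
    """A network node: a sphere in MNI space with a hierarchy rank.

    ``group`` names the bilateral region family (e.g. left and right LGN
    both belong to group ``"LGN"``); ``level`` is the hierarchy rank
    LGN=1 < V1=2 < HC=3 < medThal=4 < PFC=5.
    """

    name: str
    hemisphere: str  # left | right | midline
    mni: tuple[float, float, float]  # mm
    radius: float  # mm
    level: int
    group: str

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right", "midline"):
            raise ValueError(f"bad hemisphere {self.hemisphere!r}")
        if self.radius not in (4.0, 8.0, 10.0):
            raise ValueError(f"radius must be 4, 8 or 10 mm, got {self.radius}")
        if self.level != HIERARCHY[self.group]:
            raise ValueError(f"level {self.level} inconsistent with group {self.group}")


@dataclass(frozen=True)
class ConnectionLabel:
    """Taxonomy of one directed connection."""

    direction: str  # top_down | bottom_up | lateral | intrinsic
    hemispheric: str  # intra | inter | not_applicable
    regions_touched: frozenset = field(default_factory=frozenset)


@dataclass(frozen=True)
class NetworkSpec:
    """Ordered region list plus the canonical connection indexing.

    Connections are indexed row-major over (destination, source):
    index = 8 * dst + src, covering all 64 directed pairs.  Self pairs
    (src == dst) are the 8 intrinsic connections.
    """

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        if len(self.regions) != 8:
            raise ValueError("the visual network has exactly 8 regions")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_connections(self) -> int:
        return self.n_regions**2

    def index_of(self, src: int, dst: int) -> int:
        n = self.n_regions
        if not (0 <= src < n and 0 <= dst < n):
            raise IndexError(f"region index out of range: src={src}, dst={dst}")
        return dst * n + src

    def pair_of(self, index: int) -> tuple[int, int]:
        n = self.n_regions
        if not 0 <= index < n * n:
            raise IndexError(f"connection index out of range: {index}")
        return index % n, index // n  # (src, dst)

    def region_index(self, name: str) -> int:
        for i, r in enumerate(self.regions):
            if r.name == name:
                return i
        raise KeyError(f"unknown region {name!r}")

    @property
    def extrinsic_indices(self) -> np.ndarray:
        """Indices of the 56 between-region connections."""
        idx = [self.index_of(s, d) for d in range(8) for s in range(8) if s != d]
        return np.asarray(sorted(idx), dtype=int)

    @property
    def intrinsic_indices(self) -> np.ndarray:
        """Indices of the 8 self connections."""
        return np.asarray([self.index_of(i, i) for i in range(8)], dtype=int)

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        payload = [
            {
                "name": r.name,
                "hemisphere": r.hemisphere,
                "mni": list(r.mni),
                "radius": r.radius,
                "level": r.level,
                "group": r.group,
            }
            for r in self.regions
        ]
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        payload = json.loads(text)
        return cls(
            tuple(
                Region(
                    name=r["name"],
                    hemisphere=r["hemisphere"],
                    mni=tuple(r["mni"]),
                    radius=float(r["radius"]),
                    level=int(r["level"]),
                    group=r["group"],
                )
                for r in payload
            )
        )


def build_visual_network() -> NetworkSpec:
    """The canonical 8-region visual network.

    Region order is fixed (lLGN, rLGN, medThal, V1, lHC, rHC, lPFC, rPFC)
    so that serialization and connection indexing are deterministic.
    Sphere radii: 4 mm (LGN), 8 mm (medial thalamus, hippocampus, PFC),
    10 mm (V1).
    """
    R = Region
    return NetworkSpec(
        (
            R("lLGN", "left", (-22.0, -29.0, -4.0), 4.0, 1, "LGN"),
            R("rLGN", "right", (21.0, -27.0, -4.0), 4.0, 1, "LGN"),
            R("medThal", "midline", (0.0, -15.0, 6.0), 8.0, 4, "medThal"),
            R("V1", "midline", (0.0, -83.0, 2.0), 10.0, 2, "V1"),
            R("lHC", "left", (-25.0, -15.0, -20.0), 8.0, 3, "HC"),
            R("rHC", "right", (25.0, -13.0, -21.0), 8.0, 3, "HC"),
            R("lPFC", "left", (-38.0, 33.0, 16.0), 8.0, 5, "PFC"),
            R("rPFC", "right", (38.0, 33.0, 16.0), 8.0, 5, "PFC"),
        )
    )


def classify_connection(src: int, dst: int, spec: NetworkSpec) -> ConnectionLabel:
    """Classify the directed connection src -> dst.

    Direction follows the hierarchy (bottom_up if the source sits lower
    than the destination, top_down if higher, lateral at equal levels,
    intrinsic for self connections).  Laterality is inter-hemispheric only
    when one endpoint is in the left and the other in the right hemisphere;
    midline nodes count as belonging to both hemispheres, so any connection
    touching a midline node is intra-hemispheric.
    """
    a = spec.regions[src]
    b = spec.regions[dst]
    if src == dst:
        return ConnectionLabel("intrinsic", "not_applicable", frozenset({a.group}))
    if a.level < b.level:
        direction = "bottom_up"
    elif a.level > b.level:
        direction = "top_down"
    else:
        direction = "lateral"
    hemis = {a.hemisphere, b.hemisphere}
    hemispheric = "inter" if hemis == {"left", "right"} else "intra"
    return ConnectionLabel(direction, hemispheric, frozenset({a.group, b.group}))
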