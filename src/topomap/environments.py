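"""Planar arenas with rectangular holes.

The test environments are 2 m x 2 m open-field arenas containing one or two
inaccessible rectangular holes.  The topology of such an arena is fully
described by its first two Betti numbers: ``b0 = 1`` (the accessible region
is connected) and ``b1 = number of holes`` (each hole contributes one
independent 1-D loop).  These ground-truth indices are what a place-cell
ensemble must recover from coactivity alone.

Three named scenarios are built in:

``A``
    one 50 cm x 50 cm hole in the centre, truth ``(1, 1)``;
``B``
    a 50 cm x 50 cm and a 50 cm x 100 cm hole, truth ``(1, 2)``;
``C``
    two 180 cm x 80 cm slabs that leave only narrow corridors, forcing
    quasi-linear running, truth ``(1, 2)``.

Hole *sizes* are fixed; hole *positions* are a configuration choice (they
are not topologically meaningful) and can be overridden via an explicit
spec.  Coordinates are continuous, metres, origin at the lower-left corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Rect",
    "Environment",
    "SpatialBinning",
    "make_environment",
    "is_accessible",
    "accessible_area_fraction",
    "NAMED_ENVIRONMENTS",
]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle (metres)."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate rectangle {self!r}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @classmethod
    def from_center(cls, cx: float, cy: float, w: float, h: float) -> "Rect":
        return cls(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)

    def contains(self, x, y, closed: bool = True):
        """Vectorised point-in-rectangle test (boundary included if closed)."""
        x = np.asarray(x)
        y = np.asarray(y)
        if closed:
            return (x >= self.x_min) & (x <= self.x_max) & (y >= self.y_min) & (y <= self.y_max)
        return (x > self.x_min) & (x < self.x_max) & (y > self.y_min) & (y < self.y_max)

    def overlaps(self, other: "Rect") -> bool:
        return not (
            self.x_max <= other.x_min
            or other.x_max <= self.x_min
            or self.y_max <= other.y_min
            or other.y_max <= self.y_min
        )


@dataclass(frozen=True)
class Environment:
    """Rectangular arena with axis-aligned rectangular holes.

    Ground-truth Betti numbers are ``(1, len(holes))``: the arena minus its
    holes is connected and each hole punches one independent loop.
    """

    width: float = 2.0
    height: float = 2.0
    holes: tuple[Rect, ...] = field(default_factory=tuple)
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("arena dimensions must be positive")
        for h in self.holes:
            if not (0 < h.x_min and h.x_max < self.width and 0 < h.y_min and h.y_max < self.height):
                raise ValueError(f"hole {h} not strictly inside the {self.width}x{self.height} arena")
        for i, a in enumerate(self.holes):
            for b in self.holes[i + 1 :]:
                if a.overlaps(b):
                    raise ValueError(f"holes {a} and {b} overlap")

    @property
    def betti_truth(self) -> tuple[int, int]:
        """(b0, b1) of the accessible region."""
        return (1, len(self.holes))

    @property
    def area(self) -> float:
        return self.width * self.height

    def to_spec(self) -> dict:
        """Serialisable description (name, dimensions, hole rectangles)."""
        return {
            "name": self.name,
            "width": self.width,
            "height": self.height,
            "holes": [[h.x_min, h.y_min, h.x_max, h.y_max] for h in self.holes],
        }

    @classmethod
    def from_spec(cls, spec: dict) -> "Environment":
        holes = tuple(Rect(*h) for h in spec.get("holes", []))
        return cls(
            width=float(spec.get("width", 2.0)),
            height=float(spec.get("height", 2.0)),
            holes=holes,
            name=str(spec.get("name", "custom")),
        )


# Hole sizes follow the three published scenarios; positions are a
# configuration choice (see module docstring).
NAMED_ENVIRONMENTS: dict[str, Environment] = {
    "A": Environment(holes=(Rect.from_center(1.0, 1.0, 0.5, 0.5),), name="A"),
    "B": Environment(
        holes=(
            Rect.from_center(0.55, 1.0, 0.5, 0.5),
            Rect.from_center(1.45, 1.0, 0.5, 1.0),
        ),
        name="B",
    ),
    "C": Environment(
        holes=(
            Rect.from_center(1.0, 0.5, 1.8, 0.8),
            Rect.from_center(1.0, 1.5, 1.8, 0.8),
        ),
        name="C",
    ),
}


def make_environment(name_or_spec: str | dict) -> Environment:
    """Build a named scenario (``"A"``, ``"B"``, ``"C"``) or a custom arena.

    A custom spec is a mapping with keys ``width``, ``height`` and ``holes``
    (list of ``[x_min, y_min, x_max, y_max]``).  Overlapping or out-of-bounds
    holes raise ``ValueError``.
    """
    if isinstance(name_or_spec, str):
        key = name_or_spec.upper()
        if key not in NAMED_ENVIRONMENTS:
            raise ValueError(f"unknown environment {name_or_spec!r}; choose from {sorted(NAMED_ENVIRONMENTS)}")
        return NAMED_ENVIRONMENTS[key]
    return Environment.from_spec(dict(name_or_spec))


def is_accessible(env: Environment, x, y):
    """True where (x, y) lies inside the arena and outside every hole.

    Hole boundaries count as inaccessible (holes are closed sets).
    Vectorised: accepts scalars or arrays.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    ok = (x >= 0) & (x <= env.width) & (y >= 0) & (y <= env.height)
    for h in env.holes:
        ok &= ~h.contains(x, y, closed=True)
    if ok.ndim == 0:
        return bool(ok)
    return ok


def accessible_area_fraction(env: Environment) -> float:
    """Fraction of the arena area not occupied by holes."""
    return (env.area - sum(h.area for h in env.holes)) / env.area


@dataclass(frozen=True)
class SpatialBinning:
    """Square spatial bins over the arena; 3 cm bins by default.

    A bin is accessible iff its centre is accessible (consistent with the
    point-level accessibility predicate).
    """

    env: Environment
    bin_size: float = 0.03

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @property
    def nx(self) -> int:
        return int(np.ceil(self.env.width / self.bin_size))

    @property
    def ny(self) -> int:
        return int(np.ceil(self.env.height / self.bin_size))

    def bin_index(self, x, y):
        """Flat bin index for each point (clipped to the grid)."""
        ix = np.clip((np.asarray(x) / self.bin_size).astype(int), 0, self.nx - 1)
        iy = np.clip((np.asarray(y) / self.bin_size).astype(int), 0, self.ny - 1)
        return ix * self.ny + iy

    @property
    def accessible_mask(self) -> np.ndarray:
        """Boolean (nx*ny,) mask of bins whose centre is accessible."""
        ix, iy = np.meshgrid(np.arange(self.nx), np.arange(self.ny), indexing="ij")
        cx = (ix.ravel() + 0.5) * self.bin_size
        cy = (iy.ravel() + 0.5) * self.bin_size
        return np.asarray(is_accessible(self.env, cx, cy))

    @property
    def n_accessible(self) -> int:
        return int(self.accessible_mask.sum())

    def to_frame(self) -> pd.DataFrame:
        """Bin table: bin_ix, bin_iy, accessible."""
        ix, iy = np.meshgrid(np.arange(self.nx), np.arange(self.ny), indexing="ij")
        return pd.DataFrame(
            {"bin_ix": ix.ravel(), "bin_iy": iy.ravel(), "accessible": self.accessible_mask}
        )
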