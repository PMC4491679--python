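"""Static multileaf-collimator (MLC) leaf fitting to an aperture polygon.

A passively scattered proton field is collimated laterally by an aperture.
Replacing a custom-milled block with a static MLC approximates the aperture
outline with a bank of rectangular leaves of finite width (default 0.5 cm at
the collimator plane).  Leaf tip positions follow the midpoint rule: each
leaf's tip is placed where the horizontal line through the midpoint of the
leaf edge crosses the aperture outline, so the midpoint of each leaf end
lies exactly on the aperture line.  The finite leaf width produces a
"scalloped" field edge; :func:`aperture_area_error` quantifies it as the
area of the symmetric difference between the polygon and the fitted leaf
opening.

Coordinates are cm at the collimator/isocenter plane.  For a lateral field
the in-plane axes are the patient's anterior-posterior (y) and
inferior-superior (z) directions; the polygon's first coordinate is taken as
leaf travel and the second as the stacking axis by default, and
:func:`orientation_variants` fits both stackings for comparison.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Polygon, box

__all__ = [
    "AperturePolygon",
    "Leaf",
    "LeafBank",
    "OrientationComparison",
    "DEFAULT_LEAF_WIDTH_CM",
    "fit_leaf_positions",
    "aperture_area_error",
    "orientation_variants",
]

DEFAULT_LEAF_WIDTH_CM = 0.5

#: Tolerance below which a leaf-row sliver at the far end of the extent is
#: attributed to floating-point round-off rather than a real extra row.
_ROW_EPS = 1e-12


class ApertureError(ValueError):
    """Raised for degenerate polygons or invalid fitting parameters."""


@dataclass(frozen=True)
class AperturePolygon:
    """A closed, simple aperture outline at the collimator plane (cm).

    Vertices are ordered (either winding); closure between the last and
    first vertex is implied.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2:
            raise ApertureError(f"vertices must be an (N, 2) array, got shape {verts.shape}")
        if np.allclose(verts[0], verts[-1]) and len(verts) > 1:
            verts = verts[:-1]
        if len(verts) < 3:
            raise ApertureError("an aperture polygon needs at least three vertices")
        poly = Polygon(verts)
        if not poly.is_valid:
            raise ApertureError("aperture polygon is self-intersecting or otherwise invalid")
        if poly.area <= 0:
            raise ApertureError("aperture polygon has zero area")
        object.__setattr__(self, "vertices", verts)

    def to_shapely(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return self.to_shapely().area

    @classmethod
    def from_csv(cls, path) -> "AperturePolygon":
        """Read vertices from a CSV with columns ``x_cm,y_cm``."""
        frame = pd.read_csv(path)
        return cls(frame[["x_cm", "y_cm"]].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame(self.vertices, columns=["x_cm", "y_cm"]).to_csv(path, index=False)

    @classmethod
    def from_json(cls, path) -> "AperturePolygon":
        with open(path) as fh:
            return cls(np.asarray(json.load(fh)["vertices"]))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"vertices": self.vertices.tolist()}, fh)


class Leaf(NamedTuple):
    """One leaf pair: the row interval it blocks and its tip positions.

    Closed leaves carry ``nan`` tips.
    """

    row_min: float
    row_max: float
    left_tip: float
    right_tip: float
    open: bool


@dataclass(frozen=True)
class LeafBank:
    """A fitted bank of leaf pairs.

    ``orientation`` records which polygon coordinate the rows tile: ``"y"``
    stacks leaves along the second coordinate (tips travel along the first),
    ``"x"`` the converse.
    """

    leaf_width: float
    orientation: str
    leaves: tuple[Leaf, ...]

    def open_leaves(self) -> list[Leaf]:
        return [leaf for leaf in self.leaves if leaf.open]

    def opening(self) -> shapely.Geometry:
        """Union of the open-leaf rectangles, in polygon coordinates."""
        boxes = []
        for leaf in self.open_leaves():
            if self.orientation == "y":
                boxes.append(box(leaf.left_tip, leaf.row_min, leaf.right_tip, leaf.row_max))
            else:
                boxes.append(box(leaf.row_min, leaf.left_tip, leaf.row_max, leaf.right_tip))
        return shapely.union_all(boxes) if boxes else Polygon()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.leaves, columns=["row_min", "row_max", "left_tip", "right_tip", "open"]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def fit_leaf_positions(
    polygon: AperturePolygon,
    leaf_width: float = DEFAULT_LEAF_WIDTH_CM,
    orientation: str = "y",
    anchor: float | None = None,
) -> LeafBank:
    """Fit leaf-pair positions to an aperture using the midpoint rule.

    Rows of width ``leaf_width`` tile the polygon's extent along the stacking
    axis, anchored so the extent's lower bound coincides with a leaf boundary
    (pass ``anchor`` to register the leaf grid at boundaries
    ``anchor + k*leaf_width`` instead).  For each row, the horizontal line
    through the row midpoint is intersected with the polygon; the leaf tips
    are the outermost crossings (one leaf pair per row, so a non-convex lobe
    structure within a row is spanned by the open interval).  Rows whose
    midpoint line misses the polygon stay closed.
    """
    if leaf_width <= 0:
        raise ApertureError(f"leaf_width must be positive, got {leaf_width}")
    if orientation not in ("x", "y"):
        raise ApertureError(f"orientation must be 'x' or 'y', got {orientation!r}")

    poly = polygon.to_shapely()
    if orientation == "x":
        poly = shapely.transform(poly, lambda pts: pts[:, ::-1])
    minx, miny, maxx, maxy = poly.bounds

    if anchor is None:
        start = miny
    else:
        start = anchor + math.floor((miny - anchor) / leaf_width) * leaf_width
    n_rows = max(1, math.ceil((maxy - start) / leaf_width - _ROW_EPS))

    leaves = []
    pad = maxx - minx + 1.0
    for i in range(n_rows):
        row_min = start + i * leaf_width
        row_max = row_min + leaf_width
        mid = row_min + 0.5 * leaf_width
        chord = poly.intersection(LineString([(minx - pad, mid), (maxx + pad, mid)]))
        if chord.is_empty:
            leaves.append(Leaf(row_min, row_max, math.nan, math.nan, False))
        else:
            x0, _, x1, _ = chord.bounds
            leaves.append(Leaf(row_min, row_max, x0, x1, True))
    return LeafBank(leaf_width=leaf_width, orientation=orientation, leaves=tuple(leaves))


def aperture_area_error(polygon: AperturePolygon, bank: LeafBank) -> float:
    """Scalloping error: area (cm^2) of polygon XOR fitted leaf opening."""
    return polygon.to_shapely().symmetric_difference(bank.opening()).area


class OrientationComparison(NamedTuple):
    bank_y: LeafBank
    bank_x: LeafBank
    error_y: float
    error_x: float


def orientation_variants(
    polygon: AperturePolygon, leaf_width: float = DEFAULT_LEAF_WIDTH_CM
) -> OrientationComparison:
    """Fit the bank with each of the two in-plane stacking axes.

    Returns both fits and their scalloping areas; which orientation is
    preferable depends on the aperture shape and is left to the caller.
    """
    bank_y = fit_leaf_positions(polygon, leaf_width, orientation="y")
    bank_x = fit_leaf_positions(polygon, leaf_width, orientation="x")
    return OrientationComparison(
        bank_y=bank_y,
        bank_x=bank_x,
        error_y=aperture_area_error(polygon, bank_y),
        error_x=aperture_area_error(polygon, bank_x),
    )
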