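"""Analytic description of the planar model geometry.

Coordinate frame: the migration axis is +x, the pore entrance plane is
x = 0, and the channel axis is y = 0.  Tissue 1 sits above the channel,
tissue 2 below.  The cell (disk + annular membrane, with a concentric
nuclear disk + annular membrane) starts to the left of the entrance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon, box

from squeezefem.config import GeometryParams

PART_NAMES = ("cell_membrane", "cytoplasm", "nuclear_membrane", "nucleus", "tissue1", "tissue2")
PART_IDS = {name: i for i, name in enumerate(PART_NAMES)}


class GeometryError(ValueError):
    pass


@dataclass
class Regions:
    """Closed planar regions for the six parts plus analytic areas."""

    params: GeometryParams
    cell_center: tuple[float, float]
    radii: dict[str, float]  # nucleus_inner, nucleus_outer, cell_inner, cell_outer
    tissue1_box: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    tissue2_box: tuple[float, float, float, float]
    polygons: dict[str, Polygon] = field(default_factory=dict)

    @property
    def analytic_areas(self) -> dict[str, float]:
        r = self.radii
        g = self.params
        w = g.tissue_block_width * g.tissue_block_height
        return {
            "nucleus": np.pi * r["nucleus_inner"] ** 2,
            "nuclear_membrane": np.pi * (r["nucleus_outer"] ** 2 - r["nucleus_inner"] ** 2),
            "cytoplasm": np.pi * (r["cell_inner"] ** 2 - r["nucleus_outer"] ** 2),
            "cell_membrane": np.pi * (r["cell_outer"] ** 2 - r["cell_inner"] ** 2),
            "tissue1": w,
            "tissue2": w,
        }


def build_geometry(g: GeometryParams) -> Regions:
    """Construct the six closed part regions from validated parameters.

    Raises :class:`GeometryError` if the cell would interpenetrate the
    tissue blocks at rest.
    """
    t = g.membrane_thickness
    r_cell = g.cell_diameter / 2.0
    r_nuc = g.nucleus_diameter / 2.0
    gap = g.pore_diameter / 2.0

    cx = -(r_cell + g.initial_standoff)
    center = (cx, 0.0)
    radii = {
        "nucleus_inner": r_nuc - t,
        "nucleus_outer": r_nuc,
        "cell_inner": r_cell - t,
        "cell_outer": r_cell,
    }

    t1 = (0.0, gap, g.tissue_block_width, gap + g.tissue_block_height)
    t2 = (0.0, -gap - g.tissue_block_height, g.tissue_block_width, -gap)

    circ = Point(center).buffer(r_cell, quad_segs=256)
    tissue1 = box(*t1)
    tissue2 = box(*t2)
    if circ.intersects(tissue1) or circ.intersects(tissue2):
        raise GeometryError("cell overlaps the tissue blocks at rest; increase initial_standoff")

    polys = {
        "nucleus": Point(center).buffer(radii["nucleus_inner"], quad_segs=256),
        "nuclear_membrane": Point(center).buffer(r_nuc, quad_segs=256).difference(
            Point(center).buffer(radii["nucleus_inner"], quad_segs=256)
        ),
        "cytoplasm": Point(center).buffer(radii["cell_inner"], quad_segs=256).difference(
            Point(center).buffer(r_nuc, quad_segs=256)
        ),
        "cell_membrane": circ.difference(Point(center).buffer(radii["cell_inner"], quad_segs=256)),
        "tissue1": tissue1,
        "tissue2": tissue2,
    }
    return Regions(params=g, cell_center=center, radii=radii, tissue1_box=t1, tissue2_box=t2, polygons=polys)
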