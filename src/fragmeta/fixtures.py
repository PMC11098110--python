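"""Deterministic tiny fixtures for tests and demos.

Writes three named landscape masks with hand-computable covers, a canned
population on the checkerboard, and a JSON manifest of derived quantities
(covers, per-site occupancy/abundance at m=2) that were worked out by hand
and can be recomputed from the files on load.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .dynamics import Population
from .landscape import Landscape, write_mask
from .random_fields import TorusGrid

__all__ = ["make_fixtures", "checkerboard", "two_patch", "single_square", "canned_population"]


def checkerboard(L: int = 4) -> Landscape:
    """Habitat on cells with even (row + col); cover exactly 1/2."""
    i, j = np.indices((L, L))
    return Landscape(TorusGrid(L), (i + j) % 2 == 0, {"type": "checkerboard", "L": L})


def two_patch(L: int = 6) -> Landscape:
    """Two 2x2 habitat patches at (0,0) and (3,3); cover 8/36."""
    mask = np.zeros((L, L), dtype=bool)
    mask[0:2, 0:2] = True
    mask[3:5, 3:5] = True
    return Landscape(TorusGrid(L), mask, {"type": "two_patch", "L": L})


def single_square(L: int = 8) -> Landscape:
    """One 3x3 habitat block at (2,2); cover 9/64."""
    mask = np.zeros((L, L), dtype=bool)
    mask[2:5, 2:5] = True
    return Landscape(TorusGrid(L), mask, {"type": "single_square", "L": L})


def canned_population() -> Population:
    """Three individuals on the 4x4 checkerboard with known site statistics.

    At m=2: site (0,0) has habitat cells (0,0),(1,1) both occupied
    (occupancy 1, abundance 1); site (0,1) has habitat cells (0,2),(1,3)
    with one occupant (occupancy 1/2, abundance 1/2); the bottom sites are
    empty.
    """
    return Population(np.array([[0.5, 0.5], [1.5, 1.5], [0.5, 2.5]]))


# Hand-computed oracle values for the fixtures above.
_MANIFEST = {
    "checkerboard_4x4": {"L": 4, "cover": 0.5, "n_habitat": 8},
    "two_patch_6x6": {"L": 6, "cover": 8 / 36, "n_habitat": 8},
    "single_square_8x8": {"L": 8, "cover": 9 / 64, "n_habitat": 9},
    "population_checkerboard": {
        "n": 3,
        "m": 2,
        "site_occupancy": [1.0, 0.5, 0.0, 0.0],
        "site_abundance": [1.0, 0.5, 0.0, 0.0],
    },
}

_BUILDERS = {
    "checkerboard_4x4": checkerboard,
    "two_patch_6x6": two_patch,
    "single_square_8x8": single_square,
}


def make_fixtures(out_dir) -> dict:
    """Write the fixture masks, population and manifest; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, builder in _BUILDERS.items():
        write_mask(builder(), out / f"{name}.txt")
    pop = canned_population()
    lines = ["id,x,y"] + [
        f"{i},{x},{y}" for i, (x, y) in enumerate(pop.positions)
    ]
    (out / "population_checkerboard.csv").write_text("\n".join(lines) + "\n")
    (out / "manifest.json").write_text(json.dumps(_MANIFEST, indent=2) + "\n")
    return _MANIFEST
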