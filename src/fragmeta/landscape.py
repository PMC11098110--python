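"""Landscape construction, transformation and plain-text mask I/O.

Four landscape classes are supported: homogeneous (all habitat), fragmented
(thresholded Gaussian random field), regular grids of identical square
patches, and arbitrary masks read from file.  Two transformations derive the
experimental landscapes: ``subsample`` cuts a square window and re-imposes
periodic boundaries on it, and ``aggregate`` collects all habitat cells into
one compact square block (same total habitat, different configuration) for
fragmentation-per-se comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .random_fields import INF, CovarianceSpec, TorusGrid, grf_sample, torus_distance

__all__ = [
    "Landscape",
    "make_homogeneous",
    "make_fragmented",
    "make_regular_grid",
    "subsample",
    "aggregate",
    "habitat_cover",
    "write_mask",
    "read_mask",
]


@dataclass(frozen=True)
class Landscape:
    """Boolean habitat mask on an L x L torus.

    ``mask[i, j]`` is True where the cell is habitat; everything else is
    hostile matrix.  ``provenance`` records how the landscape was built so
    that result files can cite it.
    """

    grid: TorusGrid
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != (self.grid.L, self.grid.L):
            raise ValueError(
                f"mask shape {mask.shape} does not match grid side {self.grid.L}"
            )
        mask.setflags(write=False)
        object.__setattr__(self, "mask", mask)

    @property
    def L(self) -> int:
        return self.grid.L

    @property
    def n_habitat(self) -> int:
        return int(self.mask.sum())

    @property
    def cover(self) -> float:
        return self.n_habitat / self.grid.n_cells

    def habitat_cells(self) -> np.ndarray:
        """(H, 2) array of (row, col) indices of habitat cells."""
        return np.argwhere(self.mask)


def make_homogeneous(L: int) -> Landscape:
    """Landscape that is habitat everywhere (cover 1)."""
    grid = TorusGrid(L)
    return Landscape(grid, np.ones((L, L), dtype=bool), {"type": "homogeneous", "L": L})


def make_fragmented(
    L: int,
    alpha_e: float,
    threshold: float,
    rng: np.random.Generator,
    *,
    direction: str = ">",
) -> Landscape:
    """Fragmented landscape by thresholding a unit-variance GRF.

    A zero-mean, unit-variance Gaussian random field with exponential
    covariance of scale ``alpha_e`` is sampled on the torus and a cell is
    habitat where the field exceeds ``threshold`` (expected cover
    1 - Phi(threshold)).  ``direction`` may be set to "<" for the opposite
    convention.
    """
    if direction not in (">", "<"):
        raise ValueError(f"direction must be '>' or '<', got {direction!r}")
    grid = TorusGrid(L)
    eps = grf_sample(CovarianceSpec(scale=alpha_e, variance=1.0), grid, rng)
    mask = eps > threshold if direction == ">" else eps < threshold
    prov = {
        "type": "fragmented",
        "L": L,
        "alpha_e": alpha_e,
        "threshold": threshold,
        "direction": direction,
    }
    return Landscape(grid, mask, prov)


def make_regular_grid(L: int, patch_side: int, spacing: int) -> Landscape:
    """Regular grid of identical square patches with equal nearest-neighbor
    distances on the torus.

    One ``patch_side`` x ``patch_side`` patch sits in every
    ``spacing`` x ``spacing`` block, so cover is (patch_side/spacing)^2.
    ``spacing`` must divide ``L`` (otherwise wrap-around would break the
    equidistance of the patch lattice).
    """
    if L % spacing != 0:
        raise ValueError(f"spacing {spacing} must divide L {L}")
    if not (1 <= patch_side <= spacing):
        raise ValueError(f"patch_side must be in [1, spacing], got {patch_side}")
    tile = np.zeros((spacing, spacing), dtype=bool)
    tile[:patch_side, :patch_side] = True
    mask = np.tile(tile, (L // spacing, L // spacing))
    prov = {"type": "regular_grid", "L": L, "patch_side": patch_side, "spacing": spacing}
    return Landscape(TorusGrid(L), mask, prov)


def subsample(landscape: Landscape, size: int, rng: np.random.Generator) -> Landscape:
    """Random square window of the landscape, returned as a fresh torus.

    The window offset is uniform and may wrap around the source torus;
    the result's own periodic boundary is then reset to the window edges.
    """
    L = landscape.L
    if not (2 <= size <= L):
        raise ValueError(f"subsample size must be in [2, L], got {size}")
    r0, c0 = rng.integers(0, L, size=2)
    rows = (np.arange(size) + r0) % L
    cols = (np.arange(size) + c0) % L
    window = landscape.mask[np.ix_(rows, cols)]
    prov = {
        "type": "subsample",
        "parent": landscape.provenance.get("type", "unknown"),
        "size": size,
        "offset": (int(r0), int(c0)),
    }
    return Landscape(TorusGrid(size), window, prov)


def aggregate(landscape: Landscape) -> Landscape:
    """Collect all habitat into one compact square block (same total area).

    The H habitat cells are re-packed row-major into a block of side
    ceil(sqrt(H)) anchored at cell (0, 0); the last row may be partial.
    Idempotent up to the canonical packing; cover is preserved exactly.
    """
    L = landscape.L
    H = landscape.n_habitat
    mask = np.zeros((L, L), dtype=bool)
    if H:
        side = int(np.ceil(np.sqrt(H)))
        full_rows, rem = divmod(H, side)
        mask[:full_rows, :side] = True
        if rem:
            mask[full_rows, :rem] = True
    prov = dict(landscape.provenance)
    prov["aggregated"] = True
    return Landscape(landscape.grid, mask, prov)


def habitat_cover(landscape: Landscape) -> float:
    """Proportion of cells that are habitat."""
    return landscape.cover


def nearest_neighbor_patch_distance(landscape: Landscape) -> np.ndarray:
    """Torus distances from each habitat cell center to its nearest habitat
    neighbor (diagnostic helper; O(H^2))."""
    cells = landscape.habitat_cells().astype(float) + 0.5
    d = torus_distance(cells[:, None, :], cells[None, :, :], landscape.grid)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


# ---------------------------------------------------------------------------
# Plain-text mask I/O: rows of '0'/'1', optional '#'-prefixed provenance.


def write_mask(landscape: Landscape, path) -> None:
    lines = [f"# L: {landscape.L}"]
    for key, value in landscape.provenance.items():
        lines.append(f"# {key}: {value}")
    for row in landscape.mask.astype(int):
        lines.append("".join(map(str, row)))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_mask(path) -> Landscape:
    provenance: dict = {}
    rows: list[list[int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    provenance[key.strip()] = value.strip()
                continue
            if set(line) - {"0", "1"}:
                raise ValueError(f"invalid mask row {line!r}")
            rows.append([int(ch) for ch in line])
    if not rows:
        raise ValueError(f"no mask rows found in {path}")
    mask = np.array(rows, dtype=bool)
    if mask.shape[0] != mask.shape[1]:
        raise ValueError(f"mask must be square, got shape {mask.shape}")
    provenance.pop("L", None)
    if not provenance:
        warnings.warn(f"mask file {path} carries no provenance header")
    return Landscape(TorusGrid(mask.shape[0]), mask, provenance)
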