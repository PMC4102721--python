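"""Multidimensional pooling designs for gridded clone libraries.

A library of ``n_plates x rows x cols`` coordinates is screened through
seven pooling dimensions.  Each dimension partitions every coordinate into
exactly one pool, so a clone is identified by the intersection of its seven
positive pools (group testing).  The default design uses the three base-6
digits of the plate index (6+6+6 pools), the row (16), the column (24), a
diagonal pool ``(plate + well) mod q`` and one pool per plate (216), i.e.
294 + q pools for the 82,944-coordinate default library.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Sequence, Tuple

import numpy as np


@dataclass(frozen=True)
class LibraryCoordinate:
    """A clone's (plate, row, column) address on the gridded library."""

    plate: int
    row: int
    col: int

    def linear_index(self, rows: int, cols: int) -> int:
        return ((self.plate * rows) + self.row) * cols + self.col

    @staticmethod
    def from_linear(index: int, rows: int, cols: int) -> "LibraryCoordinate":
        plate, rest = divmod(index, rows * cols)
        row, col = divmod(rest, cols)
        return LibraryCoordinate(plate, row, col)


@dataclass(frozen=True)
class DimensionSpec:
    """One screening dimension: a total map coordinate -> local pool id."""

    name: str
    n_pools: int
    assign: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]


class PoolingDesign:
    """Assignment of every library coordinate to one pool per dimension.

    Attributes
    ----------
    membership : (library_size, n_dims) int array
        Global pool index of each coordinate in each dimension.
    pool_labels : list of str
        Human-readable pool names, indexed by global pool id.
    """

    def __init__(self, n_plates: int, rows: int, cols: int,
                 dimensions: Sequence[DimensionSpec]):
        self.n_plates = n_plates
        self.rows = rows
        self.cols = cols
        self.library_size = n_plates * rows * cols
        self.dimensions = list(dimensions)
        self.n_dims = len(self.dimensions)

        idx = np.arange(self.library_size)
        plate, rest = np.divmod(idx, rows * cols)
        row, col = np.divmod(rest, cols)

        offsets = []
        off = 0
        cols_mem = []
        for d, dim in enumerate(self.dimensions):
            local = np.asarray(dim.assign(plate, row, col), dtype=np.int64)
            if local.shape != idx.shape:
                raise ValueError(
                    f"dimension '{dim.name}' does not assign every "
                    "coordinate to a pool")
            if local.size and (local.min() < 0 or local.max() >= dim.n_pools):
                raise ValueError(
                    f"dimension '{dim.name}' assigns pools outside "
                    f"[0, {dim.n_pools}) and does not partition the library")
            offsets.append(off)
            cols_mem.append(local + off)
            off += dim.n_pools
        self.dim_offsets = offsets
        self.n_pools = off
        self.membership = (np.stack(cols_mem, axis=1)
                           if cols_mem else np.empty((self.library_size, 0),
                                                     dtype=np.int64))
        self.pool_labels: List[str] = []
        for dim in self.dimensions:
            self.pool_labels.extend(
                f"{dim.name}-{i:03d}" for i in range(dim.n_pools))

    def pools_of(self, coord: LibraryCoordinate) -> Tuple[int, ...]:
        """The seven (one per dimension) global pool ids of a coordinate."""
        if not (0 <= coord.plate < self.n_plates
                and 0 <= coord.row < self.rows
                and 0 <= coord.col < self.cols):
            raise ValueError(f"coordinate {coord} outside the library grid")
        li = coord.linear_index(self.rows, self.cols)
        return tuple(int(p) for p in self.membership[li])

    def pools_of_scalar(self, plate: int, row: int, col: int) -> Tuple[int, ...]:
        """Arithmetic (membership-matrix-free) pool computation.

        Used by the exhaustive decoding oracle so that it does not share
        the precomputed membership table with the optimised decoder.
        """
        out = []
        p = np.asarray([plate]); r = np.asarray([row]); c = np.asarray([col])
        for off, dim in zip(self.dim_offsets, self.dimensions):
            out.append(int(dim.assign(p, r, c)[0]) + off)
        return tuple(out)

    def pool_sizes(self) -> np.ndarray:
        return np.bincount(self.membership.ravel(), minlength=self.n_pools)

    def dim_of_pool(self, pool: int) -> str:
        for off, dim in zip(self.dim_offsets, self.dimensions):
            if off <= pool < off + dim.n_pools:
                return dim.name
        raise ValueError(f"unknown pool id {pool}")


def build_pooling_design(n_plates: int, rows: int, cols: int,
                         diagonal_modulus: int = 23) -> PoolingDesign:
    """The default seven-dimension design.

    Dimensions 1-3 are the base-6 digits of the plate index, dimension 4
    the row, dimension 5 the column, dimension 6 a diagonal
    ``(plate + well) mod q`` and dimension 7 one pool per plate.
    """
    if n_plates > 216:
        raise ValueError("default design encodes the plate index in three "
                         "base-6 digits; n_plates must be <= 216")
    q = diagonal_modulus
    wells = rows * cols
    dims = [
        DimensionSpec("D1", 6, lambda p, r, c: (p // 36) % 6),
        DimensionSpec("D2", 6, lambda p, r, c: (p // 6) % 6),
        DimensionSpec("D3", 6, lambda p, r, c: p % 6),
        DimensionSpec("ROW", rows, lambda p, r, c: r),
        DimensionSpec("COL", cols, lambda p, r, c: c),
        DimensionSpec("DIAG", q,
                      lambda p, r, c: (p + r * cols + c) % q),
        DimensionSpec("PLATE", n_plates, lambda p, r, c: p),
    ]
    del wells
    return PoolingDesign(n_plates, rows, cols, dims)
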