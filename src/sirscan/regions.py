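"""Synthetic study regions: centroids, adjacency, population weights.

A :class:`RegionSet` stands in for the administrative units of a screening
study area (municipalities): each region has an integer id, a planar centroid
in km, a share of the cohort population, and a symmetric adjacency relation
used by the spatial scan statistic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from ._rng import substream
from .errors import InvalidArgumentError

__all__ = [
    "RegionSet",
    "generate_regions",
    "read_gal",
    "write_gal",
    "read_edge_list",
    "write_edge_list",
]


@dataclass
class RegionSet:
    """Regions with centroids (km), adjacency and population weights.

    ``adjacency`` maps each region id to a sorted tuple of neighbour ids; the
    relation is symmetric and irreflexive and the region graph is connected.
    ``population_weight`` sums to 1 and gives each region's share of subjects.
    """

    region_ids: np.ndarray
    centroids: np.ndarray  # (n, 2), km
    adjacency: dict[int, tuple[int, ...]]
    population_weight: np.ndarray
    _index: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.population_weight = np.asarray(self.population_weight, dtype=float)
        self._index = {int(r): i for i, r in enumerate(self.region_ids)}
        self.validate()

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def index_of(self, region_id: int) -> int:
        return self._index[int(region_id)]

    def validate(self) -> None:
        n = self.n_regions
        if n < 2:
            raise InvalidArgumentError("a RegionSet needs at least 2 regions")
        if self.centroids.shape != (n, 2):
            raise InvalidArgumentError("centroids must be (n_regions, 2)")
        for rid, nbrs in self.adjacency.items():
            if rid in nbrs:
                raise InvalidArgumentError(f"region {rid} is its own neighbour")
            for nb in nbrs:
                if rid not in self.adjacency.get(nb, ()):
                    raise InvalidArgumentError("adjacency is not symmetric")
        if not np.isclose(self.population_weight.sum(), 1.0):
            raise InvalidArgumentError("population weights must sum to 1")
        if np.any(self.population_weight < 0):
            raise InvalidArgumentError("population weights must be nonnegative")
        # empty adjacency means "not supplied"; only the spatial scan needs it
        if self.adjacency:
            n_comp, _ = connected_components(self.adjacency_matrix(),
                                             directed=False)
            if n_comp != 1:
                raise InvalidArgumentError("region graph must be connected")

    def adjacency_matrix(self) -> csr_matrix:
        """Symmetric 0/1 adjacency in region-index order."""
        rows, cols = [], []
        for rid, nbrs in self.adjacency.items():
            i = self.index_of(rid)
            for nb in nbrs:
                rows.append(i)
                cols.append(self.index_of(nb))
        data = np.ones(len(rows), dtype=np.int8)
        return csr_matrix((data, (rows, cols)), shape=(self.n_regions,) * 2)

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean centroid distances (km)."""
        d = self.centroids[:, None, :] - self.centroids[None, :, :]
        return np.sqrt((d**2).sum(axis=2))

    # ---- I/O -------------------------------------------------------------

    def write_csv(self, centroid_path: str | Path, edges_path: str | Path) -> None:
        with open(centroid_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["region_id", "x_km", "y_km", "population_weight"])
            for i, rid in enumerate(self.region_ids):
                w.writerow(
                    [int(rid), self.centroids[i, 0], self.centroids[i, 1],
                     self.population_weight[i]]
                )
        write_edge_list(self.adjacency, edges_path)


def _grid_layout(n_regions: int, spacing_km: float = 10.0):
    side = int(np.ceil(np.sqrt(n_regions)))
    coords = []
    for r in range(n_regions):
        coords.append(((r % side) * spacing_km, (r // side) * spacing_km))
    coords = np.asarray(coords, dtype=float)
    adjacency: dict[int, set[int]] = {i: set() for i in range(n_regions)}
    for r in range(n_regions):
        row, col = divmod(r, side)
        for dr, dc in ((0, 1), (1, 0)):
            rr, cc = row + dr, col + dc
            nb = rr * side + cc
            if cc < side and nb < n_regions and rr < side:
                adjacency[r].add(nb)
                adjacency[nb].add(r)
    return coords, adjacency


def _delaunay_layout(n_regions: int, rng: np.random.Generator, extent_km: float):
    # rejection-free: Delaunay of points in general position is connected
    coords = rng.uniform(0.0, extent_km, size=(n_regions, 2))
    # nudge until no duplicate points (vanishing probability, but be safe)
    while len(np.unique(coords, axis=0)) < n_regions:  # pragma: no cover
        coords += rng.normal(scale=1e-6, size=coords.shape)
    tri = Delaunay(coords)
    adjacency: dict[int, set[int]] = {i: set() for i in range(n_regions)}
    for simplex in tri.simplices:
        for a in simplex:
            for b in simplex:
                if a != b:
                    adjacency[int(a)].add(int(b))
    return coords, adjacency


def generate_regions(
    n_regions: int,
    seed: int,
    layout: str = "random-planar",
    extent_km: float = 100.0,
) -> RegionSet:
    """Generate a connected synthetic region set.

    ``layout="grid"`` places regions on a square lattice with rook adjacency
    (10 km spacing); ``layout="random-planar"`` scatters centroids uniformly
    in a square of side ``extent_km`` and takes Delaunay-triangulation
    adjacency, giving an irregular but connected planar graph. Population
    weights are drawn log-normally (heterogeneous region sizes, as for real
    municipalities) and normalised. Deterministic for a fixed seed.
    """
    if n_regions < 2:
        raise InvalidArgumentError("n_regions must be >= 2")
    rng = substream(seed, "regions")
    if layout == "grid":
        coords, adjacency = _grid_layout(n_regions)
    elif layout == "random-planar":
        coords, adjacency = _delaunay_layout(n_regions, rng, extent_km)
    else:
        raise InvalidArgumentError(f"unknown layout {layout!r}")
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=n_regions)
    weights /= weights.sum()
    adj = {i: tuple(sorted(v)) for i, v in adjacency.items()}
    return RegionSet(
        region_ids=np.arange(n_regions),
        centroids=coords,
        adjacency=adj,
        population_weight=weights,
    )


# ---- adjacency file formats ---------------------------------------------


def write_edge_list(adjacency: dict[int, tuple[int, ...]], path: str | Path) -> None:
    """Write undirected edges once each as a two-column CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["region_a", "region_b"])
        for a in sorted(adjacency):
            for b in adjacency[a]:
                if a < b:
                    w.writerow([a, b])


def read_edge_list(path: str | Path) -> dict[int, tuple[int, ...]]:
    adjacency: dict[int, set[int]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header and header[0].strip().isdigit():  # headerless file
            fh.seek(0)
            reader = csv.reader(fh)
        for row in reader:
            if not row:
                continue
            a, b = int(row[0]), int(row[1])
            adjacency.setdefault(a, set()).add(b)
            adjacency.setdefault(b, set()).add(a)
    return {k: tuple(sorted(v)) for k, v in adjacency.items()}


def write_gal(adjacency: dict[int, tuple[int, ...]], path: str | Path) -> None:
    """Write adjacency in GAL spatial-weights format (header: n, then
    id/degree lines alternating with neighbour lines)."""
    with open(path, "w") as fh:
        fh.write(f"{len(adjacency)}\n")
        for rid in sorted(adjacency):
            nbrs = adjacency[rid]
            fh.write(f"{rid} {len(nbrs)}\n")
            fh.write(" ".join(str(n) for n in nbrs) + "\n")


def read_gal(path: str | Path) -> dict[int, tuple[int, ...]]:
    with open(path) as fh:
        tokens_lines = [ln.split() for ln in fh if ln.strip()]
    header = tokens_lines[0]
    # GAL headers are "n" or "0 n shapefile field"; the count is the sole or
    # second token
    n = int(header[0]) if len(header) == 1 else int(header[1])
    adjacency: dict[int, tuple[int, ...]] = {}
    i = 1
    for _ in range(n):
        rid, deg = int(tokens_lines[i][0]), int(tokens_lines[i][1])
        if deg:
            nbrs = tuple(sorted(int(t) for t in tokens_lines[i + 1]))
            if len(nbrs) != deg:
                raise InvalidArgumentError(f"GAL degree mismatch for region {rid}")
            i += 2
        else:
            nbrs = ()
            i += 1
        adjacency[rid] = nbrs
    return adjacency
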