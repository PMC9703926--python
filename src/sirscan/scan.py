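"""Flexibly shaped spatial scan statistic with Monte Carlo inference.

Candidate zones are connected sets of regions: for every starting region i,
all connected subsets of size <= K drawn from i plus its K-1 nearest
neighbouring regions (centroid distance) that contain i. Each zone Z is
scored with the Poisson likelihood ratio comparing risk inside and outside,

    llr(Z) = o_Z log(o_Z/e_Z) + (O - o_Z) log((O - o_Z)/(E - e_Z))
             - O log(O/E)        if o_Z/e_Z > (O - o_Z)/(E - e_Z), else 0,

and the zone maximising llr is the *most likely cluster*. Because the test
statistic is the maximum over all zones, a single Monte Carlo reference
distribution (total cases redistributed multinomially in proportion to the
expected counts) gives a multiplicity-honest p-value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from ._rng import substream
from .errors import InvalidArgumentError, NoCasesError
from .survival import RegionTable

__all__ = ["Zone", "ScanResult", "enumerate_zones", "zone_llr", "run_flexscan"]

DEFAULT_MAX_ZONE_SIZE = 15


@dataclass(frozen=True)
class Zone:
    """A connected candidate cluster with its counts and likelihood ratio."""

    region_ids: tuple[int, ...]
    observed: float
    expected: float
    llr: float

    @property
    def relative_risk(self) -> float:
        return self.observed / self.expected

    def to_dict(self) -> dict:
        return {
            "region_ids": list(self.region_ids),
            "observed": self.observed,
            "expected": self.expected,
            "relative_risk": self.relative_risk,
            "llr": self.llr,
        }


@dataclass
class ScanResult:
    """Most likely cluster, secondary clusters and Monte Carlo p-value."""

    most_likely: Zone
    p_value: float
    secondary: list[Zone]
    n_replicates: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "most_likely_cluster": self.most_likely.to_dict(),
            "p_value": self.p_value,
            "secondary_clusters": [z.to_dict() for z in self.secondary],
            "n_replicates": self.n_replicates,
            "seed": self.seed,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _candidate_sets(regions: RegionTable, K: int) -> list[np.ndarray]:
    """Per start region: itself plus its K-1 nearest regions (ties by id)."""
    D = regions.distance_matrix()
    n = D.shape[0]
    cands = []
    for i in range(n):
        order = np.lexsort((np.arange(n), D[i]))  # distance, then region index
        cands.append(order[:K])
    return cands


def _connected_subsets_containing(
    root: int, candidate: set[int], adjacency: dict[int, set[int]], K: int
):
    """Yield all connected subsets of `candidate` containing `root`, |S| <= K.

    Classic grow-only enumeration: each subset is extended by neighbours with
    index greater than the excluded frontier, so every subset is produced
    exactly once per root.
    """
    results = []

    def grow(current: frozenset, frontier: set[int], forbidden: set[int]):
        results.append(current)
        if len(current) == K:
            return
        frontier = sorted(frontier)
        banned = set(forbidden)
        for v in frontier:
            new_frontier = {
                w
                for u in (current | {v})
                for w in adjacency.get(u, ())
                if w in candidate and w not in current and w != v
                and w not in banned
            }
            grow(current | {v}, new_frontier, banned)
            banned.add(v)

    start_frontier = {
        w for w in adjacency.get(root, ()) if w in candidate
    }
    grow(frozenset([root]), start_frontier, set())
    return results


def enumerate_zones(regions: RegionTable, K: int = DEFAULT_MAX_ZONE_SIZE):
    """Enumerate candidate zones as sorted tuples of region *indices*.

    For each region i, connected subsets (size <= K) of {i} union the K-1
    regions nearest to i that contain i; duplicates across starting regions
    are removed. Region ids are mapped to row indices of the region table.
    """
    if K < 1:
        raise InvalidArgumentError("K must be >= 1")
    ids = regions.region_ids
    id_to_idx = {int(r): i for i, r in enumerate(ids)}
    adjacency = {
        id_to_idx[r]: {id_to_idx[n] for n in nbrs if int(n) in id_to_idx}
        for r, nbrs in regions.adjacency.items()
        if int(r) in id_to_idx
    }
    seen: set[frozenset] = set()
    zones: list[tuple[int, ...]] = []
    for i, cand in enumerate(_candidate_sets(regions, K)):
        cand_set = set(int(c) for c in cand)
        for sub in _connected_subsets_containing(i, cand_set, adjacency, K):
            if sub not in seen:
                seen.add(sub)
                zones.append(tuple(sorted(sub)))
    zones.sort()
    return zones


def zone_llr(o_z: float, e_z: float, O_total: float, E_total: float) -> float:
    """Poisson likelihood-ratio score of one zone (0 unless risk is elevated)."""
    if e_z <= 0 or e_z >= E_total:
        raise InvalidArgumentError("need 0 < e_Z < E_total")
    if not 0 <= o_z <= O_total:
        raise InvalidArgumentError("need 0 <= o_Z <= O_total")
    o_out = O_total - o_z
    e_out = E_total - e_z
    inside = o_z / e_z
    outside = o_out / e_out
    if inside <= outside:
        return 0.0
    term_in = o_z * np.log(o_z / e_z) if o_z > 0 else 0.0
    term_out = o_out * np.log(o_out / e_out) if o_out > 0 else 0.0
    base = O_total * np.log(O_total / E_total)
    return float(term_in + term_out - base)


def _llr_matrix(OZ: np.ndarray, e_z: np.ndarray, O: float, E: float) -> np.ndarray:
    """Vectorised llr for zone-count matrix OZ (n_zones x n_datasets)."""
    e_z = e_z[:, None]
    o_out = O - OZ
    e_out = E - e_z
    with np.errstate(divide="ignore", invalid="ignore"):
        term_in = np.where(OZ > 0, OZ * np.log(OZ / e_z), 0.0)
        term_out = np.where(o_out > 0, o_out * np.log(o_out / e_out), 0.0)
    llr = term_in + term_out - O * np.log(O / E)
    elevated = OZ * e_out > o_out * e_z  # o_z/e_z > o_out/e_out without division
    return np.where(elevated, llr, 0.0)


def _zone_matrix(zones, n_regions: int) -> sparse.csr_matrix:
    rows, cols = [], []
    for zi, z in enumerate(zones):
        rows.extend([zi] * len(z))
        cols.extend(z)
    data = np.ones(len(rows), dtype=np.float64)
    return sparse.csr_matrix((data, (rows, cols)), shape=(len(zones), n_regions))


def run_flexscan(
    regions: RegionTable,
    K: int = DEFAULT_MAX_ZONE_SIZE,
    R: int = 999,
    seed: int = 0,
    zones=None,
    max_secondary: int = 5,
    chunk: int = 64,
) -> ScanResult:
    """Scan for the most likely cluster and assess it by Monte Carlo.

    Null replicates redistribute the observed case total over regions
    multinomially with probabilities e_i / sum(e), conditioning on the total;
    p = (1 + #{replicate max llr >= observed}) / (R + 1). Regions with zero
    expected count are dropped before scanning. ``zones`` may carry a
    precomputed :func:`enumerate_zones` result for the same region table.
    """
    regions = regions.analysed()
    o = regions.observed
    e = regions.expected
    O = float(o.sum())
    E = float(e.sum())
    if O < 1:
        raise NoCasesError("no observed cases; nothing to scan")
    if zones is None:
        zones = enumerate_zones(regions, K)
    M = _zone_matrix(zones, len(o))
    e_z = M @ e
    # guard: a zone holding every analysed region has no outside — drop it
    valid = e_z < E
    obs_llr_all = _llr_matrix((M @ o)[valid][:, None], e_z[valid], O, E)[:, 0]
    order = np.argsort(obs_llr_all)[::-1]
    valid_zones = [z for z, v in zip(zones, valid) if v]

    best_idx = order[0]
    observed_stat = float(obs_llr_all[best_idx])

    ids = regions.region_ids

    def make_zone(zidx: int) -> Zone:
        z = valid_zones[zidx]
        oz = float(sum(o[list(z)]))
        ez = float(sum(e[list(z)]))
        return Zone(
            region_ids=tuple(int(ids[i]) for i in z),
            observed=oz,
            expected=ez,
            llr=float(obs_llr_all[zidx]),
        )

    most_likely = make_zone(best_idx)

    # greedy non-overlapping secondary clusters by descending llr
    secondary: list[Zone] = []
    taken = set(valid_zones[best_idx])
    for zidx in order[1:]:
        if obs_llr_all[zidx] <= 0 or len(secondary) >= max_secondary:
            break
        z = valid_zones[zidx]
        if taken.isdisjoint(z):
            secondary.append(make_zone(zidx))
            taken.update(z)

    # Monte Carlo under the homogeneous-risk null
    rng = substream(seed, "flexscan")
    Mv = M[valid]
    e_zv = e_z[valid]
    exceed = 0
    done = 0
    while done < R:
        b = min(chunk, R - done)
        null_counts = rng.multinomial(int(round(O)), e / E, size=b).T.astype(float)
        OZ = Mv @ null_counts
        null_max = _llr_matrix(OZ, e_zv, O, E).max(axis=0)
        exceed += int((null_max >= observed_stat - 1e-12).sum())
        done += b
    p = (1 + exceed) / (R + 1)

    return ScanResult(
        most_likely=most_likely,
        p_value=float(p),
        secondary=secondary,
        n_replicates=R,
        seed=seed,
    )
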