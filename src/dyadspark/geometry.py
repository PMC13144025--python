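"""Calcium-release-unit geometries on the 30-nm channel lattice.

A CRU is a rectangular lattice of 30 nm x 30 nm sites, each empty or holding
exactly one channel (RyR2 or IP3R2).  Constructors cover the healthy-control
checkerboard, heart-failure-like fragmented/dispersed clusters grown from
seed points, and random IP3R2 interspersal among existing RyR2s; dSTORM-like
channel maps can also be read from a simple CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "RYR", "IP3R", "Site", "CruGeometry", "GeometryStats",
    "CapacityError", "GeometryFormatError",
    "make_checkerboard", "place_ip3rs", "make_fragmented", "compute_stats",
    "read_geometry", "write_geometry", "ctrl_preset", "hf_preset",
]

RYR = "RYR"
IP3R = "IP3R"
_KINDS = (RYR, IP3R)

DEFAULT_MARGIN = 10      # empty border sites around the channel bounding box
DEFAULT_LINK_RADIUS = 100.0  # nm, center-distance criterion for one cluster


class CapacityError(ValueError):
    """Requested channel placement does not fit the available sites."""


class GeometryFormatError(ValueError):
    """Malformed geometry CSV."""


@dataclass(frozen=True, order=True)
class Site:
    ix: int
    iy: int
    kind: str


@dataclass(frozen=True)
class CruGeometry:
    """Immutable channel arrangement on an ``nx`` x ``ny`` lattice."""

    nx: int
    ny: int
    sites: tuple[Site, ...]
    pitch_nm: float = 30.0

    def __post_init__(self):
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid dimensions must be >= 1")
        seen = set()
        for s in self.sites:
            if s.kind not in _KINDS:
                raise ValueError(f"unknown channel kind {s.kind!r}")
            if not (0 <= s.ix < self.nx and 0 <= s.iy < self.ny):
                raise ValueError(f"site ({s.ix},{s.iy}) outside {self.nx}x{self.ny} grid")
            if (s.ix, s.iy) in seen:
                raise ValueError(f"duplicate channel at ({s.ix},{s.iy})")
            seen.add((s.ix, s.iy))

    def ryr_sites(self) -> tuple[Site, ...]:
        return tuple(s for s in self.sites if s.kind == RYR)

    def ip3r_sites(self) -> tuple[Site, ...]:
        return tuple(s for s in self.sites if s.kind == IP3R)

    @property
    def n_ryr(self) -> int:
        return len(self.ryr_sites())

    @property
    def n_ip3r(self) -> int:
        return len(self.ip3r_sites())

    def occupied(self) -> set[tuple[int, int]]:
        return {(s.ix, s.iy) for s in self.sites}

    def __eq__(self, other):
        if not isinstance(other, CruGeometry):
            return NotImplemented
        return (self.nx, self.ny, self.pitch_nm) == (other.nx, other.ny, other.pitch_nm) \
            and sorted(self.sites) == sorted(other.sites)

    def __hash__(self):
        return hash((self.nx, self.ny, self.pitch_nm, tuple(sorted(self.sites))))


@dataclass(frozen=True)
class GeometryStats:
    n_ryr: int
    n_ip3r: int
    n_clusters: int
    mean_ryr_per_cluster: float   # nan when no RyRs
    mean_nn_distance: float       # nm between cluster centroids; nan if < 2 clusters


def make_checkerboard(n_ryr: int, margin: int = DEFAULT_MARGIN,
                      seed: int = 0) -> CruGeometry:
    """RyR2s in an alternating-cell (checkerboard) block, centered in the grid.

    The block is the smallest near-square board whose dark cells can hold
    ``n_ryr`` channels; cells are filled row-major, so the layout is
    deterministic (``seed`` is accepted for interface symmetry with the other
    constructors but is not used).  No two channels share an edge.
    """
    if n_ryr < 0 or margin < 0:
        raise ValueError("n_ryr and margin must be >= 0")
    if n_ryr == 0:
        side = max(1, 2 * margin + 1)
        return CruGeometry(nx=side, ny=side, sites=())
    side = max(1, math.ceil(math.sqrt(2 * n_ryr)))
    while sum(1 for j in range(side) for i in range(side) if (i + j) % 2 == 0) < n_ryr:
        side += 1
    sites = []
    for j in range(side):
        for i in range(side):
            if (i + j) % 2 == 0 and len(sites) < n_ryr:
                sites.append(Site(ix=i + margin, iy=j + margin, kind=RYR))
    dim = side + 2 * margin
    return CruGeometry(nx=dim, ny=dim, sites=tuple(sites))


def _placement_region(geom: CruGeometry) -> list[tuple[int, int]]:
    """Unoccupied cells within the RyR bounding box expanded by one site."""
    ryr = geom.ryr_sites()
    if not ryr:
        cells = [(i, j) for j in range(geom.ny) for i in range(geom.nx)]
    else:
        x0 = max(min(s.ix for s in ryr) - 1, 0)
        x1 = min(max(s.ix for s in ryr) + 1, geom.nx - 1)
        y0 = max(min(s.iy for s in ryr) - 1, 0)
        y1 = min(max(s.iy for s in ryr) + 1, geom.ny - 1)
        cells = [(i, j) for j in range(y0, y1 + 1) for i in range(x0, x1 + 1)]
    occ = geom.occupied()
    return [c for c in cells if c not in occ]


def place_ip3rs(geom: CruGeometry, n_ip3r: int, seed: int) -> CruGeometry:
    """Add ``n_ip3r`` IP3R2s at uniform-random free cells among the RyR2s.

    Placement cells are drawn without replacement from the unoccupied sites
    inside the RyR bounding box expanded by one site, emulating random
    interspersal of IP3R2s within the CRU.  Deterministic for a fixed seed.
    """
    if n_ip3r < 0:
        raise ValueError("n_ip3r must be >= 0")
    if n_ip3r == 0:
        return geom
    free = _placement_region(geom)
    if n_ip3r > len(free):
        raise CapacityError(
            f"cannot place {n_ip3r} IP3R2s in {len(free)} free sites")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(free), size=n_ip3r, replace=False)
    new = tuple(Site(ix=free[k][0], iy=free[k][1], kind=IP3R) for k in sorted(chosen))
    return replace(geom, sites=geom.sites + new)


def make_fragmented(n_ryr: int, n_clusters: int, spread: float = 200.0,
                    seed: int = 0, margin: int = DEFAULT_MARGIN,
                    max_retries: int = 200) -> CruGeometry:
    """HF-like fragmented CRU: ``n_clusters`` connected RyR blobs.

    Cluster seed points are scattered with pairwise center spacing controlled
    by ``spread`` (nm): centers are drawn uniformly in a square of side
    ``~spread * sqrt(n_clusters)`` and rejected when closer than
    ``0.6 * spread``.  Each blob is grown from its seed point by repeatedly
    occupying a random free 4-neighbor of the blob, which produces compact,
    irregular clusters; RyR counts are split as evenly as possible.  Growth
    keeps distinct blobs more than 100 nm apart (the default cluster-link
    criterion), so the requested cluster count is what compute_stats reports.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_ryr < n_clusters:
        raise ValueError("need n_ryr >= n_clusters")
    rng = np.random.default_rng(seed)
    pitch = 30.0
    spread_sites = max(1.0, spread / pitch)
    box = max(int(math.ceil(spread_sites * math.sqrt(n_clusters))) + 2,
              int(math.ceil(math.sqrt(4 * n_ryr))))
    sizes = [n_ryr // n_clusters] * n_clusters
    for k in range(n_ryr % n_clusters):
        sizes[k] += 1

    for _ in range(max_retries):
        # scatter cluster centers with a minimum-separation rejection rule
        centers: list[tuple[int, int]] = []
        ok = True
        min_sep = max(0.6 * spread_sites, 4.0)
        for _c in range(n_clusters):
            for _try in range(200):
                cand = (int(rng.integers(0, box)), int(rng.integers(0, box)))
                if all(math.hypot(cand[0] - a, cand[1] - b) >= min_sep
                       for a, b in centers):
                    centers.append(cand)
                    break
            else:
                ok = False
                break
        if not ok:
            continue
        occ: set[tuple[int, int]] = set()
        grown = True
        for (cx, cy), size in zip(centers, sizes):
            blob = _grow_blob((cx, cy), size, occ, box, rng)
            if blob is None:
                grown = False
                break
            occ |= blob
        if not grown:
            continue
        xs = [c[0] for c in occ]
        ys = [c[1] for c in occ]
        x0, y0 = min(xs), min(ys)
        nx = max(xs) - x0 + 1 + 2 * margin
        ny = max(ys) - y0 + 1 + 2 * margin
        sites = tuple(Site(ix=i - x0 + margin, iy=j - y0 + margin, kind=RYR)
                      for i, j in sorted(occ))
        return CruGeometry(nx=nx, ny=ny, sites=sites)
    raise CapacityError(
        f"could not pack {n_ryr} RyRs into {n_clusters} clusters "
        f"(spread={spread} nm) after {max_retries} retries")


# site offsets within 100 nm (squared lattice distance <= (100/30)^2)
_HALO = tuple((dx, dy) for dx in range(-3, 4) for dy in range(-3, 4)
              if dx * dx + dy * dy <= 11)


def _too_close(cell, occupied):
    for dx, dy in _HALO:
        if (cell[0] + dx, cell[1] + dy) in occupied:
            return True
    return False


def _grow_blob(center, size, occupied, box, rng):
    if _too_close(center, occupied):
        return None
    blob = {center}
    for _ in range(size - 1):
        frontier = []
        for (i, j) in blob:
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                c = (i + di, j + dj)
                if (0 <= c[0] < box and 0 <= c[1] < box
                        and c not in blob and not _too_close(c, occupied)):
                    frontier.append(c)
        if not frontier:
            return None
        blob.add(frontier[int(rng.integers(0, len(frontier)))])
    return blob


def compute_stats(geom: CruGeometry,
                  link_radius: float = DEFAULT_LINK_RADIUS) -> GeometryStats:
    """Cluster statistics of the RyR arrangement.

    Clusters are connected components of RyR sites under center distance
    <= ``link_radius`` (nm).  ``mean_nn_distance`` is the mean over clusters
    of the distance (nm) to the nearest other cluster centroid; it is nan
    when fewer than two clusters exist.
    """
    ryr = geom.ryr_sites()
    n_ip3r = geom.n_ip3r
    if not ryr:
        return GeometryStats(0, n_ip3r, 0, math.nan, math.nan)
    pos = np.array([(s.ix, s.iy) for s in ryr], dtype=float) * geom.pitch_nm
    if len(pos) == 1:
        return GeometryStats(1, n_ip3r, 1, 1.0, math.nan)
    dmat = squareform(pdist(pos))
    adj = csr_matrix(dmat <= link_radius)
    n_comp, labels = connected_components(adj, directed=False)
    centroids = np.array([pos[labels == k].mean(axis=0) for k in range(n_comp)])
    if n_comp >= 2:
        cd = squareform(pdist(centroids))
        np.fill_diagonal(cd, np.inf)
        mean_nn = float(cd.min(axis=1).mean())
    else:
        mean_nn = math.nan
    return GeometryStats(
        n_ryr=len(ryr), n_ip3r=n_ip3r, n_clusters=int(n_comp),
        mean_ryr_per_cluster=len(ryr) / n_comp, mean_nn_distance=mean_nn)


def ctrl_preset(seed: int = 0) -> CruGeometry:
    """Healthy-control stand-in: 50 RyRs in two compact clusters."""
    return make_fragmented(n_ryr=50, n_clusters=2, spread=450.0, seed=seed)


def hf_preset(seed: int = 0) -> CruGeometry:
    """Heart-failure stand-in: 50 RyRs fragmented into eight dispersed blobs."""
    return make_fragmented(n_ryr=50, n_clusters=8, spread=200.0, seed=seed)


def write_geometry(geom: CruGeometry, path: str | Path) -> None:
    """Write a geometry CSV (``kind,ix,iy`` with ``#`` metadata comments)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# pitch_nm={geom.pitch_nm}\n")
        fh.write(f"# nx={geom.nx} ny={geom.ny}\n")
        fh.write("kind,ix,iy\n")
        for s in sorted(geom.sites):
            fh.write(f"{s.kind},{s.ix},{s.iy}\n")


def read_geometry(path: str | Path) -> CruGeometry:
    """Read a geometry CSV written by :func:`write_geometry` (or dSTORM-derived).

    Raises :class:`GeometryFormatError` naming the offending row on duplicate
    cells, out-of-range indices or unknown channel kinds.
    """
    path = Path(path)
    pitch = 30.0
    nx = ny = None
    rows: list[tuple[str, int, int, int]] = []
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].replace(",", " ").split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        if k == "pitch_nm":
                            pitch = float(v)
                        elif k == "nx":
                            nx = int(v)
                        elif k == "ny":
                            ny = int(v)
                continue
            if not header_seen:
                if [t.strip() for t in line.split(",")] != ["kind", "ix", "iy"]:
                    raise GeometryFormatError(
                        f"{path}:{lineno}: expected header 'kind,ix,iy'")
                header_seen = True
                continue
            parts = [t.strip() for t in line.split(",")]
            if len(parts) != 3:
                raise GeometryFormatError(f"{path}:{lineno}: expected 3 fields")
            kind, sx, sy = parts
            if kind not in _KINDS:
                raise GeometryFormatError(
                    f"{path}:{lineno}: unknown channel kind {kind!r}")
            try:
                ix, iy = int(sx), int(sy)
            except ValueError as exc:
                raise GeometryFormatError(
                    f"{path}:{lineno}: non-integer index") from exc
            rows.append((kind, ix, iy, lineno))
    if not header_seen:
        raise GeometryFormatError(f"{path}: missing 'kind,ix,iy' header")
    if nx is None:
        nx = (max((r[1] for r in rows), default=0) + 1 + DEFAULT_MARGIN)
    if ny is None:
        ny = (max((r[2] for r in rows), default=0) + 1 + DEFAULT_MARGIN)
    seen: dict[tuple[int, int], int] = {}
    sites = []
    for kind, ix, iy, lineno in rows:
        if not (0 <= ix < nx and 0 <= iy < ny):
            raise GeometryFormatError(
                f"{path}:{lineno}: index ({ix},{iy}) outside {nx}x{ny} grid")
        if (ix, iy) in seen:
            raise GeometryFormatError(
                f"{path}:{lineno}: duplicate cell ({ix},{iy}), "
                f"first used on line {seen[(ix, iy)]}")
        seen[(ix, iy)] = lineno
        sites.append(Site(ix=ix, iy=iy, kind=kind))
    return CruGeometry(nx=nx, ny=ny, sites=tuple(sites), pitch_nm=pitch)
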