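"""Isolation by distance and by resistance.

Geographic distance matrices, hurricane-incidence conductance grids,
circuit-theory effective resistance from the grid's graph Laplacian, and
Mantel / partial Mantel permutation tests on distance matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .popgen_stats import DistanceMatrix

__all__ = [
    "ConductanceGrid",
    "MantelResult",
    "geographic_distance_matrix",
    "linearize_fst",
    "build_conductance_grid",
    "pairwise_resistance",
    "mantel_test",
    "partial_mantel_test",
    "read_ascii_grid",
    "write_ascii_grid",
]

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# Distances


def geographic_distance_matrix(
    coords: dict[str, tuple[float, float]], method: str = "planar"
) -> DistanceMatrix:
    """Pairwise geographic distances between populations.

    ``coords`` maps population label to (lat, lon) in decimal degrees.
    ``planar`` treats (lon, lat) as planar x/y coordinates (the convention of
    spreadsheet-based toolkits working in decimal degrees); ``great_circle``
    uses the haversine formula with Earth radius 6371 km.  Distances are raw;
    take logs downstream for isolation-by-distance regressions.
    """
    labels = list(coords)
    if len(labels) < 2:
        raise ValueError("need at least two populations")
    lat = np.array([coords[l][0] for l in labels], dtype=float)
    lon = np.array([coords[l][1] for l in labels], dtype=float)
    if not (np.isfinite(lat).all() and np.isfinite(lon).all()):
        raise ValueError("coordinates must be finite")
    if method == "planar":
        d = np.hypot(lon[:, None] - lon[None, :], lat[:, None] - lat[None, :])
    elif method == "great_circle":
        la, lo = np.radians(lat), np.radians(lon)
        h = (
            np.sin((la[:, None] - la[None, :]) / 2) ** 2
            + np.cos(la)[:, None]
            * np.cos(la)[None, :]
            * np.sin((lo[:, None] - lo[None, :]) / 2) ** 2
        )
        d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    else:
        raise ValueError("method must be 'planar' or 'great_circle'")
    np.fill_diagonal(d, 0.0)
    iu = np.triu_indices(len(labels), 1)
    if (d[iu] == 0).any():
        warnings.warn("duplicate coordinates give zero distances (log undefined)")
    return DistanceMatrix(labels, d)


def linearize_fst(fst: DistanceMatrix) -> DistanceMatrix:
    """Rousset linearization x -> x/(1-x), elementwise off the diagonal."""
    v = fst.values
    off = ~np.eye(fst.n, dtype=bool)
    if np.any(v[off] >= 1.0):
        raise ValueError("FST = 1 gives infinite linearized distance")
    out = np.where(off, v / (1.0 - v), 0.0)
    return DistanceMatrix(list(fst.labels), out)


# ---------------------------------------------------------------------------
# Conductance grids and effective resistance


@dataclass
class ConductanceGrid:
    """Raster of per-cell conductances with population anchor cells.

    ``conductance`` is an (n_rows, n_cols) array; non-finite or non-positive
    cells are masked (no flow).  ``neighbors`` is 4 or 8; diagonal edges are
    down-weighted by 1/sqrt(2).  Edge conductance between two neighboring
    cells is the mean of the two cell conductances.
    """

    conductance: np.ndarray
    anchors: dict[str, tuple[int, int]]
    neighbors: int = 8

    def __post_init__(self) -> None:
        self.conductance = np.asarray(self.conductance, dtype=float)
        if self.neighbors not in (4, 8):
            raise ValueError("neighbors must be 4 or 8")
        mask = self.mask
        for label, (r, c) in self.anchors.items():
            if not (0 <= r < self.conductance.shape[0] and 0 <= c < self.conductance.shape[1]):
                raise ValueError(f"anchor {label!r} outside the grid")
            if not mask[r, c]:
                raise ValueError(f"anchor {label!r} lies on a masked cell")

    @property
    def mask(self) -> np.ndarray:
        """True where the cell conducts."""
        with np.errstate(invalid="ignore"):
            return np.isfinite(self.conductance) & (self.conductance > 0)


def build_conductance_grid(
    category_raster: np.ndarray,
    anchors: dict[str, tuple[int, int]],
    mapping: dict[int, float] | None = None,
    neighbors: int = 8,
) -> ConductanceGrid:
    """Map a hurricane-incidence category raster (1..5, 0/negative = masked)
    to per-cell conductances.

    ``mapping`` must be strictly positive and non-decreasing in category; the
    default is the identity (category c -> conductance c).
    """
    cat = np.asarray(category_raster)
    if mapping is None:
        mapping = {c: float(c) for c in range(1, 6)}
    cats = sorted(mapping)
    vals = [mapping[c] for c in cats]
    if any(v <= 0 for v in vals) or any(b < a for a, b in zip(vals, vals[1:])):
        raise ValueError("category mapping must be positive and non-decreasing")
    cond = np.full(cat.shape, np.nan)
    for c, v in mapping.items():
        cond[cat == c] = v
    return ConductanceGrid(cond, dict(anchors), neighbors)


def _grid_laplacian(grid: ConductanceGrid) -> tuple[sp.csc_matrix, np.ndarray]:
    """Weighted graph Laplacian over unmasked cells; returns (L, node index map)."""
    mask = grid.mask
    nr, nc = mask.shape
    node = -np.ones((nr, nc), dtype=np.int64)
    node[mask] = np.arange(mask.sum())
    n = int(mask.sum())
    offsets = [(0, 1), (1, 0)]
    if grid.neighbors == 8:
        offsets += [(1, 1), (1, -1)]
    rows, cols, w = [], [], []
    for dr, dc in offsets:
        scale = 1.0 / np.sqrt(2.0) if dr and dc else 1.0
        r0 = slice(max(0, -dr), nr - max(0, dr))
        c0 = slice(max(0, -dc), nc - max(0, dc))
        r1 = slice(max(0, dr), nr + min(0, dr))
        c1 = slice(max(0, dc), nc + min(0, dc))
        both = mask[r0, c0] & mask[r1, c1]
        a = node[r0, c0][both]
        b = node[r1, c1][both]
        g = 0.5 * (grid.conductance[r0, c0][both] + grid.conductance[r1, c1][both]) * scale
        rows.append(a)
        cols.append(b)
        w.append(g)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    w = np.concatenate(w)
    A = sp.coo_matrix((np.r_[w, w], (np.r_[rows, cols], np.r_[cols, rows])), shape=(n, n))
    L = (sp.diags(np.asarray(A.sum(axis=1)).ravel()) - A).tocsc()
    return L, node


def pairwise_resistance(grid: ConductanceGrid) -> DistanceMatrix:
    """Effective resistance between every pair of anchor cells.

    One node is grounded; for each pair (s, t), solve L x = e_s - e_t on the
    remaining nodes; R_eff = x_s - x_t (potential drop under unit current).
    """
    labels = list(grid.anchors)
    L, node = _grid_laplacian(grid)
    anchor_nodes = {l: int(node[r, c]) for l, (r, c) in grid.anchors.items()}

    # connectivity check on the anchors' component
    n = L.shape[0]
    n_comp, comp = sp.csgraph.connected_components(L, directed=False)
    comps = {comp[anchor_nodes[l]] for l in labels}
    if len(comps) > 1:
        bad = sorted({l: comp[anchor_nodes[l]] for l in labels}.items(), key=lambda kv: kv[1])
        raise ValueError(f"anchors are not mutually connected: components {bad}")

    ground = anchor_nodes[labels[0]]
    keep = np.ones(n, dtype=bool)
    keep[ground] = False
    keep &= comp == comp[ground]
    idx = -np.ones(n, dtype=np.int64)
    idx[keep] = np.arange(int(keep.sum()))
    Lr = L[keep][:, keep].tocsc()
    lu = splu(Lr)

    m = np.zeros((len(labels), len(labels)))
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            s, t = anchor_nodes[labels[i]], anchor_nodes[labels[j]]
            b = np.zeros(int(keep.sum()))
            if s != ground:
                b[idx[s]] += 1.0
            if t != ground:
                b[idx[t]] -= 1.0
            x = lu.solve(b)
            vs = x[idx[s]] if s != ground else 0.0
            vt = x[idx[t]] if t != ground else 0.0
            m[i, j] = m[j, i] = vs - vt
    return DistanceMatrix(labels, m)


# ---------------------------------------------------------------------------
# ASCII-grid raster I/O (ncols/nrows header, integer cells, NODATA mask)


def read_ascii_grid(path) -> np.ndarray:
    """Read an ASCII-grid raster; NODATA cells become 0 (masked)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(x) for x in parts])
    grid = np.array(rows)
    nodata = header.get("nodata_value")
    if nodata is not None:
        grid[grid == nodata] = 0
    if "ncols" in header and grid.shape[1] != int(header["ncols"]):
        raise ValueError("ncols header does not match data")
    if "nrows" in header and grid.shape[0] != int(header["nrows"]):
        raise ValueError("nrows header does not match data")
    return grid.astype(int)


def write_ascii_grid(raster: np.ndarray, path, nodata: int = -9999) -> None:
    raster = np.asarray(raster)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"ncols {raster.shape[1]}\n")
        fh.write(f"nrows {raster.shape[0]}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in raster:
            fh.write(" ".join(str(int(v)) if v > 0 else str(nodata) for v in row) + "\n")


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Mantel tests


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    partial: bool = False
    conditioning: str | None = None


def _aligned_offdiag(*mats: DistanceMatrix) -> list[np.ndarray]:
    labels = mats[0].labels
    for m in mats[1:]:
        if m.labels != labels:
            raise ValueError("distance matrices must share labels and order")
    return [m.condensed() for m in mats]


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero variance among off-diagonal entries")
    return float(np.corrcoef(x, y)[0, 1])


def mantel_test(
    A: DistanceMatrix, B: DistanceMatrix, n_perm: int = 10_000, seed: int = 0
) -> MantelResult:
    """Mantel permutation test of matrix correlation.

    r is the Pearson correlation over the n(n-1)/2 off-diagonal pairs; the
    one-tailed (upper) p permutes B's rows and columns simultaneously and
    uses the (b+1)/(m+1) estimator.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    a, b = _aligned_offdiag(A, B)
    r_obs = _corr(a, b)
    rng = np.random.default_rng(seed)
    n = A.n
    hits = 0
    Bv = B.values
    iu = np.triu_indices(n, 1)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = Bv[np.ix_(perm, perm)][iu]
        if _corr(a, bp) >= r_obs - 1e-12:
            hits += 1
    return MantelResult(r_obs, (hits + 1) / (n_perm + 1), n_perm)


def _residualize(y: np.ndarray, c: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(c), c])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_mantel_test(
    A: DistanceMatrix,
    B: DistanceMatrix,
    C: DistanceMatrix,
    n_perm: int = 10_000,
    seed: int = 0,
    conditioning_label: str = "C",
) -> MantelResult:
    """Partial Mantel test of A vs B controlling for C.

    r is the correlation of the residuals of A and B after least-squares
    regression on C's off-diagonal vector.  The permutation null follows the
    residual-permutation method: A's residuals are written back into matrix
    form and their rows/columns permuted simultaneously (one-tailed upper p).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    a, b, c = _aligned_offdiag(A, B, C)
    ra = _residualize(a, c)
    rb = _residualize(b, c)
    # degenerate case: conditioning explains one matrix exactly (e.g. A == C);
    # the residual is numerical noise and the partial correlation is zero
    if np.std(ra) <= 1e-8 * np.std(a) or np.std(rb) <= 1e-8 * np.std(b):
        return MantelResult(0.0, 1.0, n_perm, partial=True, conditioning=conditioning_label)
    r_obs = _corr(ra, rb)

    n = A.n
    iu = np.triu_indices(n, 1)
    Ra = np.zeros((n, n))
    Ra[iu] = ra
    Ra += Ra.T
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rap = Ra[np.ix_(perm, perm)][iu]
        if _corr(rap, rb) >= r_obs - 1e-12:
            hits += 1
    return MantelResult(
        r_obs,
        (hits + 1) / (n_perm + 1),
        n_perm,
        partial=True,
        conditioning=conditioning_label,
    )
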