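"""Single-subject grey-matter covariance network extraction.

A grey-matter probability volume is parcellated into small cubes of voxels
(the network nodes); the Pearson correlation of grey-matter intensities
between every pair of cubes defines edge weights, and a subject-specific
threshold — the upper quantile of a null correlation distribution obtained by
spatially permuting the in-mask voxel values — selects which correlations
survive as binary edges.  The permutation null preserves the subject's
intensity histogram while destroying all spatial structure, so every subject
admits the same fraction of chance-level correlations into their network.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

logger = logging.getLogger("gmnet")

__all__ = [
    "GreyMatterVolume",
    "CubeParcellation",
    "CorrelationMatrix",
    "BinaryNetwork",
    "parcellate",
    "correlate",
    "permutation_threshold",
    "binarize",
    "total_gm_volume",
]


@dataclass
class GreyMatterVolume:
    """A 3D scalar field of grey-matter probability with voxel spacing in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(
                f"volume must be 3D, got {self.values.ndim} dimensions"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class CubeParcellation:
    """Cube nodes of one volume: origins, per-cube intensity vectors, inclusion.

    ``origins`` holds the 0-based voxel coordinate of each cube's low corner;
    ``intensities`` holds the cube_edge**3 voxel values per cube in fixed
    C-order scan order.  Node ordering is lexicographic by origin.  ``included``
    marks cubes that pass the grey-matter inclusion rule; only included cubes
    become network nodes.
    """

    cube_edge: int
    origins: np.ndarray          # (n_cubes, 3) int
    intensities: np.ndarray      # (n_cubes, cube_edge**3) float
    included: np.ndarray         # (n_cubes,) bool

    @property
    def n_nodes(self) -> int:
        return int(self.included.sum())

    def node_origins(self) -> np.ndarray:
        """Origins of included cubes only, in node order."""
        return self.origins[self.included]

    def node_intensities(self) -> np.ndarray:
        return self.intensities[self.included]


@dataclass
class CorrelationMatrix:
    """Symmetric node-by-node Pearson correlations; NaN marks undefined cells."""

    values: np.ndarray           # (n, n) float, diagonal NaN
    node_origins: np.ndarray     # (n, 3) int
    undefined: np.ndarray = field(default=None)  # (n, n) bool

    def __post_init__(self) -> None:
        if self.undefined is None:
            self.undefined = ~np.isfinite(self.values)
            np.fill_diagonal(self.undefined, False)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryNetwork:
    """Undirected, unweighted network over cube nodes after thresholding."""

    adjacency: sparse.csr_matrix   # symmetric, zero diagonal, dtype int8
    node_origins: np.ndarray | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.adjacency = sparse.csr_matrix(self.adjacency, dtype=np.int8)
        if self.adjacency.shape[0] != self.adjacency.shape[1]:
            raise ValueError("adjacency must be square")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    @property
    def density(self) -> float:
        n = self.n_nodes
        if n < 2:
            return 0.0
        return self.n_edges / (n * (n - 1) / 2)

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    def edge_set(self) -> set[tuple[int, int]]:
        coo = sparse.triu(self.adjacency, k=1).tocoo()
        return set(zip(coo.row.tolist(), coo.col.tolist()))


def parcellate(
    vol: GreyMatterVolume,
    cube_edge: int = 3,
    gm_threshold: float = 0.1,
    min_gm_voxels: int = 1,
) -> CubeParcellation:
    """Tile the volume into disjoint cubes of ``cube_edge`` voxels per side.

    Tiling starts at voxel (0, 0, 0); trailing slabs smaller than a full cube
    are discarded.  A cube is an included node iff at least ``min_gm_voxels``
    of its voxels exceed ``gm_threshold`` grey-matter probability.
    """
    if cube_edge < 1:
        raise ValueError("cube_edge must be >= 1")
    e = int(cube_edge)
    shape = vol.shape
    n_per_axis = tuple(s // e for s in shape)
    if any(n == 0 for n in n_per_axis):
        raise ValueError(
            f"volume shape {shape} smaller than one {e}x{e}x{e} cube"
        )
    nx, ny, nz = n_per_axis
    trimmed = vol.values[: nx * e, : ny * e, : nz * e]
    # (nx, e, ny, e, nz, e) -> (nx, ny, nz, e, e, e) -> (n_cubes, e^3)
    blocks = (
        trimmed.reshape(nx, e, ny, e, nz, e)
        .transpose(0, 2, 4, 1, 3, 5)
        .reshape(nx * ny * nz, e**3)
    )
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    origins = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1) * e
    included = (blocks > gm_threshold).sum(axis=1) >= min_gm_voxels
    logger.info(
        "parcellate: cube_edge=%d gm_threshold=%g min_gm_voxels=%d "
        "cubes=%d included=%d",
        e, gm_threshold, min_gm_voxels, blocks.shape[0], int(included.sum()),
    )
    return CubeParcellation(
        cube_edge=e, origins=origins, intensities=blocks, included=included
    )


def _rotation_permutations(edge: int) -> np.ndarray:
    """Column permutations realizing the 48 axis-aligned rotations/reflections
    of an edge^3 voxel grid flattened in C order."""
    idx = np.arange(edge**3).reshape(edge, edge, edge)
    perms = []
    seen = set()
    import itertools

    for axes in itertools.permutations(range(3)):
        for flips in itertools.product([False, True], repeat=3):
            g = np.transpose(idx, axes)
            for ax, f in enumerate(flips):
                if f:
                    g = np.flip(g, axis=ax)
            key = g.tobytes()
            if key not in seen:
                seen.add(key)
                perms.append(g.ravel().copy())
    return np.array(perms)


def correlate(parc: CubeParcellation, rotation_mode: bool = False) -> CorrelationMatrix:
    """Pearson correlation of grey-matter intensities for every pair of cubes.

    In plain mode this is the textbook Pearson r between the two intensity
    vectors.  In rotation mode the reported value is the maximum r over the 48
    axis-aligned rotations/reflections of the second cube's intensity grid,
    making the similarity measure invariant to cube orientation.  Zero-variance
    cubes produce flagged undefined (NaN) entries rather than silent zeros.
    """
    if parc.n_nodes < 2:
        raise ValueError("need at least 2 included nodes to correlate")
    x = parc.node_intensities().astype(np.float64)
    n, m = x.shape
    sd = x.std(axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - x.mean(axis=1, keepdims=True)) / (sd[:, None] * np.sqrt(m))
    z[degenerate] = np.nan

    if not rotation_mode:
        r = z @ z.T
    else:
        r = np.full((n, n), -np.inf)
        for perm in _rotation_permutations(parc.cube_edge):
            np.maximum(r, z @ z[:, perm].T, out=r)
    r = np.clip(r, -1.0, 1.0)
    r = np.where(np.isnan(r) | np.isnan(r.T), np.nan, (r + r.T) / 2.0)
    np.fill_diagonal(r, np.nan)
    undefined = np.zeros((n, n), dtype=bool)
    undefined[degenerate, :] = True
    undefined[:, degenerate] = True
    np.fill_diagonal(undefined, False)
    return CorrelationMatrix(values=r, node_origins=parc.node_origins(), undefined=undefined)


def permutation_threshold(
    vol: GreyMatterVolume,
    cube_edge: int = 3,
    gm_threshold: float = 0.1,
    min_gm_voxels: int = 1,
    alpha: float = 0.05,
    n_null_pairs: int = 1_000_000,
    seed: int | np.random.Generator = 0,
    rotation_mode: bool = False,
) -> float:
    """Subject-specific correlation threshold from a spatial-permutation null.

    The voxel values inside the included cubes of the original parcellation
    are shuffled across those same positions, which preserves the intensity
    multiset but removes spatial structure.  The permuted volume is
    re-parcellated, null Pearson correlations are computed on up to
    ``n_null_pairs`` randomly sampled node pairs, and the (1 - alpha) upper
    quantile of that null distribution is returned: applying it admits only
    the fraction ``alpha`` of chance-level correlations.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    parc = parcellate(vol, cube_edge, gm_threshold, min_gm_voxels)
    e = cube_edge
    mask = np.zeros(vol.shape, dtype=bool)
    for i, j, k in parc.origins[parc.included]:
        mask[i : i + e, j : j + e, k : k + e] = True

    permuted = vol.values.copy()
    vals = permuted[mask]
    permuted[mask] = rng.permutation(vals)
    pvol = GreyMatterVolume(values=permuted, spacing=vol.spacing)

    pparc = parcellate(pvol, cube_edge, gm_threshold, min_gm_voxels)
    if pparc.n_nodes < 2:
        raise ValueError("degenerate permuted volume with fewer than 2 nodes")
    pcorr = correlate(pparc, rotation_mode=rotation_mode)
    iu, ju = np.triu_indices(pcorr.n_nodes, k=1)
    null_vals = pcorr.values[iu, ju]
    null_vals = null_vals[np.isfinite(null_vals)]
    if null_vals.size > n_null_pairs:
        idx = rng.choice(null_vals.size, size=n_null_pairs, replace=False)
        null_vals = null_vals[idx]
    threshold = float(np.quantile(null_vals, 1.0 - alpha))
    logger.info(
        "permutation_threshold: alpha=%g n_null=%d threshold=%.6f",
        alpha, null_vals.size, threshold,
    )
    return threshold


def binarize(corr: CorrelationMatrix, threshold: float) -> BinaryNetwork:
    """Binarize a correlation matrix: edge iff r > threshold.

    Undefined (NaN-flagged) correlations never form edges; their nodes are
    retained so the node count is unaffected.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    with np.errstate(invalid="ignore"):
        adj = np.where(np.isfinite(corr.values) & (corr.values > threshold), 1, 0)
    adj = np.triu(adj, k=1)
    adj = adj + adj.T
    net = BinaryNetwork(
        adjacency=sparse.csr_matrix(adj.astype(np.int8)),
        node_origins=corr.node_origins,
        threshold=float(threshold),
    )
    logger.info(
        "binarize: threshold=%.6f n_nodes=%d n_edges=%d density=%.4f",
        threshold, net.n_nodes, net.n_edges, net.density,
    )
    return net


def extract_network(
    vol: GreyMatterVolume,
    cube_edge: int = 3,
    gm_threshold: float = 0.1,
    min_gm_voxels: int = 1,
    alpha: float = 0.05,
    n_null_pairs: int = 1_000_000,
    seed: int | np.random.Generator = 0,
    rotation_mode: bool = False,
) -> BinaryNetwork:
    """Full pipeline: parcellate, correlate, permutation-threshold, binarize."""
    parc = parcellate(vol, cube_edge, gm_threshold, min_gm_voxels)
    corr = correlate(parc, rotation_mode=rotation_mode)
    thr = permutation_threshold(
        vol, cube_edge, gm_threshold, min_gm_voxels,
        alpha=alpha, n_null_pairs=n_null_pairs, seed=seed,
        rotation_mode=rotation_mode,
    )
    return binarize(corr, thr)


def total_gm_volume(vol: GreyMatterVolume) -> float:
    """Total grey-matter volume in millilitres: sum of probabilities times
    voxel volume."""
    return float(vol.values.sum() * vol.voxel_volume_mm3 / 1000.0)
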