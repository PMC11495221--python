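"""File I/O: NIfTI volumes, cohort CSVs, Matrix Market networks, JSON results,
and the flat-text analysis configuration.

All round trips are lossless at the stated precision (floats written with 12
significant digits), and result JSON is written with sorted keys and a fixed
float representation so identically-seeded runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .network import BinaryNetwork, GreyMatterVolume

logger = logging.getLogger("gmnet")

__all__ = [
    "AnalysisConfig",
    "read_gm_volume",
    "write_gm_volume",
    "read_cohort_table",
    "write_cohort_table",
    "read_network",
    "write_network",
    "write_results_json",
]

REQUIRED_COHORT_COLUMNS = ("subject_id", "mutation_status", "sex")


@dataclass
class AnalysisConfig:
    """Fixed method constants of the pipeline, serializable to flat text.

    Defaults follow the published procedure: 3x3x3-voxel cubes, a 5%
    permutation-null exceedance threshold, 5 network randomizations, and
    posterior sampling with 10 000 iterations in 8 chains thinned by 10.
    """

    cube_edge: int = 3
    gm_inclusion_threshold: float = 0.1
    min_gm_voxels: int = 1
    null_alpha: float = 0.05
    n_null_pairs: int = 1_000_000
    n_random_graphs: int = 5
    rotation_mode: bool = False
    mcmc_chains: int = 8
    mcmc_iterations: int = 10_000
    mcmc_thinning: int = 10
    eyo_grid_min: float = -25.0
    eyo_grid_max: float = 10.0
    eyo_grid_step: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.null_alpha < 1:
            raise ValueError("null_alpha must be in (0, 1)")
        if self.cube_edge < 1:
            raise ValueError("cube_edge must be >= 1")
        for name in ("min_gm_voxels", "n_null_pairs", "n_random_graphs",
                     "mcmc_chains", "mcmc_iterations", "mcmc_thinning"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.gm_inclusion_threshold <= 1:
            raise ValueError("gm_inclusion_threshold must be in [0, 1]")

    def save(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, bool):
                v = "true" if v else "false"
            elif isinstance(v, float):
                v = f"{v:.12g}"
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "AnalysisConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            t = types[key]
            if t in ("bool", bool):
                kwargs[key] = raw.lower() == "true"
            elif t in ("int", int):
                kwargs[key] = int(raw)
            else:
                kwargs[key] = float(raw)
        return cls(**kwargs)

    @property
    def eyo_grid(self) -> np.ndarray:
        return np.round(
            np.arange(self.eyo_grid_min, self.eyo_grid_max + 1e-9, self.eyo_grid_step),
            6,
        )


def read_gm_volume(path: str | Path) -> GreyMatterVolume:
    """Read a grey-matter probability volume from NIfTI.

    Singleton trailing dimensions are squeezed; values outside [0, 1] are
    clipped with a logged warning; voxel spacing comes from the header.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise ValueError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"volume must be 3D, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"missing or invalid voxel spacing in {path}")
    lo, hi = float(data.min()), float(data.max())
    if lo < 0.0 or hi > 1.0:
        logger.warning(
            "volume %s has values outside [0, 1] (range %.4g..%.4g); clipping",
            path, lo, hi,
        )
        data = np.clip(data, 0.0, 1.0)
    return GreyMatterVolume(values=data, spacing=tuple(float(z) for z in zooms))


def write_gm_volume(vol: GreyMatterVolume, path: str | Path) -> None:
    """Write a volume as NIfTI with its spacing in the affine."""
    affine = np.diag([*vol.spacing, 1.0])
    img = nib.Nifti1Image(vol.values.astype(np.float32), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV; empty biomarker cells become missing values."""
    table = pd.read_csv(path)
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    dup = table["subject_id"][table["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject_id: {dup.iloc[0]!r}")
    return table


def write_cohort_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort CSV with 12-significant-digit floats."""
    table.to_csv(path, index=False, float_format="%.12g")


def write_network(net: BinaryNetwork, path: str | Path) -> None:
    """Write a network as Matrix Market (upper triangle, pattern-like 1s)
    plus a ``<path>.nodes.csv`` sidecar with cube origins and the threshold."""
    path = Path(path)
    lower = sparse.tril(net.adjacency, k=-1).tocoo()
    spio.mmwrite(str(path), lower, field="integer", symmetry="symmetric")
    n = net.n_nodes
    origins = (
        net.node_origins
        if net.node_origins is not None
        else np.full((n, 3), -1, dtype=int)
    )
    sidecar = pd.DataFrame(
        {
            "node": np.arange(n),
            "origin_i": origins[:, 0],
            "origin_j": origins[:, 1],
            "origin_k": origins[:, 2],
        }
    )
    sidecar.attrs["threshold"] = net.threshold
    with open(path.with_suffix(path.suffix + ".nodes.csv"), "w") as fh:
        thr = "" if net.threshold is None else f"{net.threshold:.12g}"
        fh.write(f"# threshold = {thr}\n")
        sidecar.to_csv(fh, index=False)


def read_network(path: str | Path) -> BinaryNetwork:
    """Read a network written by :func:`write_network`."""
    path = Path(path)
    mat = spio.mmread(str(path)).tocsr()
    mat = ((mat + mat.T) > 0).astype(np.int8)
    mat.setdiag(0)
    mat.eliminate_zeros()
    sidecar_path = path.with_suffix(path.suffix + ".nodes.csv")
    origins = None
    threshold = None
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            first = fh.readline()
            if first.startswith("# threshold"):
                raw = first.partition("=")[2].strip()
                threshold = float(raw) if raw else None
                sidecar = pd.read_csv(fh)
            else:
                fh.seek(0)
                sidecar = pd.read_csv(fh)
        origins = sidecar[["origin_i", "origin_j", "origin_k"]].to_numpy()
    return BinaryNetwork(adjacency=mat, node_origins=origins, threshold=threshold)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_results_json(results: dict, path: str | Path) -> None:
    """Deterministic JSON output: sorted keys, no timestamps."""
    Path(path).write_text(
        json.dumps(results, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
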