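"""Data containers and on-disk formats for multi-sample SRT data.

A sample is a spots/cells x genes count matrix with 2D spatial coordinates
per unit. Three interchange formats are supported: a 10x-style Matrix Market
triplet with a positions sidecar, a plain CSV pair, and a single HDF5
container. All formats round-trip exactly for integer counts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SRTSample",
    "RunConfig",
    "read_sample",
    "write_sample",
    "write_labels",
    "read_labels",
]


@dataclass
class SRTSample:
    """One tissue sample: counts, spatial coordinates, identifiers.

    Parameters
    ----------
    sample_id : str
        Unique sample name.
    counts : ndarray of shape (n_units, n_genes)
        Non-negative expression values (raw counts or simulated values).
    coords : ndarray of shape (n_units, 2)
        Spatial positions in platform units (micrometres or array indices),
        treated as continuous 2D Euclidean positions.
    gene_ids, unit_ids : list of str
        Row/column identifiers.
    annotations : dict, optional
        unit_id -> ground-truth label.
    landmarks : ndarray of shape (n_landmarks, 2), optional
        Positions of spatial landmarks (e.g. amyloid plaques) used by the
        co-localization metric.
    """

    sample_id: str
    counts: np.ndarray
    coords: np.ndarray
    gene_ids: list
    unit_ids: list
    annotations: Optional[dict] = None
    landmarks: Optional[np.ndarray] = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.unit_ids = list(self.unit_ids)
        self.validate()

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def validate(self):
        if self.counts.ndim != 2:
            raise ValueError(f"counts must be 2D, got shape {self.counts.shape}")
        if self.n_units == 0:
            raise ValueError("sample has 0 units")
        if self.coords.shape != (self.n_units, 2):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"({self.n_units}, 2) for sample {self.sample_id!r}"
            )
        if len(self.unit_ids) != self.n_units:
            raise ValueError("unit_ids length does not match counts rows")
        if len(self.gene_ids) != self.n_genes:
            raise ValueError("gene_ids length does not match counts columns")
        if np.any(self.counts < 0):
            raise ValueError(f"negative counts in sample {self.sample_id!r}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates in sample {self.sample_id!r}")
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise ValueError("duplicate unit ids")

    def subset_units(self, idx) -> "SRTSample":
        """Return a copy restricted to the given unit indices (order kept)."""
        idx = np.asarray(idx)
        unit_ids = [self.unit_ids[i] for i in idx]
        ann = None
        if self.annotations is not None:
            ann = {u: self.annotations[u] for u in unit_ids if u in self.annotations}
        return replace(
            self,
            counts=self.counts[idx],
            coords=self.coords[idx],
            unit_ids=unit_ids,
            annotations=ann,
        )


@dataclass
class RunConfig:
    """Pipeline configuration; defaults follow the method's published values.

    k_spatial=6 neighbours for the spatial graph, 30 PCs, smoothed edge
    pruning at threshold 0.6, Louvain resolution 10 for the niche stage and
    1 for the domain stage, niches below 5 units merged, 5 mutual nearest
    neighbours between samples.
    """

    n_pcs: int = 30
    k_spatial: int = 6
    weight_mode: str = "pearson"  # or "snn"
    prune_mode: str = "smoothed"  # or "fixed"
    prune_threshold: float = 0.6
    q_smooth: Optional[int] = None  # None -> k_spatial
    resolution_stage1: float = 10.0
    resolution_stage2: float = 1.0
    min_niche_size: int = 5
    k_mnn: int = 15
    include_self_sample: bool = False
    seed: int = 0
    # secondary knobs
    residual_kind_stage1: str = "deviance"
    residual_kind_stage2: str = "pearson"
    reduction_method: str = "residual_pca"  # or "hvg_pca"
    clip_residuals: bool = True
    k_snn: int = 20
    n_hvg: int = 2000
    keep_unassigned: bool = False
    n_workers: int = 1

    def __post_init__(self):
        if self.k_spatial < 1:
            raise ValueError("k_spatial must be >= 1")
        if self.n_pcs < 2:
            raise ValueError("n_pcs must be >= 2")
        if self.resolution_stage1 <= 0 or self.resolution_stage2 <= 0:
            raise ValueError("resolutions must be positive")
        if self.min_niche_size < 1:
            raise ValueError("min_niche_size must be >= 1")
        if not np.isfinite(self.prune_threshold):
            raise ValueError("prune_threshold must be finite")
        if self.weight_mode not in ("pearson", "snn"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")
        if self.prune_mode not in ("fixed", "smoothed"):
            raise ValueError(f"unknown prune_mode {self.prune_mode!r}")
        if self.q_smooth is None:
            self.q_smooth = self.k_spatial


# ---------------------------------------------------------------------------
# readers / writers

_FORMATS = ("mtx_dir", "csv_pair", "h5")


def read_sample(path, fmt: str = "h5", sample_id: Optional[str] = None) -> SRTSample:
    """Read one sample from disk.

    ``mtx_dir``: directory with matrix.mtx (units x genes), genes.tsv,
    barcodes.tsv and positions.csv (unit_id,x,y).
    ``csv_pair``: ``<path>`` is a prefix; ``<prefix>_counts.csv`` has unit_id
    index and gene columns, ``<prefix>_coords.csv`` has unit_id,x,y.
    ``h5``: single HDF5 file with /counts, /coords, /gene_ids, /unit_ids.
    """
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "mtx_dir":
        return _read_mtx_dir(path, sample_id)
    if fmt == "csv_pair":
        return _read_csv_pair(path, sample_id)
    return _read_h5(path, sample_id)


def write_sample(sample: SRTSample, path, fmt: str = "h5") -> None:
    """Write a sample in one of the supported formats (see :func:`read_sample`)."""
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    sample.validate()
    if fmt == "mtx_dir":
        _write_mtx_dir(sample, path)
    elif fmt == "csv_pair":
        _write_csv_pair(sample, path)
    else:
        _write_h5(sample, path)


def _require(path):
    if not os.path.exists(path):
        raise FileNotFoundError(f"missing file: {path}")
    return path


def _finish(sample_id, counts, coords, gene_ids, unit_ids, annotations=None,
            landmarks=None):
    counts = np.asarray(counts, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if counts.shape[0] != coords.shape[0]:
        raise ValueError(
            f"counts has {counts.shape[0]} rows but coords has "
            f"{coords.shape[0]} for sample {sample_id!r}"
        )
    return SRTSample(
        sample_id=sample_id, counts=counts, coords=coords,
        gene_ids=gene_ids, unit_ids=unit_ids,
        annotations=annotations, landmarks=landmarks,
    )


def _read_mtx_dir(path, sample_id):
    from scipy.io import mmread

    mtx = _require(os.path.join(path, "matrix.mtx"))
    genes = _require(os.path.join(path, "genes.tsv"))
    barcodes = _require(os.path.join(path, "barcodes.tsv"))
    positions = _require(os.path.join(path, "positions.csv"))
    counts = np.asarray(mmread(mtx).todense(), dtype=float)
    gene_ids = pd.read_csv(genes, sep="\t", header=None)[0].astype(str).tolist()
    unit_ids = pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str).tolist()
    pos = pd.read_csv(positions).set_index("unit_id")
    pos.index = pos.index.astype(str)
    try:
        coords = pos.loc[unit_ids, ["x", "y"]].to_numpy(dtype=float)
    except KeyError as e:
        raise ValueError(f"positions.csv missing unit ids: {e}") from e
    return _finish(sample_id or os.path.basename(os.path.normpath(path)),
                   counts, coords, gene_ids, unit_ids)


def _write_mtx_dir(sample, path):
    from scipy.io import mmwrite
    from scipy.sparse import coo_matrix

    os.makedirs(path, exist_ok=True)
    mmwrite(os.path.join(path, "matrix.mtx"), coo_matrix(sample.counts))
    pd.Series(sample.gene_ids).to_csv(
        os.path.join(path, "genes.tsv"), sep="\t", header=False, index=False)
    pd.Series(sample.unit_ids).to_csv(
        os.path.join(path, "barcodes.tsv"), sep="\t", header=False, index=False)
    pd.DataFrame({
        "unit_id": sample.unit_ids,
        "x": sample.coords[:, 0],
        "y": sample.coords[:, 1],
    }).to_csv(os.path.join(path, "positions.csv"), index=False)


def _read_csv_pair(path, sample_id):
    counts_path = _require(str(path) + "_counts.csv")
    coords_path = _require(str(path) + "_coords.csv")
    cdf = pd.read_csv(counts_path, index_col=0)
    cdf.index = cdf.index.astype(str)
    xdf = pd.read_csv(coords_path).set_index("unit_id")
    xdf.index = xdf.index.astype(str)
    if len(cdf) != len(xdf):
        raise ValueError(
            f"counts has {len(cdf)} rows but coords has {len(xdf)} rows")
    coords = xdf.loc[cdf.index, ["x", "y"]].to_numpy(dtype=float)
    return _finish(sample_id or os.path.basename(str(path)),
                   cdf.to_numpy(dtype=float), coords,
                   [str(g) for g in cdf.columns], cdf.index.tolist())


def _write_csv_pair(sample, path):
    parent = os.path.dirname(str(path))
    if parent:
        os.makedirs(parent, exist_ok=True)
    pd.DataFrame(sample.counts, index=sample.unit_ids,
                 columns=sample.gene_ids).to_csv(str(path) + "_counts.csv")
    pd.DataFrame({
        "unit_id": sample.unit_ids,
        "x": sample.coords[:, 0],
        "y": sample.coords[:, 1],
    }).to_csv(str(path) + "_coords.csv", index=False)


def _read_h5(path, sample_id):
    import h5py

    _require(path)
    with h5py.File(path, "r") as f:
        counts = f["counts"][:]
        coords = f["coords"][:]
        gene_ids = [g.decode() if isinstance(g, bytes) else str(g)
                    for g in f["gene_ids"][:]]
        unit_ids = [u.decode() if isinstance(u, bytes) else str(u)
                    for u in f["unit_ids"][:]]
        sid = sample_id or f.attrs.get("sample_id", os.path.basename(path))
        ann = None
        if "annotation_values" in f:
            vals = [v.decode() if isinstance(v, bytes) else str(v)
                    for v in f["annotation_values"][:]]
            ann = dict(zip(unit_ids, vals))
        landmarks = f["landmarks"][:] if "landmarks" in f else None
    return _finish(str(sid), counts, coords, gene_ids, unit_ids, ann, landmarks)


def _write_h5(sample, path):
    import h5py

    parent = os.path.dirname(str(path))
    if parent:
        os.makedirs(parent, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["sample_id"] = sample.sample_id
        f.create_dataset("counts", data=sample.counts)
        f.create_dataset("coords", data=sample.coords)
        str_dt = h5py.string_dtype()
        f.create_dataset("gene_ids", data=np.array(sample.gene_ids, dtype=object),
                         dtype=str_dt)
        f.create_dataset("unit_ids", data=np.array(sample.unit_ids, dtype=object),
                         dtype=str_dt)
        if sample.annotations is not None:
            vals = [str(sample.annotations.get(u, "")) for u in sample.unit_ids]
            f.create_dataset("annotation_values",
                             data=np.array(vals, dtype=object), dtype=str_dt)
        if sample.landmarks is not None:
            f.create_dataset("landmarks", data=np.asarray(sample.landmarks, float))


def write_labels(assignments: dict, path) -> None:
    """Write per-unit domain labels as a tidy CSV.

    ``assignments`` maps sample_id -> (unit_ids, coords, labels). Columns:
    sample_id, unit_id, x, y, domain. Every unit must carry a label.
    """
    frames = []
    for sid, (unit_ids, coords, labels) in assignments.items():
        coords = np.asarray(coords, dtype=float)
        if len(unit_ids) != len(labels):
            raise ValueError(
                f"sample {sid!r}: {len(unit_ids)} units but {len(labels)} labels")
        if any(l is None for l in labels):
            raise ValueError(f"sample {sid!r}: missing labels")
        frames.append(pd.DataFrame({
            "sample_id": sid,
            "unit_id": list(unit_ids),
            "x": coords[:, 0],
            "y": coords[:, 1],
            "domain": list(labels),
        }))
    parent = os.path.dirname(str(path))
    if parent:
        os.makedirs(parent, exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_labels(path) -> dict:
    """Inverse of :func:`write_labels`."""
    df = pd.read_csv(_require(path))
    out = {}
    for sid, g in df.groupby("sample_id", sort=False):
        out[str(sid)] = (
            g["unit_id"].astype(str).tolist(),
            g[["x", "y"]].to_numpy(dtype=float),
            g["domain"].tolist(),
        )
    return out
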