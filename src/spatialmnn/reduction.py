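"""Per-sample dimensionality reduction.

The default route computes residuals of the counts under a null
multinomial/Poisson model (constant relative gene abundance across units)
and feeds them to PCA. The residuals approximate GLM-PCA and avoid the
distortions of log-transforming sparse counts; the Pearson variant also
absorbs part of additive sample-level shifts, which matters for the
cross-sample stage. An alternative route selects highly variable genes and
applies standard PCA to log-normalized counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import SRTSample, RunConfig

__all__ = [
    "ReducedMatrix",
    "null_residuals",
    "select_hvg",
    "reduce_sample",
    "drop_empty_units",
    "pca",
]


@dataclass
class ReducedMatrix:
    """PC scores for one sample: values[M, N] with M units and N PCs."""

    values: np.ndarray
    sample_id: str
    method: str
    explained_variance: np.ndarray = field(default=None)
    rank_limited: bool = False

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite entries in reduced matrix")


def null_residuals(counts, kind: str = "deviance", clip: bool = True):
    """Residuals of a count matrix under the null model mu_ij = n_i * pi_j.

    n_i is the unit's total count and pi_j the gene's share of the grand
    total, so the null expects every unit to express genes in the same
    proportions; residuals carry the signal that deviates from it.

    Pearson: r = (y - mu) / sqrt(mu).
    Deviance: sign(y - mu) * sqrt(2 * [y*ln(y/mu) - (y - mu)]), with the
    y*ln(y/mu) term defined as 0 at y = 0.

    Entries where mu = 0 (all-zero gene) are set to 0. With ``clip`` the
    residuals are truncated at +/- sqrt(M) to bound the leverage of
    individual units, a common practice for count residuals.
    """
    y = np.asarray(counts, dtype=float)
    if y.ndim != 2:
        raise ValueError("counts must be 2D")
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if kind not in ("deviance", "pearson"):
        raise ValueError(f"unknown residual kind {kind!r}")
    n = y.sum(axis=1, keepdims=True)
    total = n.sum()
    if total == 0:
        raise ValueError("zero grand total")
    if np.any(n == 0):
        raise ValueError("all-zero unit rows; drop them first (drop_empty_units)")
    pi = y.sum(axis=0, keepdims=True) / total
    mu = n * pi
    with np.errstate(divide="ignore", invalid="ignore"):
        if kind == "pearson":
            r = (y - mu) / np.sqrt(mu)
            r[mu == 0] = 0.0
        else:
            ylog = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) /
                                              np.where(mu > 0, mu, 1.0)), 0.0)
            dev = 2.0 * (ylog - (y - mu))
            # tiny negative values can appear from cancellation
            dev = np.maximum(dev, 0.0)
            r = np.sign(y - mu) * np.sqrt(dev)
            r[mu == 0] = 0.0
    if clip:
        bound = np.sqrt(y.shape[0])
        r = np.clip(r, -bound, bound)
    return r


def select_hvg(counts, n_top: int):
    """Indices of the ``n_top`` most variable genes.

    Variance is taken on log1p counts-per-10k; ties break by column order
    (gene id order of the source), making the selection stable.
    """
    y = np.asarray(counts, dtype=float)
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if n_top > y.shape[1]:
        raise ValueError(f"n_top={n_top} exceeds n_genes={y.shape[1]}")
    n = y.sum(axis=1, keepdims=True)
    n = np.where(n == 0, 1.0, n)
    logx = np.log1p(y / n * 1e4)
    var = logx.var(axis=0)
    # stable sort on (-var, index): mergesort keeps index order within ties
    order = np.argsort(-var, kind="mergesort")
    return np.sort(order[:n_top])


def pca(x, n_components: int):
    """Centered PCA via full SVD.

    Returns (scores, loadings, explained_variance). Deterministic: the sign
    of each component is fixed so that its largest-magnitude loading is
    positive (first occurrence wins ties).
    """
    x = np.asarray(x, dtype=float)
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # effective rank: discard numerically null directions
    tol = s[0] * max(xc.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    k = min(n_components, rank)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    flip = np.sign(vt[np.arange(k), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    scores = u * s * flip[None, :]
    explained = s**2 / max(x.shape[0] - 1, 1)
    return scores, vt, explained


def drop_empty_units(sample: SRTSample):
    """Remove all-zero units (nothing measured there); warn if any.

    Returns (filtered sample, kept indices into the original)."""
    keep = np.flatnonzero(sample.counts.sum(axis=1) > 0)
    if keep.size == 0:
        raise ValueError(f"sample {sample.sample_id!r}: all units are empty")
    if keep.size < sample.n_units:
        warnings.warn(
            f"sample {sample.sample_id!r}: dropping "
            f"{sample.n_units - keep.size} all-zero units")
        return sample.subset_units(keep), keep
    return sample, keep


def reduce_sample(sample: SRTSample, config: RunConfig) -> ReducedMatrix:
    """Reduce one sample to its top PCs (matrix Y used by all graph stages)."""
    if config.reduction_method == "hvg_pca":
        idx = select_hvg(sample.counts, min(config.n_hvg, sample.n_genes))
        y = sample.counts[:, idx]
        n = y.sum(axis=1, keepdims=True)
        n = np.where(n == 0, 1.0, n)
        mat = np.log1p(y / n * 1e4)
        method = "hvg_pca"
    else:
        kind = config.residual_kind_stage1
        mat = null_residuals(sample.counts, kind=kind, clip=config.clip_residuals)
        method = f"{kind}_pca"
    if config.n_pcs >= min(mat.shape):
        raise ValueError(
            f"n_pcs={config.n_pcs} must be < min(n_units, n_genes)="
            f"{min(mat.shape)}")
    scores, _, explained = pca(mat, config.n_pcs)
    rank_limited = scores.shape[1] < config.n_pcs
    if rank_limited:
        warnings.warn(
            f"sample {sample.sample_id!r}: rank limited to {scores.shape[1]} "
            f"PCs (requested {config.n_pcs})")
    return ReducedMatrix(values=scores, sample_id=sample.sample_id,
                         method=method, explained_variance=explained,
                         rank_limited=rank_limited)
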