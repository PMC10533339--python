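"""Voxel-wise regression of contrast maps on a predictor, with
cluster-level familywise-error control by permutation.

Clusters are formed by thresholding the predictor's t map at an
uncorrected one-sided voxel threshold (default p < 0.001) and labelling
connected components.  Cluster-level corrected p values come from the
permutation distribution of the maximum supra-threshold cluster size:
with covariates present, residuals of the reduced (covariates-only)
model are permuted and added back to its fitted values (Freedman-Lane),
which keeps the covariate structure intact under the null; without
covariates this reduces to a simple exchange of rows.  The corrected
p for an observed cluster of size s is
``(1 + #{permutation max >= s}) / (n_perm + 1)``, exact under
exchangeability and monotone non-increasing in s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage.measure import label as cc_label

from .reference import _CONNECTIVITY_STEPS

__all__ = [
    "ClusterInferenceResult",
    "voxelwise_regression",
    "cluster_fwe_permutation",
]


@dataclass
class ClusterInferenceResult:
    """Outcome of permutation-based cluster inference.

    ``stat_map`` is the observed t map (flat over mask voxels),
    ``cluster_labels`` an integer volume labelling supra-threshold
    voxels (0 = background), ``clusters`` a table with one row per
    observed cluster (size, peak t, peak coordinate, corrected p).
    """

    stat_map: np.ndarray
    df: int
    mask: np.ndarray
    cluster_labels: np.ndarray
    clusters: pd.DataFrame
    params: dict = field(default_factory=dict)


def _stack(maps, contrast):
    mask = maps[0].mask
    for m in maps[1:]:
        if not np.array_equal(m.mask, mask):
            raise ValueError("all subjects must share one analysis mask")
    Y = np.stack([m.gamma[contrast] for m in maps])
    return Y, mask


def _design(predictor, covariates, n):
    x = np.asarray(predictor, dtype=float).ravel()
    if x.size != n:
        raise ValueError("one predictor value per subject map required")
    if x.std() == 0:
        raise ValueError("predictor has zero variance")
    if covariates is None:
        Z = np.empty((n, 0))
    else:
        Z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Z.shape[0] != n:
            Z = Z.T
        if Z.shape[0] != n:
            raise ValueError("covariates must have one row per subject")
    X = np.column_stack([x, Z, np.ones(n)])
    if n <= X.shape[1]:
        raise ValueError("too few subjects for the model")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient voxel-wise design")
    return x, Z, X


def _t_map(X, Y, pinv=None, xtx_inv_00=None):
    """t statistic of the first design column, per voxel (column of Y)."""
    if pinv is None:
        pinv = np.linalg.pinv(X)
        xtx_inv_00 = float((pinv @ pinv.T)[0, 0])
    beta = pinv @ Y
    resid = Y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[0] / np.sqrt(sigma2 * xtx_inv_00)
    return np.where(np.isfinite(t), t, 0.0), df


def voxelwise_regression(maps, contrast, predictor, covariates=None):
    """Per-voxel OLS of contrast estimates on [predictor, covariates, 1].

    Returns ``(t_map, df)`` where ``t_map`` is the t statistic for the
    predictor slope, flat over the mask voxels.
    """
    Y, _ = _stack(maps, contrast)
    _, _, X = _design(predictor, covariates, Y.shape[0])
    return _t_map(X, Y.reshape(Y.shape[0], -1))


def _max_cluster_size(t_flat, t_crit, mask, step):
    supra = np.zeros(mask.shape, dtype=bool)
    supra[mask] = t_flat > t_crit
    if not supra.any():
        return 0, None
    labels = cc_label(supra, connectivity=step)
    sizes = np.bincount(labels.ravel())[1:]
    return int(sizes.max()), labels


def cluster_fwe_permutation(maps, contrast, predictor, covariates=None,
                            cluster_forming_p: float = 0.001,
                            n_perm: int = 1000, seed: int = 0,
                            connectivity: int = 18,
                            affine=None) -> ClusterInferenceResult:
    """Permutation test of positive predictor effects at cluster level.

    Parameters
    ----------
    maps : sequence of ContrastMaps
    contrast : str
        Which contrast's gamma maps to analyse.
    predictor : array
        One value per subject (e.g. an Openness score).
    covariates : array, optional
        n x q nuisance matrix; handled by Freedman-Lane residual
        permutation.
    cluster_forming_p : float
        One-sided uncorrected voxel threshold defining clusters.
    n_perm : int
        Number of permutations (>= 100).
    affine : 4x4 array, optional
        If given, peak coordinates are reported in its world space
        in addition to voxel indices.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if connectivity not in _CONNECTIVITY_STEPS:
        raise ValueError("connectivity must be one of 6, 18, 26")
    step = _CONNECTIVITY_STEPS[connectivity]

    Y, mask = _stack(maps, contrast)
    n = Y.shape[0]
    x, Z, X = _design(predictor, covariates, n)
    pinv = np.linalg.pinv(X)
    xtx00 = float((pinv @ pinv.T)[0, 0])

    t_obs, df = _t_map(X, Y, pinv, xtx00)
    t_crit = float(sps.t.isf(cluster_forming_p, df))

    _, labels = _max_cluster_size(t_obs, t_crit, mask, step)
    if labels is None:
        labels = np.zeros(mask.shape, dtype=int)
        obs_sizes = np.array([], dtype=int)
    else:
        obs_sizes = np.bincount(labels.ravel())[1:]

    # Freedman-Lane: permute reduced-model residuals, keep fitted part
    Zr = np.column_stack([Z, np.ones(n)])
    pinv_r = np.linalg.pinv(Zr)
    fitted = Zr @ (pinv_r @ Y)
    resid = Y - fitted

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm, dtype=int)
    for j in range(n_perm):
        perm = rng.permutation(n)
        t_perm, _ = _t_map(X, fitted + resid[perm], pinv, xtx00)
        null_max[j], _ = _max_cluster_size(t_perm, t_crit, mask, step)

    rows = []
    t_vol = np.zeros(mask.shape)
    t_vol[mask] = t_obs
    for lab in range(1, obs_sizes.size + 1):
        in_cluster = labels == lab
        size = int(obs_sizes[lab - 1])
        peak_idx = np.unravel_index(np.argmax(np.where(in_cluster, t_vol,
                                                       -np.inf)), mask.shape)
        p_corr = (1 + int((null_max >= size).sum())) / (n_perm + 1)
        row = {"cluster": lab, "size": size,
               "peak_t": float(t_vol[peak_idx]),
               "peak_i": peak_idx[0], "peak_j": peak_idx[1],
               "peak_k": peak_idx[2], "p_corrected": p_corr}
        if affine is not None:
            xyz = np.asarray(affine) @ np.array([*peak_idx, 1.0])
            row.update({"peak_x": xyz[0], "peak_y": xyz[1], "peak_z": xyz[2]})
        rows.append(row)
    clusters = pd.DataFrame(rows).sort_values(
        "size", ascending=False).reset_index(drop=True) if rows else \
        pd.DataFrame(columns=["cluster", "size", "peak_t", "peak_i",
                              "peak_j", "peak_k", "p_corrected"])

    params = {"cluster_forming_p": cluster_forming_p, "t_crit": t_crit,
              "n_perm": n_perm, "seed": seed, "connectivity": connectivity,
              "df": df, "method": "freedman-lane permutation, max cluster size"}
    return ClusterInferenceResult(stat_map=t_obs, df=df, mask=mask,
                                  cluster_labels=labels, clusters=clusters,
                                  params=params)
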