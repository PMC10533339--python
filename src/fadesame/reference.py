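"""Young-adult reference maps for single-value score extraction.

The reference for a contrast consists of

* ``J+`` — voxels with a significant *positive* group effect in young
  adults (one-sample t over their contrast estimates, one-sided
  familywise-corrected p < alpha, connected components of at least
  ``k`` voxels), and analogously ``J-`` for negative effects;
* the voxel-wise young-group mean contrast estimate ``beta_hat`` and
  its standard deviation ``sigma_hat`` over the whole analysis mask.

Familywise error is controlled with Bonferroni over the mask voxels —
a conservative but assumption-free alternative to random-field theory.
The correction method, alpha, extent threshold and connectivity are
recorded in ``params`` for provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from skimage.measure import label as cc_label

__all__ = [
    "YoungReference",
    "group_one_sample_t",
    "fwe_threshold_masks",
    "extent_filter",
    "build_reference",
]

#: Map neighbourhood definitions (face/edge/corner) to skimage steps.
_CONNECTIVITY_STEPS = {6: 1, 18: 2, 26: 3}


@dataclass
class YoungReference:
    """Reference maps and young-group moments for one contrast.

    ``j_plus``/``j_minus`` are boolean flat arrays over the ``mask``
    voxels; ``beta_hat``/``sigma_hat`` are flat arrays over the same
    voxels.
    """

    contrast: str
    mask: np.ndarray
    j_plus: np.ndarray
    j_minus: np.ndarray
    beta_hat: np.ndarray
    sigma_hat: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        v = int(self.mask.sum())
        for name in ("j_plus", "j_minus"):
            arr = np.asarray(getattr(self, name), dtype=bool)
            if arr.shape != (v,):
                raise ValueError(f"{name} must be boolean over mask voxels")
            setattr(self, name, arr)
        for name in ("beta_hat", "sigma_hat"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (v,):
                raise ValueError(f"{name} must have one value per mask voxel")
            setattr(self, name, arr)
        if np.any(self.j_plus & self.j_minus):
            raise ValueError("J+ and J- must be disjoint")

    @property
    def v_plus(self) -> int:
        return int(self.j_plus.sum())

    @property
    def v_minus(self) -> int:
        return int(self.j_minus.sum())

    def to_volume(self, flat) -> np.ndarray:
        vol = np.zeros(self.mask.shape, dtype=np.asarray(flat).dtype)
        vol[self.mask] = flat
        return vol


def _stack_gammas(maps, contrast):
    mask = maps[0].mask
    for m in maps[1:]:
        if not np.array_equal(m.mask, mask):
            raise ValueError("all subjects must share one analysis mask")
    try:
        G = np.stack([m.gamma[contrast] for m in maps])
    except KeyError:
        raise KeyError(f"contrast {contrast!r} missing from a subject's maps")
    return G, mask


def group_one_sample_t(maps, contrast):
    """Voxel-wise one-sample t over subjects' contrast estimates.

    Returns ``(t, df)`` with ``t = mean / (sd / sqrt(n))`` and
    ``df = n - 1``.  Voxels with zero variance and zero mean yield
    t = 0 with a warning; zero variance with a nonzero mean is an
    error (a degenerate voxel that would give infinite t).
    """
    if len(maps) < 3:
        raise ValueError("need at least 3 subjects for a group t map")
    G, _ = _stack_gammas(maps, contrast)
    n = G.shape[0]
    mean = G.mean(axis=0)
    sd = G.std(axis=0, ddof=1)
    zero = sd == 0
    if np.any(zero & (mean != 0)):
        idx = np.flatnonzero(zero & (mean != 0))[:5]
        raise ValueError(
            f"degenerate voxel(s) with zero variance but nonzero mean, e.g. {idx}")
    if np.any(zero):
        warnings.warn("voxels with zero mean and zero variance set to t = 0",
                      RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(zero, 0.0, t)
    return t, n - 1


def extent_filter(volume, k: int, connectivity: int = 18):
    """Remove connected components smaller than ``k`` voxels.

    ``connectivity`` counts the voxel neighbourhood: 6 (faces),
    18 (faces + edges) or 26 (faces + edges + corners).
    """
    if k < 1:
        raise ValueError("extent threshold k must be >= 1")
    if connectivity not in _CONNECTIVITY_STEPS:
        raise ValueError("connectivity must be one of 6, 18, 26")
    vol = np.asarray(volume, dtype=bool)
    if not vol.any() or k == 1:
        return vol.copy()
    labels = cc_label(vol, connectivity=_CONNECTIVITY_STEPS[connectivity])
    sizes = np.bincount(labels.ravel())
    keep = sizes >= k
    keep[0] = False
    return keep[labels]


def fwe_threshold_masks(tmap, df, mask, alpha: float = 0.05, k: int = 10,
                        method: str = "bonferroni", connectivity: int = 18):
    """Threshold a group t map into positive and negative survivor masks.

    A voxel survives if its one-sided p value is below ``alpha / V``
    (Bonferroni over the V mask voxels); survivors are split by sign and
    extent-filtered at ``k`` voxels.  Returns flat boolean arrays
    ``(j_plus, j_minus)`` over the mask voxels.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if method != "bonferroni":
        raise ValueError(f"unknown FWE method {method!r}")
    mask = np.asarray(mask, dtype=bool)
    v_total = int(mask.sum())
    if v_total == 0:
        raise ValueError("empty analysis mask")
    tmap = np.asarray(tmap, dtype=float)
    if tmap.shape != (v_total,):
        raise ValueError("t map must be flat over the mask voxels")
    cutoff = alpha / v_total
    pos = sps.t.sf(tmap, df) < cutoff
    neg = sps.t.sf(-tmap, df) < cutoff

    out = []
    for flat in (pos, neg):
        vol = np.zeros(mask.shape, dtype=bool)
        vol[mask] = flat
        out.append(extent_filter(vol, k, connectivity)[mask])
    return out[0], out[1]


def build_reference(maps, contrast, alpha: float = 0.05, k: int = 10,
                    method: str = "bonferroni",
                    connectivity: int = 18) -> YoungReference:
    """Build the young-adult reference for one contrast.

    ``beta_hat`` and ``sigma_hat`` (n-1 denominator) are computed from
    the young contrast estimates over the full mask; J+/J- come from the
    thresholded group t map.  An empty J+ is an error (FADE and SAME are
    undefined without a positive reference); an empty J- is tolerated
    with a warning and flagged in ``params`` — the SAME score then uses
    its activation term only.
    """
    t, df = group_one_sample_t(maps, contrast)
    G, mask = _stack_gammas(maps, contrast)
    j_plus, j_minus = fwe_threshold_masks(
        t, df, mask, alpha=alpha, k=k, method=method, connectivity=connectivity)
    if not j_plus.any():
        raise ValueError(
            f"no significant positive voxels for contrast {contrast!r}; "
            "FADE/SAME scores are undefined without J+")
    empty_minus = not j_minus.any()
    if empty_minus:
        warnings.warn(
            f"no significant negative voxels for contrast {contrast!r}; "
            "SAME scores will use the activation term only",
            RuntimeWarning, stacklevel=2)
    params = {
        "alpha": alpha, "k": k, "method": method,
        "connectivity": connectivity, "n_young": G.shape[0], "df": df,
        "empty_j_minus": empty_minus,
    }
    return YoungReference(
        contrast=contrast, mask=mask, j_plus=j_plus, j_minus=j_minus,
        beta_hat=G.mean(axis=0), sigma_hat=G.std(axis=0, ddof=1),
        params=params)
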