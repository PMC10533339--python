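"""First-level GLM for the visual memory encoding task.

The encoding task shows novel scene images interleaved with two highly
pre-familiarized "master" images.  About 70 minutes later, subjects rate
each image in a surprise recognition test on a 5-point scale from 1
("definitely new") to 5 ("definitely old").  Two per-subject contrasts
are derived from a voxel-wise ordinary-least-squares fit:

* **novelty** — novel minus master images, indexing novelty processing;
* **memory** — the slope of a parametric modulator that weights each
  novel-image response by the arcsine-transformed recognition rating
  (the classic subsequent-memory effect).

Regressors are boxcars convolved with a canonical double-gamma
haemodynamic response function; slow drifts are absorbed by a linear
term plus a discrete-cosine set below 1/128 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "NOVEL",
    "MASTER",
    "TrialEvents",
    "BoldRun",
    "DesignMatrix",
    "ContrastMaps",
    "arcsine_modulator",
    "canonical_hrf",
    "build_design_matrix",
    "fit_first_level",
]

NOVEL = "novel"
MASTER = "master"

#: Contrast weights, as {column: weight}, applied to the design columns.
DEFAULT_CONTRASTS = {
    "novelty": {NOVEL: 1.0, MASTER: -1.0},
    "memory": {"novel_x_memory": 1.0},
}


def arcsine_modulator(rating):
    """Map a recognition rating r in {1..5} to ``arcsin((r - 3) / 2)``.

    The affine pre-map centres the scale at the neutral rating 3 and
    stretches the extremes, so ratings 1..5 land symmetrically on
    [-pi/2, pi/2].  Odd-symmetric about rating 3.

    Parameters
    ----------
    rating : int or array-like of int
        Recognition-confidence rating(s), each in 1..5.

    Returns
    -------
    float or ndarray
    """
    r = np.asarray(rating, dtype=float)
    if r.size == 0:
        raise ValueError("empty rating input")
    if not np.all(np.isfinite(r)) or np.any((r < 1) | (r > 5)):
        raise ValueError("ratings must be finite and within 1..5")
    out = np.arcsin((r - 3.0) / 2.0)
    if np.isscalar(rating) or np.ndim(rating) == 0:
        return float(out)
    return out


def canonical_hrf(t, peak_delay=6.0, undershoot_delay=16.0,
                  peak_disp=1.0, undershoot_disp=1.0, ratio=1.0 / 6.0):
    """Canonical double-gamma haemodynamic response sampled at times ``t``.

    Difference of two gamma densities (shape = delay/dispersion,
    scale = dispersion); with the default parameters the response peaks
    about 5 s after stimulus onset and shows a late undershoot.  The
    kernel is normalized to unit peak.
    """
    t = np.asarray(t, dtype=float)
    peak = sps.gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    under = sps.gamma.pdf(t, undershoot_delay / undershoot_disp,
                          scale=undershoot_disp)
    h = peak - ratio * under
    m = np.max(np.abs(h))
    if m > 0:
        h = h / m
    return h


@dataclass
class TrialEvents:
    """Trial onsets, durations, conditions and recognition ratings.

    Master trials carry no rating (NaN); every novel trial must have a
    rating in 1..5.  Onsets are in seconds, non-negative and sorted.
    """

    onset: np.ndarray
    duration: np.ndarray
    condition: np.ndarray
    rating: np.ndarray

    def __post_init__(self):
        self.onset = np.asarray(self.onset, dtype=float)
        self.duration = np.asarray(self.duration, dtype=float)
        self.condition = np.asarray(self.condition, dtype=object)
        self.rating = np.asarray(self.rating, dtype=float)
        n = self.onset.size
        if not (self.duration.size == self.condition.size == self.rating.size == n):
            raise ValueError("event fields must have equal length")
        if n == 0:
            raise ValueError("no trials")
        if np.any(self.onset < 0) or np.any(np.diff(self.onset) < 0):
            raise ValueError("onsets must be non-negative and sorted")
        if np.any(self.duration <= 0):
            raise ValueError("durations must be positive")
        bad = set(self.condition) - {NOVEL, MASTER}
        if bad:
            raise ValueError(f"unknown trial condition(s): {sorted(bad)}")
        novel = self.condition == NOVEL
        r = self.rating[novel]
        if np.any(~np.isfinite(r)):
            raise ValueError("every novel trial needs a recognition rating")
        if np.any((r < 1) | (r > 5)):
            raise ValueError("ratings must lie in 1..5")

    @property
    def n_trials(self) -> int:
        return int(self.onset.size)

    @property
    def end_time(self) -> float:
        """Time at which the last trial ends (seconds)."""
        return float(np.max(self.onset + self.duration))

    def to_dataframe(self) -> pd.DataFrame:
        """BIDS-style events table (onset, duration, trial_type, rating)."""
        return pd.DataFrame({
            "onset": self.onset,
            "duration": self.duration,
            "trial_type": self.condition.astype(str),
            "rating": self.rating,
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TrialEvents":
        return cls(onset=df["onset"].to_numpy(),
                   duration=df["duration"].to_numpy(),
                   condition=df["trial_type"].to_numpy(),
                   rating=df["rating"].to_numpy())

    @classmethod
    def from_tsv(cls, path) -> "TrialEvents":
        return cls.from_dataframe(pd.read_csv(path, sep="\t"))


@dataclass
class BoldRun:
    """A masked BOLD run: ``data`` is voxels x scans, mask a boolean volume."""

    data: np.ndarray
    tr: float
    mask: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise ValueError("BOLD data must be voxels x scans with >= 2 scans")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if int(self.mask.sum()) != self.data.shape[0]:
            raise ValueError("mask voxel count must equal number of data rows")

    @property
    def n_scans(self) -> int:
        return int(self.data.shape[1])


@dataclass
class DesignMatrix:
    """Named design columns sampled at scan times."""

    values: np.ndarray
    columns: list
    tr: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column names do not match design width")
        if "intercept" not in self.columns:
            raise ValueError("design must contain an intercept")

    @property
    def n_scans(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_columns(self) -> int:
        return int(self.values.shape[1])

    def column_index(self, name: str) -> int:
        try:
            return self.columns.index(name)
        except ValueError:
            raise KeyError(f"no design column named {name!r}") from None

    def contrast_vector(self, weights: dict) -> np.ndarray:
        c = np.zeros(self.n_columns)
        for name, w in weights.items():
            c[self.column_index(name)] = w
        return c


@dataclass
class ContrastMaps:
    """Per-subject contrast estimates (gamma) and t values over a mask.

    ``gamma[c]`` and ``t[c]`` are flat arrays over the ``mask`` voxels
    for each contrast name c.
    """

    subject_id: str
    mask: np.ndarray
    gamma: dict
    t: dict
    group: str = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        v = int(self.mask.sum())
        for name, d in (("gamma", self.gamma), ("t", self.t)):
            for c, arr in d.items():
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (v,):
                    raise ValueError(
                        f"{name}[{c!r}] must have one value per mask voxel")
                if not np.all(np.isfinite(arr)):
                    raise ValueError(f"{name}[{c!r}] contains non-finite values")
                d[c] = arr

    @property
    def contrasts(self):
        return sorted(self.gamma)

    def volume(self, kind: str, contrast: str) -> np.ndarray:
        """Embed a flat map back into the mask volume (zeros outside)."""
        src = {"gamma": self.gamma, "t": self.t}[kind][contrast]
        vol = np.zeros(self.mask.shape)
        vol[self.mask] = src
        return vol


def _boxcar(onsets, durations, dt, n_fine, weights=None):
    x = np.zeros(n_fine)
    w = np.ones(len(onsets)) if weights is None else weights
    for o, d, a in zip(onsets, durations, w):
        i0 = int(np.round(o / dt))
        i1 = int(np.round((o + d) / dt))
        x[i0:min(i1, n_fine)] += a
    return x


def build_design_matrix(events: TrialEvents, tr: float, n_scans: int,
                        oversample: int = 16, highpass: float = 128.0,
                        modulator=arcsine_modulator) -> DesignMatrix:
    """Build the encoding-task design matrix.

    Columns: ``master`` and ``novel`` condition boxcars convolved with
    the canonical HRF; ``novel_x_memory`` — the novel boxcar weighted by
    the mean-centred modulator of each trial's recognition rating, then
    convolved; a linear drift plus discrete cosines below
    ``1/highpass`` Hz; and an intercept.

    The modulator is mean-centred over novel trials *before*
    convolution, which decorrelates the memory regressor from the main
    novelty effect and makes the memory contrast invariant to adding a
    constant to all modulator values.
    """
    if n_scans < 2:
        raise ValueError("need at least 2 scans")
    run_end = n_scans * tr
    if events.end_time > run_end + 1e-9:
        raise ValueError(
            f"events end at {events.end_time:.1f}s, beyond run end {run_end:.1f}s")
    for cond in (MASTER, NOVEL):
        if not np.any(events.condition == cond):
            raise ValueError(f"no {cond!r} trials in events")

    dt = tr / oversample
    n_fine = n_scans * oversample
    hrf = canonical_hrf(np.arange(0, 32.0 + dt, dt))

    novel = events.condition == NOVEL
    master = events.condition == MASTER
    mod_vals = np.asarray([modulator(r) for r in events.rating[novel]], float)
    mod_vals = mod_vals - mod_vals.mean()

    cols, names = [], []
    for name, sel, weights in (
            (MASTER, master, None),
            (NOVEL, novel, None),
            ("novel_x_memory", novel, mod_vals)):
        fine = _boxcar(events.onset[sel], events.duration[sel], dt, n_fine,
                       weights)
        conv = np.convolve(fine, hrf)[:n_fine]
        cols.append(conv[::oversample])
        names.append(name)

    # drift: linear + DCT-II cosine set strictly below 1/highpass Hz
    t_total = n_scans * tr
    cols.append(np.linspace(-1.0, 1.0, n_scans))
    names.append("drift_linear")
    n_cos = int(np.floor(2.0 * t_total / highpass - 1e-9))
    i = np.arange(n_scans)
    for k in range(1, n_cos + 1):
        cols.append(np.cos(np.pi * k * (2 * i + 1) / (2 * n_scans)))
        names.append(f"drift_cos{k}")
    cols.append(np.ones(n_scans))
    names.append("intercept")

    return DesignMatrix(values=np.column_stack(cols), columns=names, tr=tr)


def fit_first_level(bold: BoldRun, design: DesignMatrix,
                    subject_id: str = "sub", group: str = None,
                    contrasts: dict = None) -> ContrastMaps:
    """Voxel-wise OLS fit and contrast extraction.

    For each contrast vector c, gamma = c'beta_hat and
    t = gamma / sqrt(sigma2_hat * c' (X'X)^-1 c) with residual degrees
    of freedom n_scans - n_columns.
    """
    if contrasts is None:
        contrasts = DEFAULT_CONTRASTS
    X = design.values
    if bold.n_scans != design.n_scans:
        raise ValueError("scan count mismatch between BOLD run and design")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    df = X.shape[0] - X.shape[1]
    if df <= 0:
        raise ValueError("non-positive residual degrees of freedom")

    Y = bold.data.T  # scans x voxels
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    xtx_inv = pinv @ pinv.T

    gamma, tval = {}, {}
    for name, weights in contrasts.items():
        c = design.contrast_vector(weights)
        g = c @ beta
        var = sigma2 * float(c @ xtx_inv @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = g / np.sqrt(var)
        t = np.where(np.isfinite(t), t, 0.0)
        gamma[name] = g
        tval[name] = t

    return ContrastMaps(subject_id=subject_id, mask=bold.mask,
                        gamma=gamma, t=tval, group=group)
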