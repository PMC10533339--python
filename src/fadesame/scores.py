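"""Single-value memory scores: A', FADE and SAME.

A' is the area under the recognition ROC built from 5-point
confidence-rating counts for old and new items: with hit rate
H(t) and false-alarm rate FA(t) defined as the proportion of old and
new items rated strictly above threshold t (t = 0..5), A' is the
trapezoidal area under the six-point polygon (FA(t), H(t)).  A' = 0.5
is chance, A' = 1 perfect recognition.

Given a young-adult reference for the same contrast, per-subject fMRI
scores are

* ``FADE_i = mean_{j not in J+} t_ij - mean_{j in J+} t_ij`` — the
  deviation of subject i's t map from the prototypical activation set;
  lower values are more young-like;
* ``SAME_i = mean_{j in J+} (gamma_ij - beta_j) / sigma_j
  + mean_{j in J-} (beta_j - gamma_ij) / sigma_j`` — the average
  standardized deviation of the subject's contrast estimates from the
  young-group mean over activations and deactivations; higher values
  are more young-like, and a subject identical to the young mean scores
  exactly 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference import YoungReference, build_reference

__all__ = [
    "RatingCounts",
    "hit_fa_rates",
    "a_prime",
    "fade_score",
    "same_score",
    "score_cohort",
    "SCORE_COLUMNS",
]

SCORE_COLUMNS = ["subject_id", "group", "a_prime",
                 "fade_novelty", "same_novelty", "fade_memory", "same_memory"]

#: Voxels whose young-group s.d. falls below this are excluded from SAME sums.
SIGMA_FLOOR = 1e-12


@dataclass
class RatingCounts:
    """Counts of old and new items per recognition rating bin 1..5."""

    old_counts: np.ndarray
    new_counts: np.ndarray

    def __post_init__(self):
        for name in ("old_counts", "new_counts"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (5,):
                raise ValueError(f"{name} must have 5 rating bins")
            if np.any(arr < 0) or not np.all(arr == np.floor(arr)):
                raise ValueError(f"{name} must be non-negative integers")
            setattr(self, name, arr.astype(np.int64))

    @property
    def n_old(self) -> int:
        return int(self.old_counts.sum())

    @property
    def n_new(self) -> int:
        return int(self.new_counts.sum())


def hit_fa_rates(counts: RatingCounts) -> np.ndarray:
    """ROC points (FA(t), H(t)) for thresholds t = 5 down to 0.

    H(t) is the proportion of old items rated strictly above t, FA(t)
    the same for new items, so the sequence runs from (0, 0) at t = 5 to
    (1, 1) at t = 0 with both coordinates non-decreasing.

    Returns an array of shape (6, 2) with columns (FA, H).
    """
    if counts.n_old == 0 or counts.n_new == 0:
        raise ValueError("hit/false-alarm rates undefined without both "
                         "old and new items")
    # cumulative counts above threshold t, for t = 5..0
    h = np.concatenate([[0], np.cumsum(counts.old_counts[::-1])]) / counts.n_old
    fa = np.concatenate([[0], np.cumsum(counts.new_counts[::-1])]) / counts.n_new
    return np.column_stack([fa, h])


def a_prime(counts: RatingCounts) -> float:
    """Area under the six-point recognition ROC polygon (trapezoidal)."""
    pts = hit_fa_rates(counts)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def fade_score(t_map, reference: YoungReference) -> float:
    """FADE: mean t outside J+ minus mean t inside J+ (lower = young-like).

    "Outside" means the analysis-mask voxels not in J+, not the whole
    volume.  Invariant under adding a constant to every voxel.
    """
    t_map = np.asarray(t_map, dtype=float)
    v_total = int(reference.mask.sum())
    if t_map.shape != (v_total,):
        raise ValueError("subject t map must be flat over the reference mask")
    inside = reference.j_plus
    if not inside.any():
        raise ValueError("empty J+: FADE undefined")
    outside = ~inside
    if not outside.any():
        raise ValueError("J+ covers the whole mask: FADE undefined")
    return float(t_map[outside].mean() - t_map[inside].mean())


def same_score(gamma_map, reference: YoungReference) -> float:
    """SAME: mean standardized similarity to the young group.

    Activation term: mean over J+ of (gamma - beta_hat) / sigma_hat.
    Deactivation term: mean over J- of (beta_hat - gamma) / sigma_hat.
    If J- is empty the score is the activation term alone (flagged at
    reference construction).  Voxels with degenerate young-group s.d.
    (below ``SIGMA_FLOOR``) are excluded from the sums with a warning.
    """
    gamma_map = np.asarray(gamma_map, dtype=float)
    v_total = int(reference.mask.sum())
    if gamma_map.shape != (v_total,):
        raise ValueError("subject map must be flat over the reference mask")
    if not reference.j_plus.any() and not reference.j_minus.any():
        raise ValueError("both J+ and J- empty: SAME undefined")
    good = reference.sigma_hat > SIGMA_FLOOR
    n_bad = int(((reference.j_plus | reference.j_minus) & ~good).sum())
    if n_bad:
        warnings.warn(f"excluding {n_bad} voxel(s) with degenerate young-group "
                      "s.d. from SAME sums", RuntimeWarning, stacklevel=2)
    dev = np.zeros_like(gamma_map)
    np.divide(gamma_map - reference.beta_hat, reference.sigma_hat,
              out=dev, where=good)
    total = 0.0
    jp = reference.j_plus & good
    if jp.any():
        total += dev[jp].mean()
    jm = reference.j_minus & good
    if jm.any():
        total += (-dev[jm]).mean()
    return float(total)


def _score_one(maps, references) -> dict:
    out = {}
    for contrast, ref in references.items():
        out[f"fade_{contrast}"] = fade_score(maps.t[contrast], ref)
        out[f"same_{contrast}"] = same_score(maps.gamma[contrast], ref)
    return out


def score_cohort(maps, ratings=None, references=None,
                 contrasts=("novelty", "memory"),
                 young_mode: str = "in_sample",
                 reference_params: dict = None) -> pd.DataFrame:
    """Score every subject in a cohort.

    Parameters
    ----------
    maps : sequence of ContrastMaps
        One entry per subject with ``group`` set to "young" or "older".
    ratings : dict, optional
        ``subject_id -> RatingCounts``; subjects without ratings get a
        missing A'.
    references : dict, optional
        ``contrast -> YoungReference``.  Built from the young subjects'
        maps when omitted.
    young_mode : {"in_sample", "leave_one_out"}
        Whether a young subject is scored against the reference that
        includes them, or against a reference rebuilt without them.
        Older subjects are always scored against the full young
        reference.

    Returns
    -------
    DataFrame with columns ``subject_id, group, a_prime, fade_novelty,
    same_novelty, fade_memory, same_memory``.
    """
    if young_mode not in ("in_sample", "leave_one_out"):
        raise ValueError("young_mode must be 'in_sample' or 'leave_one_out'")
    ratings = ratings or {}
    reference_params = reference_params or {}
    young = [m for m in maps if m.group == "young"]
    if references is None:
        if not young:
            raise ValueError("no young subjects to build a reference from")
        references = {c: build_reference(young, c, **reference_params)
                      for c in contrasts}

    rows = []
    for m in maps:
        if m.group == "young" and young_mode == "leave_one_out":
            others = [y for y in young if y.subject_id != m.subject_id]
            refs = {c: build_reference(others, c, **reference_params)
                    for c in references}
        else:
            refs = references
        row = {"subject_id": m.subject_id, "group": m.group}
        rc = ratings.get(m.subject_id)
        row["a_prime"] = a_prime(rc) if rc is not None else np.nan
        row.update(_score_one(m, refs))
        rows.append(row)
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)
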