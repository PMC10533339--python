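"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a two-group encoding study: a young reference
group and an older group whose memory-network (de)activations are
attenuated.  A latent per-subject *network integrity* variable drives
everything that should covary:

* contrast maps — each contrast has a prototype pattern (+1 over an
  "activation" voxel set, -1 over a "deactivation" set); a subject's
  gamma map is the prototype scaled by their integrity plus i.i.d.
  Gaussian noise.  Young subjects sit at the integrity ceiling (1.0);
  older subjects' integrity is Normal(attenuation_older,
  integrity_sd^2), so their group-mean map is the prototype shrunk by
  the attenuation factor;
* recognition ratings — drawn from an equal-variance signal-detection
  model with per-subject d' = dprime_base + dprime_per_integrity *
  integrity, binned by four ordered criteria into the 1..5 scale
  (88 old / 44 new items by default);
* Openness — correlated with integrity at ``openness_integrity_r`` in
  the older group only; young Openness is independent noise.  All other
  demographic and personality columns are cosmetic draws with
  realistic group means and spreads.

The planted latent variables are kept in ``CohortBundle.ground_truth``
so recovery tests can compare estimates against what was simulated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .glm import NOVEL, MASTER, BoldRun, TrialEvents, build_design_matrix, \
    ContrastMaps
from .scores import RatingCounts

__all__ = [
    "SimulationConfig",
    "CohortBundle",
    "generate_cohort",
    "generate_ratings_from_dprime",
    "generate_subject_bold",
    "generate_trial_events",
    "simulate_mediation_cohort",
]

CONTRASTS = ("novelty", "memory")

# Group-level descriptive constants used for the cosmetic columns
# (means / s.d. of demographics and Big Five sums on the 0-48 scale).
_DEMOGRAPHICS = {
    "young": dict(age=(24.30, 3.29), mwtb=(26.73, 3.15), p_female=112 / 209,
                  p_abitur=203 / 209, neuroticism=(28.53, 6.39),
                  extraversion=(42.33, 5.35), openness=(43.14, 5.74),
                  agreeableness=(46.17, 5.40), conscientiousness=(45.66, 6.09)),
    "older": dict(age=(63.80, 6.68), mwtb=(30.20, 3.26), p_female=87 / 143,
                  p_abitur=65 / 143, neuroticism=(27.09, 5.34),
                  extraversion=(40.01, 4.82), openness=(40.97, 4.51),
                  agreeableness=(45.61, 4.38), conscientiousness=(47.50, 5.25)),
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic two-group cohort.

    ``attenuation_older`` is the mean integrity of the older group
    relative to the young ceiling of 1; ``integrity_sd`` its spread.
    ``openness_integrity_r`` is the planted Openness-integrity
    correlation in the older group.  ``dprime_base`` and
    ``dprime_per_integrity`` map integrity onto recognition
    discriminability.  ``smooth_noise_fwhm`` (voxels) optionally adds
    spatial autocorrelation to the map noise for cluster-inference
    simulations; the default is unsmoothed noise.
    """

    n_young: int = 209
    n_older: int = 143
    grid_shape: tuple = (16, 16, 12)
    n_active_voxels: int = 200
    n_deactive_voxels: int = 120
    attenuation_older: float = 0.8
    integrity_sd: float = 0.12
    openness_integrity_r: float = 0.3
    dprime_base: float = -0.2
    dprime_per_integrity: float = 1.5
    n_old_items: int = 88
    n_new_items: int = 44
    noise_sd: float = 0.5
    smooth_noise_fwhm: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_young", "n_older", "n_active_voxels",
                     "n_deactive_voxels", "n_old_items", "n_new_items"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive count")
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        if len(self.grid_shape) != 3 or any(v <= 0 for v in self.grid_shape):
            raise ValueError("grid_shape must be three positive voxel counts")
        volume = int(np.prod(self.grid_shape))
        if volume < self.n_active_voxels + self.n_deactive_voxels:
            raise ValueError(
                f"grid volume {volume} is too small for "
                f"{self.n_active_voxels} active + {self.n_deactive_voxels} "
                "deactive voxels")
        if not 0 <= self.attenuation_older <= 1:
            raise ValueError("attenuation_older must lie in [0, 1]")
        if self.integrity_sd <= 0 or self.noise_sd < 0:
            raise ValueError("integrity_sd must be positive and noise_sd "
                             "non-negative")
        if not -1 <= self.openness_integrity_r <= 1:
            raise ValueError("openness_integrity_r must lie in [-1, 1]")


@dataclass
class CohortBundle:
    """Everything generate_cohort produces.

    ``subjects`` is the demographic/personality table, ``maps`` the
    per-subject contrast maps, ``ratings`` maps subject id to
    recognition rating counts, and ``ground_truth`` keeps the planted
    latent variables and prototypes for recovery tests.
    """

    subjects: pd.DataFrame
    maps: list
    ratings: dict
    ground_truth: dict

    def __post_init__(self):
        ids = set(self.subjects["subject_id"])
        if len(ids) != len(self.subjects):
            raise ValueError("duplicate subject ids")
        if {m.subject_id for m in self.maps} != ids:
            raise ValueError("one map set per subject row required")
        if set(self.ratings) != ids:
            raise ValueError("one rating set per subject row required")


def generate_ratings_from_dprime(dprime: float, criteria, n_old: int,
                                 n_new: int, seed=None) -> RatingCounts:
    """Recognition rating counts from an equal-variance SDT model.

    New-item memory strength is Normal(0, 1) and old-item strength
    Normal(dprime, 1); the four strictly increasing ``criteria``
    partition the strength axis into the five rating bins.
    """
    criteria = np.asarray(criteria, dtype=float)
    if criteria.shape != (4,) or np.any(np.diff(criteria) <= 0):
        raise ValueError("criteria must be 4 strictly increasing values")
    if n_old <= 0 or n_new <= 0:
        raise ValueError("item counts must be positive")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    old = rng.normal(dprime, 1.0, n_old)
    new = rng.normal(0.0, 1.0, n_new)
    old_counts = np.bincount(np.searchsorted(criteria, old), minlength=5)
    new_counts = np.bincount(np.searchsorted(criteria, new), minlength=5)
    return RatingCounts(old_counts=old_counts, new_counts=new_counts)


def default_criteria(dprime: float) -> np.ndarray:
    """Symmetric rating criteria centred between the two strength means."""
    return dprime / 2.0 + np.array([-1.5, -0.5, 0.5, 1.5])


def _nearest_blob(coords, center, n, exclude=None):
    """Indices of the n voxels nearest to center (a compact blob)."""
    d = ((coords - center) ** 2).sum(axis=1)
    order = np.argsort(d, kind="stable")
    if exclude is not None:
        order = order[~exclude[order]]
    if order.size < n:
        raise ValueError("grid too small for the requested blob")
    return order[:n]


def _noise(rng, shape, sd, fwhm):
    eps = rng.normal(0.0, 1.0, shape)
    if fwhm > 0:
        sigma = fwhm / 2.3548
        eps = gaussian_filter(eps, sigma)
        eps /= eps.std() if eps.std() > 0 else 1.0
    return sd * eps


def generate_cohort(config: SimulationConfig) -> CohortBundle:
    """Generate a full synthetic cohort; bitwise reproducible per seed."""
    rng = np.random.default_rng(config.seed)
    shape = config.grid_shape
    volume = int(np.prod(shape))
    mask = np.ones(shape, dtype=bool)

    # per-contrast prototype patterns: compact +1 activation and -1
    # deactivation blobs (contiguous, so extent thresholds behave like
    # they do on smoothed group maps)
    coords = np.indices(shape).reshape(3, -1).T
    prototypes = {}
    for contrast in CONTRASTS:
        center_act = np.array([rng.integers(0, s) for s in shape])
        active = _nearest_blob(coords, center_act, config.n_active_voxels)
        taken = np.zeros(volume, dtype=bool)
        taken[active] = True
        d_act = ((coords - center_act) ** 2).sum(axis=1)
        center_deact = coords[np.argmax(d_act)]
        deactive = _nearest_blob(coords, center_deact,
                                 config.n_deactive_voxels, exclude=taken)
        proto = np.zeros(volume)
        proto[active] = 1.0
        proto[deactive] = -1.0
        prototypes[contrast] = proto

    n_total = config.n_young + config.n_older
    groups = ["young"] * config.n_young + ["older"] * config.n_older
    ids = [f"sub-{i + 1:03d}" for i in range(n_total)]

    z_int = rng.normal(0.0, 1.0, config.n_older)
    integrity = np.concatenate([
        np.ones(config.n_young),
        config.attenuation_older + config.integrity_sd * z_int])

    # Openness: coupled to integrity in older adults only
    r = config.openness_integrity_r
    eps_open = rng.normal(0.0, 1.0, n_total)
    open_z = eps_open.copy()
    open_z[config.n_young:] = (r * z_int
                               + np.sqrt(max(0.0, 1 - r ** 2))
                               * eps_open[config.n_young:])

    rows = []
    for i, (sid, grp) in enumerate(zip(ids, groups)):
        d = _DEMOGRAPHICS[grp]
        row = {"subject_id": sid, "group": grp,
               "age": rng.normal(*d["age"]),
               "gender": int(rng.random() < d["p_female"]),
               "education": int(rng.random() < d["p_abitur"]),
               "mwtb": rng.normal(*d["mwtb"])}
        for trait in ("neuroticism", "extraversion", "agreeableness",
                      "conscientiousness"):
            row[trait] = float(np.clip(rng.normal(*d[trait]), 0, 48))
        mu, sd = d["openness"]
        row["openness"] = float(np.clip(mu + sd * open_z[i], 0, 48))
        rows.append(row)
    subjects = pd.DataFrame(rows)

    se = config.noise_sd if config.noise_sd > 0 else 1.0
    maps, ratings = [], {}
    dprimes = (config.dprime_base
               + config.dprime_per_integrity * integrity)
    for i, (sid, grp) in enumerate(zip(ids, groups)):
        gamma, tval = {}, {}
        for contrast in CONTRASTS:
            g = integrity[i] * prototypes[contrast] \
                + _noise(rng, shape, config.noise_sd,
                         config.smooth_noise_fwhm).ravel()
            gamma[contrast] = g
            # nominal first-level t: contrast estimate over its noise s.d.
            tval[contrast] = g / se
        maps.append(ContrastMaps(subject_id=sid, mask=mask, gamma=gamma,
                                 t=tval, group=grp))
        ratings[sid] = generate_ratings_from_dprime(
            dprimes[i], default_criteria(dprimes[i]),
            config.n_old_items, config.n_new_items, seed=rng)

    ground_truth = {
        "config": dataclasses.asdict(config),
        "integrity": integrity,
        "dprime": dprimes,
        "openness_z": open_z,
        "prototypes": prototypes,
        "planted_openness_integrity_r": r,
    }
    return CohortBundle(subjects=subjects, maps=maps, ratings=ratings,
                        ground_truth=ground_truth)


def generate_trial_events(n_novel: int = 88, n_master: int = 44,
                          duration: float = 2.5, iti=(0.5, 1.8),
                          ratings=None, seed=None) -> TrialEvents:
    """Randomly interleaved novel/master trial sequence with jittered ITIs.

    ``ratings`` supplies recognition ratings for the novel trials (drawn
    uniformly from 1..5 when omitted).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    conds = np.array([NOVEL] * n_novel + [MASTER] * n_master, dtype=object)
    rng.shuffle(conds)
    n = conds.size
    gaps = rng.uniform(iti[0], iti[1], n)
    onsets = np.concatenate([[0.0], np.cumsum(duration + gaps)[:-1]])
    if ratings is None:
        ratings = rng.integers(1, 6, n_novel)
    rating_col = np.full(n, np.nan)
    rating_col[conds == NOVEL] = np.asarray(ratings, dtype=float)
    return TrialEvents(onset=onsets, duration=np.full(n, duration),
                       condition=conds, rating=rating_col)


def generate_subject_bold(events: TrialEvents, planted_betas: dict,
                          tr: float, n_scans: int, noise_sd: float,
                          seed=None, n_voxels: int = 1) -> BoldRun:
    """BOLD time series from planted design weights plus Gaussian noise.

    ``planted_betas`` maps design-column names to a scalar or a
    per-voxel array; unnamed columns get weight zero.  Events that
    extend beyond the run raise at design construction.
    """
    design = build_design_matrix(events, tr, n_scans)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    B = np.zeros((design.n_columns, n_voxels))
    for name, val in planted_betas.items():
        B[design.column_index(name)] = np.asarray(val, dtype=float)
    data = (design.values @ B).T
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, data.shape)
    mask = np.ones((n_voxels, 1, 1), dtype=bool)
    return BoldRun(data=data, tr=tr, mask=mask)


def simulate_mediation_cohort(a: float, b: float, c_prime: float, n: int,
                              seed=None):
    """Standardized trivariate Gaussian triples with planted paths.

    ``m = a*x + e1`` and ``y = c_prime*x + b*m + e2`` with noise scaled
    so x, m and y all have unit population variance; the population
    total effect is ``c = c_prime + a*b``.  Returns ``(x, m, y)``.
    """
    var_m = 1.0 - a ** 2
    var_y = 1.0 - c_prime ** 2 - b ** 2 - 2 * a * b * c_prime
    if var_m <= 0 or var_y <= 0:
        raise ValueError("planted paths imply non-positive noise variance")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, n)
    m = a * x + np.sqrt(var_m) * rng.normal(0.0, 1.0, n)
    y = c_prime * x + b * m + np.sqrt(var_y) * rng.normal(0.0, 1.0, n)
    return x, m, y
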