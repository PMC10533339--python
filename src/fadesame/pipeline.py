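"""End-to-end orchestration: simulate (or ingest) -> reference -> scores
-> statistics -> voxel-wise mapping, from one validated configuration.

A run writes, under its output directory: the resolved configuration
with the package version, the young-adult reference volumes, a
``scores.tsv`` and merged ``subjects_scored.tsv``, the four report
tables, cluster-inference outputs, a ``run.log`` and a deterministic
``summary.json`` with every headline statistic.  Any stage failure
leaves a ``FAILED`` marker naming the stage.  A single global seed fans
out to per-stage seeds through a counter-based spawn scheme so each
stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as fio
from .reference import build_reference
from .scores import score_cohort
from .simulate import SimulationConfig, generate_cohort
from .stats import build_table1, build_table2, build_table3, build_table4
from .voxelwise import cluster_fwe_permutation

__all__ = ["PipelineConfig", "run_pipeline", "make_fixtures"]

log = logging.getLogger("fadesame")

_REFERENCE_DEFAULTS = {"alpha": 0.05, "k": 10, "method": "bonferroni",
                       "connectivity": 18}
_MEDIATION_DEFAULTS = {"method": "delta", "n_boot": 1000}
_PERMUTATION_DEFAULTS = {"cluster_forming_p": 0.001, "n_perm": 500,
                         "connectivity": 18}


def _merge(defaults: dict, given: dict, where: str) -> dict:
    unknown = set(given) - set(defaults)
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")
    out = dict(defaults)
    out.update(given)
    return out


@dataclass
class PipelineConfig:
    """Validated run configuration; unknown keys are rejected."""

    mode: str = "simulate"
    seed: int = 0
    out_dir: str = "fadesame_out"
    force: bool = False
    young_mode: str = "in_sample"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    reference: dict = field(default_factory=lambda: dict(_REFERENCE_DEFAULTS))
    mediation: dict = field(default_factory=lambda: dict(_MEDIATION_DEFAULTS))
    permutation: dict = field(
        default_factory=lambda: dict(_PERMUTATION_DEFAULTS))
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("simulate", "ingest"):
            raise ValueError("mode must be 'simulate' or 'ingest'")
        if self.young_mode not in ("in_sample", "leave_one_out"):
            raise ValueError("young_mode must be 'in_sample' or "
                             "'leave_one_out'")
        self.reference = _merge(_REFERENCE_DEFAULTS, self.reference,
                                "reference")
        self.mediation = _merge(_MEDIATION_DEFAULTS, self.mediation,
                                "mediation")
        self.permutation = _merge(_PERMUTATION_DEFAULTS, self.permutation,
                                  "permutation")
        allowed_paths = {"maps_dir", "subjects_tsv", "ratings_tsv"}
        unknown = set(self.paths) - allowed_paths
        if unknown:
            raise ValueError(f"unknown key(s) in paths: {sorted(unknown)}")
        if self.mode == "ingest":
            missing = {"maps_dir", "subjects_tsv"} - set(self.paths)
            if missing:
                raise ValueError(f"ingest mode needs paths: {sorted(missing)}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        if "simulation" in d and not isinstance(d["simulation"],
                                                SimulationConfig):
            sim = dict(d["simulation"])
            sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
            bad = set(sim) - sim_known
            if bad:
                raise ValueError(
                    f"unknown key(s) in simulation: {sorted(bad)}")
            d["simulation"] = SimulationConfig(**sim)
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _stage_seed(seed: int, index: int) -> int:
    """Counter-based per-stage seed below 2**31."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _load_ingest(config: PipelineConfig):
    from .scores import RatingCounts  # noqa: F401  (type used by read_ratings)
    maps = fio.read_contrast_maps(config.paths["maps_dir"])
    subjects = pd.read_csv(config.paths["subjects_tsv"], sep="\t")
    by_id = dict(zip(subjects["subject_id"].astype(str), subjects["group"]))
    for m in maps:
        if m.group is None:
            m.group = by_id.get(m.subject_id)
    ratings = {}
    if "ratings_tsv" in config.paths:
        ratings = fio.read_ratings(config.paths["ratings_tsv"])
    return subjects, maps, ratings


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the output directory."""
    out = Path(config.out_dir)
    if out.exists() and (out / "summary.json").exists() and not config.force:
        raise FileExistsError(
            f"{out} already holds a completed run; pass force=True "
            "(or --force) to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "FAILED"
    if marker.exists():
        marker.unlink()

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s "
                                           "%(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    stage = "configure"
    try:
        resolved = config.to_dict()
        resolved["version"] = __version__
        fio.write_json(resolved, out / "config.json")
        log.info("fadesame %s; global seed %d", __version__, config.seed)
        log.info("reference thresholds: alpha=%(alpha)s k=%(k)s "
                 "method=%(method)s connectivity=%(connectivity)s",
                 config.reference)
        log.info("cluster inference: forming p=%(cluster_forming_p)s "
                 "n_perm=%(n_perm)s connectivity=%(connectivity)s",
                 config.permutation)

        stage = "cohort"
        if config.mode == "simulate":
            sim = dataclasses.replace(config.simulation,
                                      seed=_stage_seed(config.seed, 0))
            log.info("simulating cohort: %d young, %d older, grid %s",
                     sim.n_young, sim.n_older, sim.grid_shape)
            bundle = generate_cohort(sim)
            subjects, maps, ratings = bundle.subjects, bundle.maps, \
                bundle.ratings
            fio.write_json({"planted_openness_integrity_r":
                            bundle.ground_truth["planted_openness_integrity_r"]},
                           out / "ground_truth.json")
        else:
            log.info("ingesting maps from %s", config.paths["maps_dir"])
            subjects, maps, ratings = _load_ingest(config)

        stage = "reference"
        young = [m for m in maps if m.group == "young"]
        contrasts = maps[0].contrasts
        references = {c: build_reference(young, c, **config.reference)
                      for c in contrasts}
        ref_dir = out / "reference"
        for ref in references.values():
            log.info("reference %s: v+=%d, v-=%d", ref.contrast, ref.v_plus,
                     ref.v_minus)
            fio.write_reference(ref, ref_dir)

        stage = "scores"
        scores = score_cohort(maps, ratings=ratings, references=references,
                              young_mode=config.young_mode)
        scores.to_csv(out / "scores.tsv", sep="\t", index=False)
        merged = subjects.merge(scores.drop(columns=["group"]),
                                on="subject_id")
        merged.to_csv(out / "subjects_scored.tsv", sep="\t", index=False)

        stage = "statistics"
        med_seed = _stage_seed(config.seed, 1)
        t1 = build_table1(merged)
        t2 = build_table2(merged)
        t3 = build_table3(merged)
        t4 = build_table4(merged, method=config.mediation["method"],
                          n_boot=config.mediation["n_boot"], seed=med_seed)
        for name, tbl in (("table1_groups", t1), ("table2_correlations", t2),
                          ("table3_regression", t3),
                          ("table4_mediation", t4)):
            tbl.to_csv(out / f"{name}.tsv", sep="\t", index=False)

        stage = "voxelwise"
        older = [m for m in maps if m.group == "older"]
        older_tab = merged.set_index("subject_id").loc[
            [m.subject_id for m in older]]
        cluster_res = cluster_fwe_permutation(
            older, "memory", older_tab["openness"].to_numpy(),
            seed=_stage_seed(config.seed, 2), **config.permutation)
        cluster_res.clusters.to_csv(out / "clusters.tsv", sep="\t",
                                    index=False)
        stat_vol = np.zeros(cluster_res.mask.shape)
        stat_vol[cluster_res.mask] = cluster_res.stat_map
        fio.save_volume(stat_vol, out / "voxelwise_t.nii")
        fio.save_volume(cluster_res.cluster_labels.astype(np.float32),
                        out / "voxelwise_clusters.nii")
        log.info("voxelwise: %d supra-threshold cluster(s)",
                 len(cluster_res.clusters))

        stage = "summary"
        summary = _summarize(merged, t1, t2, t4, cluster_res, config)
        fio.write_json(summary, out / "summary.json")
        log.info("run complete")
    except Exception as exc:
        marker.write_text(f"stage: {stage}\nerror: {exc}\n")
        log.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


def _summarize(merged, t1, t2, t4, cluster_res, config) -> dict:
    def t1_row(var):
        row = t1[t1["variable"] == var].iloc[0]
        return {"young_mean": row["young_mean"], "older_mean":
                row["older_mean"], "statistic": row["statistic"],
                "p": row["p"]}

    def t2_r(measure, trait):
        sel = t2[(t2["group"] == "older") & (t2["measure"] == measure)
                 & (t2["trait"] == trait)].iloc[0]
        return {"r": sel["r"], "p": sel["p"]}

    med = {}
    for mediator in t4["mediator"].unique():
        sub = t4[t4["mediator"] == mediator].set_index("path")
        med[mediator] = {
            "total": sub.loc["total", "beta"],
            "indirect": sub.loc["indirect", "beta"],
            "direct": sub.loc["direct_x_to_y", "beta"],
            "p_indirect": sub.loc["indirect", "p"],
            "proportion_mediated": sub.loc["indirect", "proportion_mediated"],
        }
    clusters = cluster_res.clusters
    return {
        "n_young": int((merged["group"] == "young").sum()),
        "n_older": int((merged["group"] == "older").sum()),
        "group_differences": {v: t1_row(v) for v in
                              ("a_prime", "fade_memory", "same_memory",
                               "openness")},
        "older_openness_correlations": {
            m: t2_r(m, "openness") for m in
            ("a_prime", "fade_memory", "same_memory")},
        "mediation": med,
        "voxelwise": {
            "n_clusters": int(len(clusters)),
            "min_p_corrected": (float(clusters["p_corrected"].min())
                                if len(clusters) else None),
        },
        "seed": config.seed,
        "version": __version__,
    }


_FIXTURE_SIZES = {
    # tiny cohorts need low map noise: a 6-subject one-sample t must
    # still clear the Bonferroni threshold to yield a usable reference
    "tiny": dict(n_young=6, n_older=6, grid_shape=(8, 8, 4),
                 n_active_voxels=30, n_deactive_voxels=20, noise_sd=0.15),
    "small": dict(n_young=30, n_older=30, grid_shape=(16, 16, 16),
                  n_active_voxels=120, n_deactive_voxels=80),
}


def make_fixtures(size: str, seed: int, out_dir) -> Path:
    """Write a deterministic fixture cohort (maps, tables, checksums).

    ``tiny`` (8x8x4 grid, 12 subjects) suits unit tests; ``small``
    (16^3, 60 subjects) suits integration tests.  ``checksums.json``
    records a SHA-256 per written file so fixture stability across runs
    is verifiable.
    """
    if size not in _FIXTURE_SIZES:
        raise ValueError(f"size must be one of {sorted(_FIXTURE_SIZES)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=seed, **_FIXTURE_SIZES[size])
    bundle = generate_cohort(cfg)
    fio.write_contrast_maps(bundle.maps, out_dir / "maps")
    bundle.subjects.to_csv(out_dir / "subjects.tsv", sep="\t", index=False)
    fio.write_ratings(bundle.ratings, out_dir / "ratings.tsv")
    fio.write_json(dataclasses.asdict(cfg), out_dir / "config.json")

    checks = {}
    for path in sorted(out_dir.rglob("*")):
        if path.is_file() and path.name != "checksums.json":
            checks[str(path.relative_to(out_dir))] = hashlib.sha256(
                path.read_bytes()).hexdigest()
    fio.write_json(checks, out_dir / "checksums.json")
    return out_dir
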