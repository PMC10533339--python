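"""Reading and writing the pipeline's on-disk formats.

Volumes are NIfTI-1 (via nibabel); tables are TSV; parameters and
summaries are JSON.  Subject contrast maps follow the naming scheme
``{subject}_{contrast}_{gamma|t}.nii`` so a directory of maps can be
re-assembled without a manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .glm import ContrastMaps
from .reference import YoungReference
from .scores import RatingCounts

__all__ = [
    "DEFAULT_AFFINE",
    "save_volume",
    "load_volume",
    "write_contrast_maps",
    "read_contrast_maps",
    "write_reference",
    "read_reference",
    "write_ratings",
    "read_ratings",
    "write_json",
]

#: 3 mm isotropic voxels, origin at the corner — a stand-in affine for
#: synthetic grids without real-world geometry.
DEFAULT_AFFINE = np.diag([3.0, 3.0, 3.0, 1.0])


def save_volume(volume, path, affine=None) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32),
                          DEFAULT_AFFINE if affine is None else affine)
    nib.save(img, path)
    return path


def load_volume(path):
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                               default=_jsonify) + "\n")
    return path


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def write_contrast_maps(maps, out_dir, affine=None) -> Path:
    """Write per-subject gamma/t volumes plus the shared mask."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_volume(maps[0].mask.astype(np.float32), out_dir / "mask.nii", affine)
    groups = {}
    for m in maps:
        groups[m.subject_id] = m.group
        for contrast in m.contrasts:
            for kind in ("gamma", "t"):
                save_volume(m.volume(kind, contrast),
                            out_dir / f"{m.subject_id}_{contrast}_{kind}.nii",
                            affine)
    write_json(groups, out_dir / "groups.json")
    return out_dir


def read_contrast_maps(maps_dir) -> list:
    """Re-assemble ContrastMaps from a directory written by
    :func:`write_contrast_maps` (or hand-assembled to the same scheme)."""
    maps_dir = Path(maps_dir)
    mask, _ = load_volume(maps_dir / "mask.nii")
    mask = mask > 0.5
    groups_file = maps_dir / "groups.json"
    groups = json.loads(groups_file.read_text()) if groups_file.exists() else {}
    found = {}
    for path in sorted(maps_dir.glob("*_*_*.nii*")):
        stem = path.name.split(".nii")[0]
        subject, contrast, kind = stem.rsplit("_", 2)
        vol, _ = load_volume(path)
        found.setdefault(subject, {"gamma": {}, "t": {}})[kind][contrast] = \
            vol[mask]
    maps = []
    for subject in sorted(found):
        d = found[subject]
        maps.append(ContrastMaps(subject_id=subject, mask=mask,
                                 gamma=d["gamma"], t=d["t"],
                                 group=groups.get(subject)))
    return maps


def write_reference(ref: YoungReference, out_dir, affine=None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    c = ref.contrast
    save_volume(ref.mask.astype(np.float32), out_dir / f"{c}_mask.nii", affine)
    for name, flat in (("jplus", ref.j_plus), ("jminus", ref.j_minus),
                       ("betahat", ref.beta_hat), ("sigmahat", ref.sigma_hat)):
        save_volume(ref.to_volume(flat.astype(np.float32)),
                    out_dir / f"{c}_{name}.nii", affine)
    write_json(ref.params, out_dir / f"{c}_params.json")
    return out_dir


def read_reference(ref_dir, contrast) -> YoungReference:
    ref_dir = Path(ref_dir)
    mask, _ = load_volume(ref_dir / f"{contrast}_mask.nii")
    mask = mask > 0.5
    vols = {}
    for name in ("jplus", "jminus", "betahat", "sigmahat"):
        vol, _ = load_volume(ref_dir / f"{contrast}_{name}.nii")
        vols[name] = vol[mask]
    params = json.loads((ref_dir / f"{contrast}_params.json").read_text())
    return YoungReference(contrast=contrast, mask=mask,
                          j_plus=vols["jplus"] > 0.5,
                          j_minus=vols["jminus"] > 0.5,
                          beta_hat=vols["betahat"],
                          sigma_hat=vols["sigmahat"], params=params)


def write_ratings(ratings: dict, path) -> Path:
    """Rating counts as a TSV: subject_id, o1..o5, n1..n5."""
    rows = []
    for sid in sorted(ratings):
        rc = ratings[sid]
        row = {"subject_id": sid}
        row.update({f"o{i + 1}": int(rc.old_counts[i]) for i in range(5)})
        row.update({f"n{i + 1}": int(rc.new_counts[i]) for i in range(5)})
        rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_ratings(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, row in df.iterrows():
        out[str(row["subject_id"])] = RatingCounts(
            old_counts=[row[f"o{i + 1}"] for i in range(5)],
            new_counts=[row[f"n{i + 1}"] for i in range(5)])
    return out
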