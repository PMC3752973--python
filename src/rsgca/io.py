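"""File round-tripping: TSV cohorts, map tables, JSON results, optional NIfTI.

On-disk layout of a cohort directory::

    cohort.tsv              id, group, age, gender, dose, severity variables
    ground_truth.json       true group weight matrices, per-subject truth, seed
    series/<id>.tsv         timepoints x regions, tab-separated, header row
    confounds/<id>.tsv      timepoints x channels, header row

Values round-trip losslessly at float precision (written with repr-level
precision).  NIfTI writers exercise the imaging path: each region becomes a
small voxel block at its MNI coordinate on a coarse grid.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .connectivity import FCMap, PathCoefficientMap
from .simulate import SEVERITY_VARS, SubjectData

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_map_table",
    "read_map_table",
    "write_json",
    "sha256_file",
    "write_subject_nifti",
    "read_subject_nifti",
]

_FLOAT_FMT = "%.17g"


def write_cohort(subjects: list[SubjectData], out_dir: str | Path,
                 networks=None) -> Path:
    """Write a cohort directory (series, confounds, cohort table, ground truth)."""
    out = Path(out_dir)
    (out / "series").mkdir(parents=True, exist_ok=True)
    (out / "confounds").mkdir(exist_ok=True)
    rows = []
    truth = {"subjects": {}}
    for s in subjects:
        pd.DataFrame(s.series, columns=s.regions).to_csv(
            out / "series" / f"{s.id}.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT,
        )
        if s.confounds is not None:
            pd.DataFrame(s.confounds, columns=list(s.confound_names)).to_csv(
                out / "confounds" / f"{s.id}.tsv", sep="\t", index=False,
                float_format=_FLOAT_FMT,
            )
        row = {"id": s.id, "group": s.group, "age": s.age, "gender": s.gender,
               "dose": s.dose}
        for v in SEVERITY_VARS:
            row[v] = s.clinical.get(v, np.nan)
        rows.append(row)
        if s.truth:
            truth["subjects"][s.id] = _jsonable(s.truth)
    pd.DataFrame(rows).to_csv(out / "cohort.tsv", sep="\t", index=False,
                              float_format=_FLOAT_FMT)
    if networks is not None:
        truth["networks"] = {
            g: {
                "regions": n.names,
                "W": n.W.tolist(),
                "influence_lag": n.influence_lag,
                "innovation_sd": n.innovation_sd.tolist(),
                "innovation_corr": {f"{a}~{b}": v
                                    for (a, b), v in n.innovation_corr.items()},
                "edge_targets": {f"{e.src}->{e.dst}": e.beta
                                 for e in n.edge_targets},
            }
            for g, n in networks.items()
        }
    write_json(truth, out / "ground_truth.json")
    return out


def read_cohort(cohort_dir: str | Path) -> list[SubjectData]:
    """Read a cohort directory written by :func:`write_cohort`."""
    root = Path(cohort_dir)
    table_path = root / "cohort.tsv"
    if not table_path.exists():
        raise FileNotFoundError(f"no cohort table at {table_path}")
    table = pd.read_csv(table_path, sep="\t", float_precision="round_trip")
    required = {"id", "group", "age", "gender", "dose"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns: {sorted(missing)}")
    truth_path = root / "ground_truth.json"
    truth_all = (
        json.loads(truth_path.read_text()) if truth_path.exists() else {}
    )
    subjects = []
    for _, row in table.iterrows():
        sid = str(row["id"])
        series_path = root / "series" / f"{sid}.tsv"
        if not series_path.exists():
            raise FileNotFoundError(f"missing series file {series_path}")
        series = pd.read_csv(series_path, sep="\t", float_precision="round_trip")
        conf_path = root / "confounds" / f"{sid}.tsv"
        conf = (pd.read_csv(conf_path, sep="\t", float_precision="round_trip")
                if conf_path.exists() else None)
        clinical = {
            v: float(row[v]) for v in SEVERITY_VARS
            if v in table.columns and np.isfinite(row[v])
        }
        subjects.append(
            SubjectData(
                id=sid,
                group=str(row["group"]),
                series=series.to_numpy(dtype=float),
                regions=list(series.columns),
                age=float(row["age"]),
                gender=str(row["gender"]),
                dose=float(row["dose"]),
                clinical=clinical,
                confounds=None if conf is None else conf.to_numpy(dtype=float),
                confound_names=() if conf is None else tuple(conf.columns),
                truth=truth_all.get("subjects", {}).get(sid, {}),
            )
        )
    return subjects


def write_map_table(
    path: str | Path,
    gca: PathCoefficientMap | None = None,
    fc: FCMap | None = None,
) -> Path:
    """Per-subject map TSV: target, beta_xy, beta_yx, net, r, z, flags."""
    if gca is None and fc is None:
        raise ValueError("nothing to write")
    ref = gca if gca is not None else fc
    df = pd.DataFrame({"target": ref.targets})
    if gca is not None:
        df["beta_xy"] = gca.beta_xy
        df["beta_yx"] = gca.beta_yx
        df["net"] = gca.beta_xy - gca.beta_yx
    if fc is not None:
        df["r"] = fc.r
        df["z"] = fc.z
    flags = [""] * len(ref.targets)
    for src in (gca, fc):
        if src is not None:
            flags = [a or b for a, b in zip(flags, src.flags)]
    df["flags"] = flags
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return Path(path)


def read_map_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "target" not in df.columns:
        raise ValueError(f"{path} is not a map table (no 'target' column)")
    return df


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# NIfTI path: one voxel block per region at its MNI coordinate
# ---------------------------------------------------------------------------

_VOXEL_MM = 6.0
_BLOCK = 1  # half-width of the region block in voxels


def _grid_for_regions(mni: np.ndarray) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Affine and shape of a coarse grid covering all region coordinates."""
    lo = mni.min(axis=0) - 3 * _VOXEL_MM
    affine = np.diag([_VOXEL_MM, _VOXEL_MM, _VOXEL_MM, 1.0])
    affine[:3, 3] = lo
    span = np.ceil((mni.max(axis=0) - lo) / _VOXEL_MM).astype(int) + 4
    return affine, tuple(span)


def write_subject_nifti(
    subject: SubjectData,
    path: str | Path,
    parcel_path: str | Path | None = None,
    region_mni: dict[str, tuple[float, float, float]] | None = None,
) -> Path:
    """Write a subject as a 4D NIfTI with one voxel block per region.

    ``region_mni`` maps region names to MNI millimetre coordinates (defaults
    to the roster's coordinates when available via the parcel argument).  A
    parcel-label image (region index + 1) is written when ``parcel_path``
    is given.
    """
    from .networks import DEFAULT_REGIONS

    lookup = region_mni or {
        r.name: r.mni_mm for r in DEFAULT_REGIONS if r.mni_mm is not None
    }
    missing = [r for r in subject.regions if r not in lookup]
    if missing:
        raise ValueError(f"no MNI coordinate for regions: {missing}")
    mni = np.array([lookup[r] for r in subject.regions], dtype=float)
    affine, shape = _grid_for_regions(mni)
    inv = np.linalg.inv(affine)
    t = subject.series.shape[0]
    vol = np.zeros(shape + (t,), dtype=np.float64)
    labels = np.zeros(shape, dtype=np.int16)
    for i, coord in enumerate(mni):
        vx = np.round(inv @ np.append(coord, 1.0))[:3].astype(int)
        sl = tuple(slice(v - _BLOCK, v + _BLOCK + 1) for v in vx)
        vol[sl] = subject.series[:, i]
        labels[sl] = i + 1
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(vol, affine), str(path))
    if parcel_path is not None:
        nib.save(nib.Nifti1Image(labels, affine), str(parcel_path))
    return path


def read_subject_nifti(
    path: str | Path, parcel_path: str | Path, region_names: list[str]
) -> np.ndarray:
    """Mean series per parcel label (timepoints x regions)."""
    img = nib.load(str(path))
    vol = np.asanyarray(img.dataobj)
    labels = np.asanyarray(nib.load(str(parcel_path)).dataobj)
    out = np.empty((vol.shape[3], len(region_names)))
    for i in range(len(region_names)):
        m = labels == i + 1
        if not m.any():
            raise ValueError(f"parcel {i + 1} ({region_names[i]}) is empty")
        out[:, i] = vol[m].mean(axis=0)
    return out
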