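"""End-to-end orchestration: simulate/load -> preprocess -> maps -> inference.

``run_pipeline`` executes the whole analysis in the order of the emulated
study: cohort generation (or loading), time-series conditioning, per-subject
directed (GCA) and instantaneous (FC) seed maps, random-effects group
inference with permutation FWE control inside one-sample-derived search
masks, Bonferroni-corrected follow-ups, mediation of the diagnostic effect
on the seed -> DLPFC outflow by the aberrant-FC eigenvariate, and the
severity composite regression in patients.  Every artifact is written under
the output directory together with a JSON manifest (config, seeds, package
versions, per-file checksums) that makes a run reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import fc_map, pairwise_gca, seed_gca_map
from .group import (
    GroupDesign,
    eigenvariate,
    followup_tests,
    fwe_correct,
    mask_from_one_sample,
    one_sample_map,
    two_sample_map,
)
from .io import (
    read_cohort,
    sha256_file,
    write_cohort,
    write_json,
    write_map_table,
)
from .mediation import fit_mediation
from .networks import LOOP_PAIRS, VISUAL_INFLOW_EDGES
from .preprocess import PreprocConfig, preprocess_series
from .severity import build_composites, severity_regression
from .simulate import CohortConfig, SubjectData, simulate_cohort

logger = logging.getLogger("rsgca")

__all__ = ["RunConfig", "run_pipeline", "write_report", "read_cohort"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    mode: str = "simulate"  # {"simulate", "tsv-cohort"}
    cohort_dir: str | None = None  # input directory for tsv-cohort mode
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    seed_region: str = "rAI"
    outflow_target: str = "rDLPFC"
    n_perm: int = 5000
    alpha: float = 0.05
    extent_k: int = 30
    n_boot: int = 5000
    out_dir: str = "rsgca_out"
    rng_seed: int = 0
    log_level: str = "INFO"
    write_cohort_files: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.mode not in {"simulate", "tsv-cohort"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "tsv-cohort" and not self.cohort_dir:
            raise ValueError("tsv-cohort mode requires cohort_dir")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "cohort" in raw:
            raw["cohort"] = CohortConfig(**raw["cohort"])
        if "preproc" in raw:
            raw["preproc"] = PreprocConfig(**raw["preproc"])
        return cls(**raw)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def compute_subject_maps(
    clean: np.ndarray,
    regions: list[str],
    seed_region: str,
    subject_id: str = "",
    tr_s: float = 2.5,
):
    """Seed GCA and FC maps plus loop-pair coefficients for one subject."""
    s_ix = regions.index(seed_region)
    others = [r for r in regions if r != seed_region]
    o_ix = [regions.index(r) for r in others]
    gca = seed_gca_map(
        clean[:, s_ix], clean[:, o_ix], target_names=others,
        subject_id=subject_id, seed_name=seed_region, lag_seconds=tr_s,
    )
    fc = fc_map(
        clean[:, s_ix], clean[:, o_ix], target_names=others,
        subject_id=subject_id, seed_name=seed_region,
    )
    pair_coeffs: dict[str, float] = {}
    for a, b in LOOP_PAIRS:
        bxy, byx = pairwise_gca(clean[:, regions.index(a)],
                                clean[:, regions.index(b)])
        pair_coeffs[f"beta:{a}->{b}"] = bxy
        pair_coeffs[f"beta:{b}->{a}"] = byx
        pair_coeffs[f"net:{a}->{b}"] = bxy - byx
    for a, b in VISUAL_INFLOW_EDGES:
        bxy, byx = pairwise_gca(clean[:, regions.index(a)],
                                clean[:, regions.index(b)])
        pair_coeffs[f"beta:{a}->{b}"] = bxy
        pair_coeffs[f"beta:{b}->{a}"] = byx
    return gca, fc, pair_coeffs


@_stage("cohort")
def _load_cohort(cfg: RunConfig) -> list[SubjectData]:
    if cfg.mode == "simulate":
        cohort_cfg = replace(cfg.cohort, rng_seed=cfg.rng_seed)
        return simulate_cohort(cohort_cfg)
    return read_cohort(cfg.cohort_dir)


@_stage("preprocess")
def _preprocess(subjects: list[SubjectData], cfg: RunConfig) -> list[np.ndarray]:
    return [
        preprocess_series(s.series, cfg.preproc, s.confounds, s.confound_names)
        for s in subjects
    ]


@_stage("maps")
def _subject_maps(subjects, cleaned, cfg: RunConfig, out: Path):
    gcas, fcs, pair_rows = [], [], []
    for s, clean in zip(subjects, cleaned):
        gca, fc, pairs = compute_subject_maps(
            clean, s.regions, cfg.seed_region, subject_id=s.id,
            tr_s=cfg.preproc.tr_s,
        )
        gcas.append(gca)
        fcs.append(fc)
        pair_rows.append({"id": s.id, **pairs})
        write_map_table(out / "maps" / f"{s.id}.tsv", gca=gca, fc=fc)
    pairs_df = pd.DataFrame(pair_rows).set_index("id")
    pairs_df.to_csv(out / "maps" / "pair_coefficients.tsv", sep="\t",
                    float_format="%.17g")
    return gcas, fcs, pairs_df


@_stage("group")
def _group_inference(subjects, gcas, fcs, cfg: RunConfig, rng, out: Path):
    targets = gcas[0].targets
    design = GroupDesign(
        subject_ids=[s.id for s in subjects],
        group=np.array([1.0 if s.group == "patient" else 0.0 for s in subjects]),
        age=np.array([s.age for s in subjects]),
        gender=np.array([1.0 if s.gender == "F" else 0.0 for s in subjects]),
    )
    results = {}
    for label, values in (
        ("gca_outflow", np.vstack([g.beta_xy for g in gcas])),
        ("gca_inflow", np.vstack([g.beta_yx for g in gcas])),
        ("fc_z", np.vstack([f.z for f in fcs])),
    ):
        one = one_sample_map(values, targets)
        one.p_fwe = fwe_correct(values, "one_sample", n_perm=cfg.n_perm,
                                rng=rng)
        mask = mask_from_one_sample(one, cfg.alpha)
        two = two_sample_map(values, design, targets)
        if mask.any():
            two.p_fwe = fwe_correct(values, "two_sample", design=design,
                                    n_perm=cfg.n_perm, mask=mask, rng=rng)
        sig = (np.nan_to_num(two.p_fwe, nan=1.0) <= cfg.alpha
               if two.p_fwe is not None else np.zeros(len(targets), bool))
        followups = {}
        for i in np.nonzero(sig)[0]:
            by_group = {
                g: values[design.group == (1.0 if g == "patient" else 0.0), i]
                for g in ("control", "patient")
            }
            followups[targets[i]] = followup_tests(by_group)
        results[label] = {
            "one_sample": one, "two_sample": two, "mask": mask,
            "followups": followups, "values": values,
        }
        df = pd.DataFrame({
            "target": targets,
            "t_one_sample": one.t, "p_fwe_one_sample": one.p_fwe,
            "t_two_sample": two.t, "df": two.df,
            "p_unc_two_sample": two.p_unc,
            "p_fwe_two_sample": (two.p_fwe if two.p_fwe is not None
                                 else np.full(len(targets), np.nan)),
            "in_mask": mask,
        })
        df.to_csv(out / "group" / f"{label}.tsv", sep="\t", index=False,
                  float_format="%.17g")
    return design, results


@_stage("mediation")
def _mediation(subjects, gcas, fcs, group_results, cfg: RunConfig, rng):
    targets = fcs[0].targets
    two = group_results["fc_z"]["two_sample"]
    z_vals = group_results["fc_z"]["values"]
    if two.p_fwe is not None and np.any(np.nan_to_num(two.p_fwe, nan=1.0) <= cfg.alpha):
        chosen = np.nan_to_num(two.p_fwe, nan=1.0) <= cfg.alpha
        rule = "fwe"
    elif np.any(two.p_unc <= 0.05):
        chosen = two.p_unc <= 0.05
        rule = "uncorrected"
    else:
        chosen = np.zeros(len(targets), bool)
        chosen[int(np.nanargmax(np.abs(two.t)))] = True
        rule = "top-statistic"
    mediator = eigenvariate(z_vals[:, chosen])
    x = np.array([1.0 if s.group == "patient" else 0.0 for s in subjects])
    y_ix = gcas[0].targets.index(cfg.outflow_target)
    y = np.array([g.beta_xy[y_ix] for g in gcas])
    result = fit_mediation(x, mediator, y, n_boot=cfg.n_boot, rng=rng)
    return result, {
        "cluster_targets": [t for t, c in zip(targets, chosen) if c],
        "cluster_rule": rule,
        "outcome": f"{cfg.seed_region}->{cfg.outflow_target}",
    }


@_stage("severity")
def _severity(subjects, pairs_df, cfg: RunConfig):
    patients = [s for s in subjects if s.group == "patient"]
    if not all(s.clinical for s in patients):
        logger.info("no clinical data for patients; skipping severity stage")
        return None
    clin = pd.DataFrame([s.clinical for s in patients],
                        index=[s.id for s in patients])
    coeffs = pairs_df.loc[[s.id for s in patients]]
    comps = build_composites(coeffs, clin)
    dose = np.array([s.dose for s in patients])
    reg = severity_regression(comps["severity"], comps["loop"],
                              comps["visual_inflow"], dose)
    return comps, reg


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the run report (also written to disk)."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    for sub in ("maps", "group"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    rng_group, rng_med = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(cfg.rng_seed).spawn(2)
    ]

    subjects = _load_cohort(cfg)
    if cfg.mode == "simulate" and cfg.write_cohort_files:
        write_cohort(subjects, out / "cohort")
    cleaned = _preprocess(subjects, cfg)
    gcas, fcs, pairs_df = _subject_maps(subjects, cleaned, cfg, out)
    design, group_results = _group_inference(subjects, gcas, fcs, cfg,
                                             rng_group, out)
    mediation_result, mediation_meta = _mediation(
        subjects, gcas, fcs, group_results, cfg, rng_med
    )
    severity_out = _severity(subjects, pairs_df, cfg)

    report = {
        "config": _config_dict(cfg),
        "n_subjects": len(subjects),
        "groups": {
            g: int(sum(s.group == g for s in subjects))
            for g in ("control", "patient")
        },
        "group": {
            label: {
                "two_sample_top_target": res["two_sample"].targets[
                    int(np.nanargmax(np.abs(res["two_sample"].t)))
                ],
                "two_sample_max_abs_t": float(np.nanmax(np.abs(res["two_sample"].t))),
                "n_in_mask": int(res["mask"].sum()),
                "significant_fwe": [
                    t for t, p in zip(
                        res["two_sample"].targets,
                        (res["two_sample"].p_fwe
                         if res["two_sample"].p_fwe is not None else []),
                    )
                    if np.isfinite(p) and p <= cfg.alpha
                ],
                "followups": res["followups"],
            }
            for label, res in group_results.items()
        },
        "mediation": {**asdict(mediation_result), **mediation_meta},
    }
    if severity_out is not None:
        comps, reg = severity_out
        report["severity"] = {
            "variance_explained": {
                k: comps[k].variance_explained for k in comps
            },
            "beta": dict(zip(reg.predictors, reg.beta.tolist())),
            "t": dict(zip(reg.predictors, reg.t.tolist())),
            "p": dict(zip(reg.predictors, reg.p.tolist())),
            "r_squared": reg.r_squared,
            "f_stat": reg.f_stat,
            "df": [reg.df_model, reg.df_resid],
            "p_model": reg.p_model,
            "collinearity_warning": reg.collinearity_warning,
        }
    write_report(report, out)
    return report


def write_report(report: dict, out_dir: str | Path) -> Path:
    """Write the report plus a manifest with checksums of all artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_json(report, out / "report.json")
    files = sorted(
        p for p in out.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "rsgca_version": __version__,
        "numpy_version": np.__version__,
        "config": report.get("config"),
        "rng_seed": report.get("config", {}).get("rng_seed"),
        "checksums": {str(p.relative_to(out)): sha256_file(p) for p in files},
    }
    write_json(manifest, out / "manifest.json")
    return out / "manifest.json"


def _config_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    d["cohort"]["networks"] = None  # network objects are not serialized
    return d
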