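"""End-to-end study analogue: simulate, model, score, measure, compare.

``run_full_comparison`` executes the whole cross-modality comparison on a
synthetic paired-modality cohort: build shape models and OA vectors from
the MR-rendered surfaces, score every knee through both pathways (MR by
direct projection; CT by fitting the MR-trained model to the CT surface
and projecting the fitted instance — the asymmetry at the heart of the
method), measure regional bone areas and 3D joint-space width on both
modalities, estimate test-retest smallest detectable differences, and
produce an agreement table per measure, plus a second table restricted to
the moderate-severity stratum.

Baseline/follow-up style repeated acquisitions would be pooled as
independent pairs; the synthetic cohort uses one timepoint per knee and
the pairing logic in :func:`count_analysis_pairs` handles arbitrary
manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .agreement import (PairedMeasures, UNITS, sdd, summarize_table,
                        render_table)
from .measures import (FEMUR_REGIONS, JSW_REGIONS, TIBIA_REGIONS, jsw_3d,
                       tab_area)
from .oa_score import build_oa_vector, score_shape, score_surface
from .shape_model import (ShapePopulation, build_shape_model, procrustes_align,
                          project)
from .synthetic import (SyntheticConfig, make_test_retest, render_modality,
                        sample_population)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "PipelineStageError",
    "run_full_comparison",
    "count_analysis_pairs",
]

log = logging.getLogger("kneeshape")

JSW_MEASURE = {"cMT": "Medial 3DJSW", "cLT": "Lateral 3DJSW"}
SCORE_MEASURE = {"femur": "B-score", "tibia": "z-score"}


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    variance_retained: float = 0.98
    with_scale: bool = True          # size-normalized alignment for shape scores
    max_dist_mm: float = 15.0        # joint-space ray cap
    sdd_z: float = 1.96
    outdir: Optional[str] = None

    @property
    def seed(self) -> int:
        return self.synthetic.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        syn = d.pop("synthetic", {})
        known = {f.name for f in dataclasses.fields(cls)} - {"synthetic"}
        return cls(synthetic=SyntheticConfig.from_dict(syn),
                   **{k: v for k, v in d.items() if k in known})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    records: pd.DataFrame          # long-format per-measurement records
    subjects: pd.DataFrame         # ground truth per knee (latent t, group, size)
    table_full: pd.DataFrame       # agreement, all knees
    table_moderate: pd.DataFrame   # agreement, moderate-severity stratum
    sdd_summary: pd.DataFrame      # test-retest SDD per shape score
    fit_residuals: pd.DataFrame    # CT-pathway fit residuals per knee/bone
    provenance: dict


def _paired(records: pd.DataFrame, subjects: Optional[pd.DataFrame] = None,
            subset: Optional[List[str]] = None) -> Dict[str, PairedMeasures]:
    """Align MR/CT values per measure over (subject, timepoint) pairs."""
    df = records
    if subset is not None:
        df = df[df["subject"].isin(subset)]
    wide = df.pivot_table(index=["measure", "subject", "timepoint"],
                          columns="modality", values="value").reset_index()
    out = {}
    for measure, grp in wide.groupby("measure", sort=False):
        grp = grp.dropna(subset=["MR", "CT"])
        if len(grp):
            out[measure] = PairedMeasures(measure, grp["MR"].to_numpy(),
                                          grp["CT"].to_numpy(),
                                          UNITS.get(measure, ""))
    return out


def run_full_comparison(cfg: PipelineConfig) -> PipelineResult:
    """Run the full synthetic cross-modality comparison.

    Stages run in order (simulate, model, oa-vector, score, measure,
    retest, agree); a failure aborts with the stage name after persisting
    whatever partial outputs exist.  Identical configurations (including
    the seed) produce byte-identical output CSVs.
    """
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(outdir / "config.yaml")
        fh = logging.FileHandler(outdir / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)

    records: List[dict] = []
    state: Dict[str, object] = {}
    try:
        result = _run_stages(cfg, records, state, outdir)
    except PipelineStageError:
        if outdir and records:
            pd.DataFrame(records).to_csv(outdir / "records_partial.csv", index=False)
        raise
    finally:
        if outdir:
            log.removeHandler(fh)
            fh.close()
    return result


def _run_stages(cfg, records, state, outdir) -> PipelineResult:
    syn = cfg.synthetic
    group_key = None if syn.n_levels == 1 else "sex"

    # -- simulate -----------------------------------------------------------
    stage = "simulate"
    try:
        log.info("stage %s: n=%d resolution=%d seed=%d",
                 stage, syn.n_subjects, syn.resolution, syn.seed)
        template, knees = sample_population(syn)
        renders = {}
        for knee in knees:
            renders[knee.subject] = {m: render_modality(knee, m, syn)
                                     for m in ("CT", "MR")}
    except Exception as e:                            # noqa: BLE001
        raise PipelineStageError(stage, e) from e

    # -- model --------------------------------------------------------------
    stage = "model"
    try:
        log.info("stage %s: building MR shape models", stage)
        models = {}
        for bone, pick in (("femur", 0), ("tibia", 1)):
            pop = ShapePopulation([renders[k.subject]["MR"][pick] for k in knees])
            aligned = procrustes_align(pop, with_scale=cfg.with_scale)
            models[bone] = build_shape_model(aligned, cfg.variance_retained)
            log.info("%s model: %d modes", bone, models[bone].n_modes)
    except Exception as e:                            # noqa: BLE001
        raise PipelineStageError(stage, e) from e

    # -- oa-vector ----------------------------------------------------------
    stage = "oa-vector"
    try:
        vectors = {}
        for bone, pick in (("femur", 0), ("tibia", 1)):
            non_oa = [renders[k.subject]["MR"][pick] for k in knees
                      if k.group == "nonOA"]
            oa = [renders[k.subject]["MR"][pick] for k in knees
                  if k.group == "OA"]
            if len(non_oa) < 2 or len(oa) < 2:
                raise ValueError(
                    f"need >= 2 knees per group to build the {bone} OA vector "
                    f"(got {len(non_oa)} non-OA, {len(oa)} OA)")
            vectors[bone] = build_oa_vector(models[bone],
                                            ShapePopulation(non_oa),
                                            ShapePopulation(oa),
                                            group_key=group_key, bone=bone)
        log.info("stage %s: OA vectors built", stage)
    except PipelineStageError:
        raise
    except Exception as e:                            # noqa: BLE001
        raise PipelineStageError(stage, e) from e

    def _level(knee):
        return knee.level if group_key else "pooled"

    # -- score --------------------------------------------------------------
    stage = "score"
    fit_rows = []
    try:
        for knee in knees:
            for bone, pick in (("femur", 0), ("tibia", 1)):
                measure = SCORE_MEASURE[bone]
                mr_surface = renders[knee.subject]["MR"][pick]
                b_mr = project(models[bone], mr_surface)
                s_mr = score_shape(vectors[bone], b_mr, _level(knee))
                records.append(_rec(knee, "MR", bone, measure, s_mr))
                ct_surface = renders[knee.subject]["CT"][pick]
                s_ct, fit = score_surface(models[bone], vectors[bone],
                                          ct_surface, _level(knee))
                records.append(_rec(knee, "CT", bone, measure, s_ct,
                                    fit_residual_mm=fit.residual_mm))
                fit_rows.append({"subject": knee.subject, "bone": bone,
                                 "residual_mm": fit.residual_mm,
                                 "residual_sd_mm": fit.residual_sd_mm,
                                 "converged": fit.converged,
                                 "n_iterations": fit.n_iterations})
        log.info("stage %s: scored %d knees (mean CT fit residual %.3f mm)",
                 stage, len(knees),
                 float(np.mean([r["residual_mm"] for r in fit_rows])))
    except Exception as e:                            # noqa: BLE001
        raise PipelineStageError(stage, e) from e

    # -- measure ------------------------------------------------------------
    stage = "measure"
    try:
        for knee in knees:
            for modality in ("CT", "MR"):
                femur, tibia = renders[knee.subject][modality]
                for name in FEMUR_REGIONS:
                    records.append(_rec(knee, modality, "femur", name,
                                        tab_area(femur, template.regions[name])))
                for name in TIBIA_REGIONS:
                    if name in JSW_REGIONS:
                        continue
                    records.append(_rec(knee, modality, "tibia", name,
                                        tab_area(tibia, template.regions[name])))
                for name in JSW_REGIONS:
                    res = jsw_3d(tibia, femur, template.regions[name],
                                 max_dist=cfg.max_dist_mm)
                    records.append(_rec(knee, modality, "tibia",
                                        JSW_MEASURE[name], res.mean_mm,
                                        n_measured=res.n_measured,
                                        n_excluded=res.n_excluded))
        log.info("stage %s: %d records", stage, len(records))
    except Exception as e:                            # noqa: BLE001
        raise PipelineStageError(stage, e) from e

    # -- retest -------------------------------------------------------------
    stage = "retest"
    try:
        retest_knees = knees[:min(syn.n_retest, len(knees))]
        rep_scores = {"femur": ([], []), "tibia": ([], [])}
        for knee in retest_knees:
            reps = make_test_retest(knee, syn)
            for bone, pick in (("femur", 0), ("tibia", 1)):
                for arm, (rep) in enumerate(reps[:2]):
                    b = project(models[bone], rep[pick])
                    rep_scores[bone][arm].append(
                        score_shape(vectors[bone], b, _level(knee)))
        sdd_rows = []
        for bone in ("femur", "tibia"):
            t0, t1 = rep_scores[bone]
            s = sdd(t0, t1, measure=SCORE_MEASURE[bone], z=cfg.sdd_z)
            sdd_rows.append({"measure": s.measure, "sdd": s.sdd,
                             "sd_differences": s.sd_differences,
                             "n_pairs": s.n_pairs})
        sdd_summary = pd.DataFrame(sdd_rows)
        log.info("stage %s: SDD %s", stage,
                 dict(zip(sdd_summary["measure"], sdd_summary["sdd"].round(3))))
    except Exception as e:                            # noqa: BLE001
        raise PipelineStageError(stage, e) from e

    # -- agree --------------------------------------------------------------
    stage = "agree"
    try:
        rec_df = pd.DataFrame(records)
        subjects = pd.DataFrame(
            [{"subject": k.subject, "t": k.t, "group": k.group,
              "level": k.level, "size": k.size} for k in knees])
        pairs = _paired(rec_df)
        table_full = summarize_table(pairs, z=cfg.sdd_z)
        moderate = [k.subject for k in knees
                    if k.group == "OA" and k.t <= syn.moderate_max_t]
        pairs_mod = _paired(rec_df, subset=moderate)
        table_moderate = (summarize_table(pairs_mod, z=cfg.sdd_z)
                          if pairs_mod else table_full.iloc[0:0].copy())
        log.info("stage %s:\n%s", stage, render_table(table_full))
    except Exception as e:                            # noqa: BLE001
        raise PipelineStageError(stage, e) from e

    fit_residuals = pd.DataFrame(fit_rows)
    provenance = {
        "config_hash": cfg.config_hash(),
        "seed": syn.seed,
        "n_subjects": syn.n_subjects,
        "model_modes": {b: int(models[b].n_modes) for b in models},
        "mean_fit_residual_mm": float(fit_residuals["residual_mm"].mean()),
        "sd_fit_residual_mm": float(fit_residuals["residual_mm"].std(ddof=1)),
        "n_moderate": len(moderate),
    }
    result = PipelineResult(cfg, rec_df, subjects, table_full, table_moderate,
                            sdd_summary, fit_residuals, provenance)
    if cfg.outdir:
        _persist(result, Path(cfg.outdir))
    return result


def _rec(knee, modality, bone, measure, value, **extra) -> dict:
    row = {"subject": knee.subject, "timepoint": "baseline", "knee": "index",
           "modality": modality, "bone": bone, "measure": measure,
           "value": float(value), "units": UNITS.get(measure, ""),
           "group": knee.group}
    row.update(extra)
    return row


def _persist(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.records.to_csv(outdir / "records_raw.csv", index=False)
    result.records.assign(value=result.records["value"].round(3)).to_csv(
        outdir / "records.csv", index=False, float_format="%.3f")
    result.table_full.to_csv(outdir / "agreement_full_raw.csv", index=False)
    result.table_full.to_csv(outdir / "agreement_full.csv", index=False,
                             float_format="%.3f")
    result.table_moderate.to_csv(outdir / "agreement_moderate.csv", index=False,
                                 float_format="%.3f")
    result.sdd_summary.to_csv(outdir / "sdd.csv", index=False,
                              float_format="%.3f")
    result.subjects.to_csv(outdir / "subjects.csv", index=False)
    result.fit_residuals.to_csv(outdir / "fit_residuals.csv", index=False)
    (outdir / "provenance.json").write_text(
        json.dumps(result.provenance, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------

def count_analysis_pairs(manifest: pd.DataFrame) -> Tuple[int, pd.DataFrame]:
    """Count complete CT-MR acquisition pairs in an availability manifest.

    A pair exists where both modalities of the same (subject, timepoint,
    knee) are present.  Returns the pair count and a per-group breakdown
    (count and percentage).  Duplicate (subject, timepoint, knee, modality)
    rows are an error.
    """
    required = {"subject", "timepoint", "knee", "modality"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")
    if len(manifest) == 0:
        return 0, pd.DataFrame(columns=["group", "n", "percent"])
    key = ["subject", "timepoint", "knee", "modality"]
    if manifest.duplicated(subset=key).any():
        dup = manifest[manifest.duplicated(subset=key, keep=False)]
        raise ValueError(f"duplicate manifest entries:\n{dup[key].head()}")
    has = manifest.pivot_table(index=["subject", "timepoint", "knee"],
                               columns="modality", values="modality",
                               aggfunc="size").reindex(columns=["CT", "MR"])
    complete = has.notna().all(axis=1)
    n_pairs = int(complete.sum())
    if "group" in manifest.columns and n_pairs:
        groups = (manifest.drop_duplicates(subset=["subject", "timepoint", "knee"])
                  .set_index(["subject", "timepoint", "knee"])["group"])
        paired_groups = groups[complete[complete].index]
        breakdown = (paired_groups.value_counts().rename_axis("group")
                     .reset_index(name="n"))
        breakdown["percent"] = 100.0 * breakdown["n"] / n_pairs
    else:
        breakdown = pd.DataFrame(columns=["group", "n", "percent"])
    return n_pairs, breakdown
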