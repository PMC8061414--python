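"""End-to-end orchestration: simulate/ingest -> fit -> summarise -> correlate.

`run_all` reproduces the study's analysis structure on either a synthetic
cohort or user-supplied CSVs: a Bayesian detection-model fit per
participant, a bCFS direct-gaze-bias summary per participant, the group
gaze sanity test, and the six headline rank correlations with Bayes
factors.  Every stochastic stage draws its seed from one global seed via a
`numpy.random.SeedSequence` spawn, so stages are independently
reproducible and the report is byte-identical across reruns.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .cfs import gaze_trials_from_frame, group_gaze_test, gaze_summary, summarize_cohort
from .cohort import CohortConfig, CohortData, generate_cohort
from .detection import face_data_from_frame, fit_cohort
from .errors import ValidationError
from .inference import (classify_evidence, correlate_report,
                        correlation_results_frame, distribution_aic)

logger = logging.getLogger("facepriors")

#: fixed order of per-stage child seeds spawned from the global seed
STAGE_ORDER = ("cohort", "fitting", "gaze", "inference")


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    seed: Optional[int]
    mode: str
    config: dict
    stage_seconds: dict[str, float] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    version: str = __version__


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def stage_seeds(seed: Optional[int]) -> dict[str, int]:
    """Expand one global seed into named per-stage seeds (documented order)."""
    children = np.random.SeedSequence(seed).spawn(len(STAGE_ORDER))
    return {name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(STAGE_ORDER, children)}


def validate_inputs(face_trials: pd.DataFrame, gaze_trials: pd.DataFrame,
                    psychometrics: pd.DataFrame,
                    max_rt: float = 15.0) -> ValidationReport:
    """Schema, range and join-key checks across the three input tables."""
    rep = ValidationReport()
    for name, df, cols in (
            ("face_trials", face_trials, {"participant_id", "face_present", "detected"}),
            ("gaze_trials", gaze_trials, {"participant_id", "gaze", "true_quadrant",
                                          "reported_quadrant", "rt_seconds"}),
            ("psychometrics", psychometrics, {"participant_id", "pdi_total", "caps_total"})):
        missing = cols - set(df.columns)
        if missing:
            rep.errors.append(f"{name}: missing columns {sorted(missing)}")
    if rep.errors:
        return rep
    bad_face = ~face_trials["face_present"].isin((0, 1)) | ~face_trials["detected"].isin((0, 1))
    if bad_face.any():
        rep.errors.append(f"face_trials: {int(bad_face.sum())} rows with non-binary flags")
    rt = gaze_trials["rt_seconds"].dropna()
    over = rt[(rt <= 0) | (rt > max_rt)]
    if len(over):
        rep.errors.append(
            f"gaze_trials: {len(over)} response times outside (0, {max_rt}] "
            f"(breakthrough times are censored at the {max_rt} s ceiling); "
            f"first offending row index {over.index[0]}")
    bad_gaze = ~gaze_trials["gaze"].isin(("direct", "averted"))
    if bad_gaze.any():
        rep.errors.append(f"gaze_trials: {int(bad_gaze.sum())} rows with unknown gaze labels")
    neg = psychometrics[(psychometrics["pdi_total"] < 0) | (psychometrics["caps_total"] < 0)]
    if len(neg):
        rep.errors.append(f"psychometrics: {len(neg)} rows with negative questionnaire totals")
    ids = {name: set(df["participant_id"].astype(str))
           for name, df in (("face", face_trials), ("gaze", gaze_trials),
                            ("psychometrics", psychometrics))}
    for a in ids:
        for b in ids:
            only = ids[a] - ids[b]
            if only and a != b:
                rep.warnings.append(
                    f"{len(only)} participant(s) present in {a} but not {b} tables")
    return rep


def analyze(face_trials: pd.DataFrame, gaze_trials: pd.DataFrame,
            psychometrics: pd.DataFrame, prior_width: float = 1.0,
            ttest_scale: float = 0.707,
            exclusion_threshold: float = 0.65) -> dict:
    """The analysis half of the pipeline, on already-loaded tables."""
    report = validate_inputs(face_trials, gaze_trials, psychometrics)
    if not report.ok:
        raise ValidationError("; ".join(report.errors))
    for w in report.warnings:
        logger.warning(w)

    fits = fit_cohort(face_data_from_frame(face_trials))
    gaze_by_pid = gaze_trials_from_frame(gaze_trials)
    gaze = summarize_cohort(gaze_by_pid, threshold=exclusion_threshold)

    cohort = (psychometrics.astype({"participant_id": str})
              .merge(fits[["participant_id", "prior", "sensitivity"]]
                     .rename(columns={"prior": "face_prior", "sensitivity": "face_sensitivity"}),
                     on="participant_id", how="left")
              .merge(gaze[["participant_id", "direct_gaze_bias", "excluded"]]
                     .rename(columns={"excluded": "gaze_excluded"}),
                     on="participant_id", how="left"))
    cohort["gaze_excluded"] = cohort["gaze_excluded"].fillna(True)

    correlations = correlate_report(cohort, prior_width=prior_width)
    usable = [gaze_summary(pid, trials, threshold=exclusion_threshold)
              for pid, trials in gaze_by_pid.items()]
    group = group_gaze_test(usable, prior_scale=ttest_scale)
    bias_vals = cohort.loc[~cohort["gaze_excluded"], "direct_gaze_bias"].dropna()
    dist = distribution_aic(bias_vals.to_numpy()) if len(bias_vals) >= 5 else None
    return dict(fits=fits, gaze=gaze, cohort=cohort, correlations=correlations,
                group_gaze_test=group, gaze_bias_distribution=dist)


def run_all(config: Optional[CohortConfig] = None, seed: Optional[int] = None,
            out_dir: Optional[str | Path] = None, mode: str = "synthetic",
            face_csv=None, gaze_csv=None, psych_csv=None,
            prior_width: float = 1.0, ttest_scale: float = 0.707) -> dict:
    """Run the whole pipeline and (optionally) write a report bundle.

    In ``synthetic`` mode a cohort is generated from ``config`` (the global
    ``seed``, when given, overrides ``config.seed``); in ``data`` mode the
    three CSV paths are read instead.
    """
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    if mode == "synthetic":
        config = config or CohortConfig()
        if seed is not None:
            config = CohortConfig(**{**config.__dict__, "seed": stage_seeds(seed)["cohort"]})
        data = generate_cohort(config)
        face, gaze, psych = data.face_trials, data.gaze_trials, data.psychometrics
        cfg_snapshot = dict(config.__dict__)
    elif mode == "data":
        if not all(p is not None for p in (face_csv, gaze_csv, psych_csv)):
            raise ValidationError("data mode requires face_csv, gaze_csv and psych_csv")
        face = pd.read_csv(face_csv)
        gaze = pd.read_csv(gaze_csv)
        psych = pd.read_csv(psych_csv)
        data = None
        cfg_snapshot = dict(face_csv=str(face_csv), gaze_csv=str(gaze_csv),
                            psych_csv=str(psych_csv))
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    timings["ingest"] = time.perf_counter() - t0

    t1 = time.perf_counter()
    result = analyze(face, gaze, psych, prior_width=prior_width, ttest_scale=ttest_scale)
    timings["analysis"] = time.perf_counter() - t1

    manifest = RunManifest(seed=seed, mode=mode, config=cfg_snapshot,
                           stage_seconds={k: round(v, 4) for k, v in timings.items()})
    result["manifest"] = manifest

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if data is not None:
            data.write(out)
        result["fits"].to_csv(out / "face_fits.csv", index=False, float_format="%.10g")
        result["gaze"].to_csv(out / "gaze_summaries.csv", index=False, float_format="%.10g")
        correlation_results_frame(result["correlations"]).to_csv(
            out / "correlations.csv", index=False, float_format="%.10g")
        report = report_dict(result)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        manifest.outputs = sorted(p.name for p in out.iterdir())
        with open(out / "manifest.json", "w") as fh:
            json.dump(asdict(manifest), fh, indent=2, sort_keys=True)
    return result


def report_dict(result: dict) -> dict:
    """JSON-serialisable Results-style report (6 correlation rows + group test)."""
    g = result["group_gaze_test"]
    rows = [dict(pairing=f"{r.x} ~ {r.y}", n=r.n, rho=round(r.rho, 6),
                 p=round(r.p_two_sided, 6), bf01=round(r.bf01, 6),
                 evidence=r.evidence_label)
            for r in result["correlations"]]
    out = dict(
        correlations=rows,
        group_gaze_test=dict(t=round(g.t, 6), df=g.df, p=round(g.p_two_sided, 6),
                             bf01=round(g.bf01, 6), n=g.n,
                             mean_bias=round(g.mean_bias, 6),
                             evidence=classify_evidence(g.bf01)),
        mean_face_prior=round(float(result["fits"]["prior"].mean()), 6),
        sd_face_prior=round(float(result["fits"]["prior"].std(ddof=1)), 6),
        mean_sensitivity=round(float(result["fits"]["sensitivity"].mean()), 6),
        sd_sensitivity=round(float(result["fits"]["sensitivity"].std(ddof=1)), 6),
    )
    if result.get("gaze_bias_distribution") is not None:
        d = result["gaze_bias_distribution"]
        out["gaze_bias_distribution"] = dict(
            aic_normal=round(d.aic_normal, 6), aic_uniform=round(d.aic_uniform, 6),
            preferred=d.preferred)
    return out
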