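"""Cohort orchestration: baseline → CPR → post-ROSC analysis per animal.

Runs every analysis family over a cohort (in-memory synthetic bundle or
files on disk), assembles one record per (subject, timepoint), computes
the cross-modality associations of interest — lung weight vs respiratory
system compliance, epoch-mean ΔPes vs lung weight, CT-measured vs ex-vivo
lung weight, lung weight vs wet-to-dry ratio — and flags CRALE per
subject.  Group-level inferential statistics beyond Pearson correlation
and paired/unpaired two-sample comparisons are deliberately left to
external tools; the report exposes tidy tables for that purpose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cralekit import ct as ctmod
from cralekit import mechanics as mech
from cralekit import oxygen as oxmod
from cralekit import stereology as ster
from cralekit.synthetic import CohortBundle

__all__ = [
    "AssociationResult",
    "CohortReport",
    "PairedChangeResult",
    "analyze_cohort",
    "correlate",
    "paired_change",
    "run_pipeline",
    "write_report",
]

REPORT_SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class AssociationResult:
    """Pearson correlation + least-squares line between two cohort variables."""

    x_name: str
    y_name: str
    r: float
    p_value: float
    slope: float
    intercept: float
    n: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class PairedChangeResult:
    """Baseline-vs-post summary for paired observations."""

    n: int
    mean_baseline: float
    sd_baseline: float
    mean_post: float
    sd_post: float
    mean_difference: float
    sd_difference: float
    test_name: str
    p_value: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def correlate(x: Sequence[float], y: Sequence[float], x_name: str = "x", y_name: str = "y") -> AssociationResult:
    """Pearson r with two-sided p (t transform) and the least-squares line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D series with n ≥ 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("series must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a series; correlation undefined")
    fit = stats.linregress(x, y)
    return AssociationResult(
        x_name=x_name,
        y_name=y_name,
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=int(x.size),
    )


def paired_change(
    baseline: Sequence[float],
    post: Sequence[float],
    test: str = "t",
) -> PairedChangeResult:
    """Within-subject baseline-vs-post change summary.

    ``test`` is ``"t"`` (paired Student) or ``"wilcoxon"`` (signed-rank)
    for non-normal differences.  With all differences equal to zero the
    test degenerates and p is reported as 1.0 by convention.
    """
    b = np.asarray(baseline, dtype=float)
    p = np.asarray(post, dtype=float)
    if b.shape != p.shape or b.ndim != 1 or b.size < 2:
        raise ValueError("need paired 1-D series with n ≥ 2")
    diff = p - b
    if np.all(diff == diff[0]) and (diff[0] == 0 or np.ptp(diff) == 0):
        # constant difference: the paired t statistic is 0/0 or infinite
        pval = 1.0 if diff[0] == 0 else 0.0
        name = f"paired {test} (degenerate: constant difference)"
    elif test == "t":
        pval = float(stats.ttest_rel(p, b).pvalue)
        name = "paired t-test"
    elif test == "wilcoxon":
        pval = float(stats.wilcoxon(p, b).pvalue)
        name = "Wilcoxon signed-rank"
    else:
        raise ValueError(f"unknown test {test!r}")
    return PairedChangeResult(
        n=int(b.size),
        mean_baseline=float(b.mean()),
        sd_baseline=float(b.std(ddof=1)),
        mean_post=float(p.mean()),
        sd_post=float(p.std(ddof=1)),
        mean_difference=float(diff.mean()),
        sd_difference=float(diff.std(ddof=1)),
        test_name=name,
        p_value=pval,
    )


@dataclass
class CohortReport:
    """Assembled per-subject records plus cohort-level associations."""

    records: list[dict] = field(default_factory=list)
    associations: dict[str, dict] = field(default_factory=dict)
    crale_flags: dict[str, bool] = field(default_factory=dict)
    schema_version: str = REPORT_SCHEMA_VERSION

    def as_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "records": self.records,
            "associations": self.associations,
            "crale_flags": self.crale_flags,
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), sort_keys=True, indent=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.json_normalize(self.records).sort_index(axis=1)

    def summary_text(self) -> str:
        lines = [f"cohort report (schema {self.schema_version})"]
        n = len(self.crale_flags)
        flagged = sum(self.crale_flags.values())
        lines.append(f"subjects: {n}; CRALE flagged post-CPR: {flagged}/{n}")
        for key, a in sorted(self.associations.items()):
            lines.append(
                f"{key}: r={a['r']:+.3f} p={a['p_value']:.3g} n={a['n']} "
                f"({a['x_name']} vs {a['y_name']})"
            )
        return "\n".join(lines) + "\n"


def analyze_cohort(bundle: CohortBundle) -> CohortReport:
    """Run the full analysis over an in-memory synthetic cohort bundle."""
    report = CohortReport()
    weights, crs_post, dpes_means = [], [], []
    ex_vivo, ct_weight, w2d = [], [], []
    for a in bundle.animals:
        rec: dict = {"subject": a.subject_id}
        for tp, ctv, msk in (
            ("baseline", a.baseline_ct, a.baseline_mask),
            ("post", a.post_ct, a.post_mask),
        ):
            rep = ctmod.quantify(ctv, msk)
            profile = ctmod.gravitational_profile(ctv, msk)
            rec[f"ct_{tp}"] = rep.as_dict()
            rec[f"ct_{tp}"]["vd_gradient_pct"] = ctmod.ventrodorsal_gradient(profile)

        panel_b = mech.partitioned_mechanics(
            a.baseline_occl_trace,
            a.baseline_occl_trace.epoch("occl_insp_0"),
            a.baseline_occl_trace.epoch("occl_exp_1"),
            a.vt_ml,
        )
        panel_p = mech.partitioned_mechanics(
            a.post_occl_trace,
            a.post_occl_trace.epoch("occl_insp_0"),
            a.post_occl_trace.epoch("occl_exp_1"),
            a.vt_ml,
        )
        rec["mechanics_baseline"] = panel_b.as_dict()
        rec["mechanics_post"] = panel_p.as_dict()

        swings = mech.pes_swing_stats(a.cc_trace)
        rec["dpes_epoch_mean_cmh2o"] = dict(swings.epoch_mean_swing)
        mean_dpes = float(np.mean(list(swings.epoch_mean_swing.values())))
        rec["dpes_mean_cmh2o"] = mean_dpes

        if a.cc_trace.pao is not None:
            cc_epochs = [e for e in a.cc_trace.epochs if e.kind in mech.CC_EPOCH_KINDS]
            cpp = mech.coronary_perfusion_pressure(a.cc_trace, cc_epochs[0])
            rec["cpp_mean_mmhg"] = cpp.mean_mmhg

        rec["oxygen"] = {}
        for label, panel, co, _truth in a.gas_panels:
            t = oxmod.transport_panel(panel, co)
            rec["oxygen"][label] = t.as_dict()

        grid = ster.overlay_grid(a.histology.data.shape[1], a.histology.data.shape[0], 100)
        counts = ster.point_count(a.histology, grid)
        rec["stereology"] = {
            "percentages": dict(counts.percentages),
            "alveolar_tissue_pct": ster.alveolar_tissue_percent(counts),
        }
        rec["necropsy"] = {
            "ex_vivo_weight_g": a.ex_vivo_weight_g,
            "wet_to_dry": ster.wet_to_dry(a.wet_mass_g, a.dry_mass_g),
            "lung_body_ratio_g_kg": ster.lung_body_ratio(
                a.ex_vivo_weight_g, a.body_weight_kg
            ),
        }
        report.records.append(rec)
        report.crale_flags[a.subject_id] = bool(rec["ct_post"]["crale"])

        weights.append(rec["ct_post"]["weight_g"])
        crs_post.append(panel_p.crs_ml_cmh2o)
        dpes_means.append(mean_dpes)
        ex_vivo.append(a.ex_vivo_weight_g)
        ct_weight.append(rec["ct_post"]["weight_g"])
        w2d.append(rec["necropsy"]["wet_to_dry"])

    if len(bundle.animals) >= 3:
        pairs = {
            "lung_weight_vs_crs": (weights, crs_post, "ct_post_weight_g", "crs_post_ml_cmh2o"),
            "dpes_vs_lung_weight": (dpes_means, weights, "dpes_mean_cmh2o", "ct_post_weight_g"),
            "ct_vs_ex_vivo_weight": (ct_weight, ex_vivo, "ct_post_weight_g", "ex_vivo_weight_g"),
            "lung_weight_vs_wet_to_dry": (weights, w2d, "ct_post_weight_g", "wet_to_dry"),
        }
        for key, (x, y, xn, yn) in pairs.items():
            report.associations[key] = correlate(x, y, xn, yn).as_dict()
    return report


def write_report(report: CohortReport, out_dir: str | Path) -> dict[str, Path]:
    """Write JSON, flat CSV and plain-text summary; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "json": out / "report.json",
        "csv": out / "records.csv",
        "txt": out / "summary.txt",
    }
    paths["json"].write_text(report.to_json())
    report.to_frame().to_csv(paths["csv"], index=False)
    paths["txt"].write_text(report.summary_text())
    return paths


def run_pipeline(
    config: dict | str | Path,
    out_dir: str | Path | None = None,
    allow_missing: bool = False,
) -> CohortReport:
    """File-based cohort analysis driven by a YAML/JSON config.

    The config lists subjects with paths to their CT/mask volumes, trace
    and annotation CSVs, blood-gas panel CSVs, histology image + legend,
    and scalar necropsy values (see :func:`cralekit.io.export_cohort`,
    which writes a ready-made config).  Missing required inputs raise an
    error naming the subject and timepoint unless ``allow_missing``.
    """
    from cralekit import io as iomod

    if not isinstance(config, dict):
        config = iomod.load_config(config)
    base = Path(config.get("root", "."))
    report = CohortReport()
    weights, crs_post, dpes_means, ex_vivo, w2d = [], [], [], [], []

    def need(sub: dict, key: str, tp: str) -> str | None:
        if key not in sub:
            if allow_missing:
                return None
            raise ValueError(
                f"subject {sub.get('id', '?')}: missing input {key!r} ({tp})"
            )
        return sub[key]

    for sub in config["subjects"]:
        sid = sub["id"]
        rec: dict = {"subject": sid}
        for tp in ("baseline", "post"):
            ct_path = need(sub, f"ct_{tp}", tp)
            mask_path = need(sub, f"mask_{tp}", tp)
            if ct_path and mask_path:
                ctv = iomod.load_nifti(base / ct_path)
                msk = iomod.load_mask_nifti(base / mask_path)
                rep = ctmod.quantify(ctv, msk)
                rec[f"ct_{tp}"] = rep.as_dict()
                rec[f"ct_{tp}"]["vd_gradient_pct"] = ctmod.ventrodorsal_gradient(
                    ctmod.gravitational_profile(ctv, msk)
                )
        vt = float(sub.get("vt_ml", 500.0))
        for tp in ("baseline", "post"):
            tr_path = need(sub, f"occlusion_trace_{tp}", tp)
            if tr_path:
                trace = iomod.load_trace_csv(
                    base / tr_path, base / sub[f"occlusion_annotations_{tp}"]
                )
                insp = next(e for e in trace.epochs if e.kind == "occlusion_insp")
                exp = next(e for e in trace.epochs if e.kind == "occlusion_exp")
                rec[f"mechanics_{tp}"] = mech.partitioned_mechanics(
                    trace, insp, exp, vt
                ).as_dict()
        cc_path = need(sub, "cc_trace", "cpr")
        if cc_path:
            cc_trace = iomod.load_trace_csv(
                base / cc_path, base / sub["cc_annotations"]
            )
            swings = mech.pes_swing_stats(cc_trace)
            rec["dpes_epoch_mean_cmh2o"] = dict(swings.epoch_mean_swing)
            rec["dpes_mean_cmh2o"] = float(
                np.mean(list(swings.epoch_mean_swing.values()))
            )
        panels_path = need(sub, "gas_panels", "gas")
        if panels_path:
            rec["oxygen"] = {}
            for label, panel, co in iomod.load_panels_csv(base / panels_path):
                rec["oxygen"][label] = oxmod.transport_panel(panel, co).as_dict()
        hist_path = sub.get("histology")
        if hist_path:
            img = iomod.load_histology(base / hist_path, base / sub["histology_legend"])
            grid = ster.overlay_grid(img.data.shape[1], img.data.shape[0], 100)
            counts = ster.point_count(img, grid)
            rec["stereology"] = {
                "percentages": dict(counts.percentages),
                "alveolar_tissue_pct": ster.alveolar_tissue_percent(counts),
            }
        nec = {}
        if "ex_vivo_weight_g" in sub:
            nec["ex_vivo_weight_g"] = float(sub["ex_vivo_weight_g"])
            if "body_weight_kg" in sub:
                nec["lung_body_ratio_g_kg"] = ster.lung_body_ratio(
                    nec["ex_vivo_weight_g"], float(sub["body_weight_kg"])
                )
        if "wet_mass_g" in sub and "dry_mass_g" in sub:
            nec["wet_to_dry"] = ster.wet_to_dry(
                float(sub["wet_mass_g"]), float(sub["dry_mass_g"])
            )
        if nec:
            rec["necropsy"] = nec

        report.records.append(rec)
        if "ct_post" in rec:
            report.crale_flags[sid] = bool(rec["ct_post"]["crale"])
            weights.append(rec["ct_post"]["weight_g"])
            if "mechanics_post" in rec:
                crs_post.append(rec["mechanics_post"]["crs_ml_cmh2o"])
            if "dpes_mean_cmh2o" in rec:
                dpes_means.append(rec["dpes_mean_cmh2o"])
            if "necropsy" in rec and "ex_vivo_weight_g" in rec["necropsy"]:
                ex_vivo.append(rec["necropsy"]["ex_vivo_weight_g"])
            if "necropsy" in rec and "wet_to_dry" in rec["necropsy"]:
                w2d.append(rec["necropsy"]["wet_to_dry"])

    n = len(weights)
    if n >= 3:
        if len(crs_post) == n:
            report.associations["lung_weight_vs_crs"] = correlate(
                weights, crs_post, "ct_post_weight_g", "crs_post_ml_cmh2o"
            ).as_dict()
        if len(dpes_means) == n:
            report.associations["dpes_vs_lung_weight"] = correlate(
                dpes_means, weights, "dpes_mean_cmh2o", "ct_post_weight_g"
            ).as_dict()
        if len(ex_vivo) == n:
            report.associations["ct_vs_ex_vivo_weight"] = correlate(
                weights, ex_vivo, "ct_post_weight_g", "ex_vivo_weight_g"
            ).as_dict()
        if len(w2d) == n:
            report.associations["lung_weight_vs_wet_to_dry"] = correlate(
                weights, w2d, "ct_post_weight_g", "wet_to_dry"
            ).as_dict()
    if out_dir is not None:
        write_report(report, out_dir)
    return report
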