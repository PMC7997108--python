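"""Study-level orchestration: data selection, pooling, tables and plots.

The selection workflow mirrors a collaborative trial: every delivered
dataset passes the integrity screen, then preprocessing, then the
calibration suitability gate; survivors contribute one prediction per
test level.  Residuals are normalized per dataset by that laboratory's
calibration reference range (labs may calibrate over different ranges)
and pooled per method into the figures of merit and quartile summaries.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calibrate import CalibrationModel, PredictionRecord, run_experiment
from .fom import FoMSet, compute_foms, normalize_foms
from .preprocess import PreprocessConfig, run_preprocess
from .spectra import Dataset, MethodId, Spectrum, integrity_check

__all__ = [
    "SelectionLog",
    "MethodSummary",
    "run_ils",
    "quartile_summary",
    "residual_rescale",
    "make_report",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal half-up rounding (22.85 -> 22.9 at 1 decimal)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SelectionLog:
    """Counters and per-dataset outcomes of the data-selection workflow."""

    planned: int
    delivered: int
    integrity_rejected: int
    calibration_rejected: int
    status: dict = field(default_factory=dict)  # "lab|method" -> (status, reason)

    @property
    def accepted(self) -> int:
        return self.delivered - self.integrity_rejected - self.calibration_rejected

    def percentages(self) -> dict[str, float]:
        """Share of planned datasets surviving each stage, half-up, 1 decimal."""
        post_integrity = self.delivered - self.integrity_rejected
        return {
            "delivered": round_half_up(100.0 * self.delivered / self.planned, 1),
            "post_integrity": round_half_up(100.0 * post_integrity / self.planned, 1),
            "accepted": round_half_up(100.0 * self.accepted / self.planned, 1),
        }


@dataclass
class MethodSummary:
    """Pooled per-method residual summary on the normalized scale."""

    method: MethodId
    n_residuals: int
    fom: FoMSet  # computed on range-normalized residuals
    q1: float
    median: float
    q3: float
    iqr: float
    lower_fence: float
    upper_fence: float
    outlier_flags: tuple[bool, ...]
    residuals_norm: tuple[float, ...]


def quartile_summary(residuals: Sequence[float]):
    """Quartiles (linear-interpolation convention), IQR, 1.5*IQR fences.

    Residuals beyond the fences are flagged, never removed.
    Returns ``(q1, median, q3, iqr, (lo_fence, hi_fence), flags)``.
    """
    e = np.asarray(residuals, dtype=float)
    if e.size < 4:
        raise ValueError("quartile summary needs n >= 4")
    q1, med, q3 = np.percentile(e, [25, 50, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    flags = tuple(bool(v < lo or v > hi) for v in e)
    return float(q1), float(med), float(q3), float(iqr), (float(lo), float(hi)), flags


def residual_rescale(records: Sequence[PredictionRecord], test_range: tuple[float, float]) -> np.ndarray:
    """Residuals divided by the width of the test-set reference range."""
    lo, hi = test_range
    if hi - lo <= 0:
        raise ValueError("test reference range must have positive width")
    return np.asarray([r.residual for r in records], dtype=float) / (hi - lo)


def run_ils(
    collection: Sequence[Dataset],
    preprocess_cfg: PreprocessConfig | None = None,
    contaminant_refs: Sequence[Spectrum] = (),
    corr_threshold: float = 0.9,
    planned: int | None = None,
) -> tuple[SelectionLog, list[MethodSummary], list[PredictionRecord]]:
    """Run the full pipeline over a delivered collection.

    ``planned`` defaults to the number of delivered datasets; pass the
    study design count when some laboratories never delivered.
    Per-dataset residuals are normalized by that dataset's calibration
    reference range before pooling, so the method FoMs are directly the
    normalized ones (fractions of range).
    """
    if not collection:
        raise ValueError("empty collection")
    planned = planned if planned is not None else len(collection)
    log = SelectionLog(planned=planned, delivered=len(collection), integrity_rejected=0, calibration_rejected=0)
    per_method: dict[MethodId, list[float]] = {}
    all_records: list[PredictionRecord] = []
    models: dict[str, CalibrationModel] = {}

    for ds in collection:
        key = f"{ds.lab_id}|{ds.method}"
        report = integrity_check(ds, contaminant_refs, corr_threshold)
        if report.verdict == "reject":
            log.integrity_rejected += 1
            log.status[key] = ("rejected-integrity", f"{report.n_flagged} flagged spectra")
            continue
        pre = run_preprocess(ds, preprocess_cfg)
        model, records = run_experiment(pre)
        models[key] = model
        if not model.suitable:
            log.calibration_rejected += 1
            log.status[key] = ("rejected-calibration", "; ".join(model.reasons))
            continue
        log.status[key] = ("accepted", "")
        all_records.extend(records)
        width = model.cal_width
        per_method.setdefault(ds.method, []).extend(r.residual / width for r in records)

    summaries: list[MethodSummary] = []
    for method in sorted(per_method, key=str):
        e = per_method[method]
        fom = normalize_foms(compute_foms(e), (0.0, 1.0))  # already on the range scale
        q1, med, q3, iqr, (lo, hi), flags = quartile_summary(e)
        summaries.append(
            MethodSummary(method, len(e), fom, q1, med, q3, iqr, lo, hi, flags, tuple(e))
        )
    return log, summaries, all_records


# ---------------------------------------------------------------------------
# report rendering


def _fom_table(summaries: Sequence[MethodSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        f = s.fom
        rows.append(
            {
                "method": str(s.method),
                "N": s.n_residuals,
                "RMSEP_pct": round_half_up(100 * f.rmsep_norm),
                "SEP_pct": round_half_up(100 * f.sep_norm),
                "BIAS_pct": round_half_up(100 * f.bias_norm),
                "inv_SEP": round_half_up(f.inv_sep_norm, 2),
                "quality_class": f.quality_class,
                "bias_significant_99": f.bias_significant,
            }
        )
    return pd.DataFrame(rows)


def make_report(
    log: SelectionLog,
    summaries: Sequence[MethodSummary],
    records: Sequence[PredictionRecord],
    outdir: str | Path,
    config: dict | None = None,
    make_plots: bool = True,
) -> dict[str, Path]:
    """Write the CSV tables, figures and run manifest for one study run."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fom_csv = outdir / "fom_table.csv"
    _fom_table(summaries).to_csv(fom_csv, index=False)
    paths["fom_table"] = fom_csv

    pred_csv = outdir / "predictions.csv"
    pd.DataFrame(
        [
            {
                "lab": r.lab_id,
                "method": str(r.method),
                "level": r.level_id,
                "reference_uM": r.reference_uM,
                "predicted_uM": r.predicted_uM,
                "residual_uM": r.residual,
                "flags": ";".join(r.flags),
            }
            for r in records
        ]
    ).to_csv(pred_csv, index=False)
    paths["predictions"] = pred_csv

    manifest = {
        "selection": {
            "planned": log.planned,
            "delivered": log.delivered,
            "integrity_rejected": log.integrity_rejected,
            "calibration_rejected": log.calibration_rejected,
            "accepted": log.accepted,
            "percentages": log.percentages(),
            "status": log.status,
        },
        "config": config or {},
        "conventions": {
            "sep_denominator": "n-1",
            "rmsep_denominator": "n",
            "quartiles": "linear interpolation between order statistics",
            "rounding": "half-up",
        },
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    manifest_path = outdir / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    paths["manifest"] = manifest_path

    if make_plots and records:
        by_method: dict[str, list[PredictionRecord]] = {}
        for r in records:
            by_method.setdefault(str(r.method), []).append(r)
        n_m = len(by_method)
        fig, axes = plt.subplots(1, n_m, figsize=(3.2 * n_m, 3.2), squeeze=False)
        for ax, (mname, recs) in zip(axes[0], sorted(by_method.items())):
            ref = [r.reference_uM for r in recs]
            pred = [r.predicted_uM for r in recs]
            ax.scatter(ref, pred, s=12, alpha=0.6)
            lim = [min(ref + pred), max(ref + pred)]
            ax.plot(lim, lim, "k--", lw=1)
            ax.set_title(mname, fontsize=9)
            ax.set_xlabel("reference (uM)")
        axes[0][0].set_ylabel("predicted (uM)")
        fig.tight_layout()
        p = outdir / "predicted_vs_reference.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths["predicted_vs_reference"] = p

        if summaries:
            fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 3.6))
            labels = [str(s.method) for s in summaries]
            for i, s in enumerate(summaries):
                x = np.full(len(s.residuals_norm), i, dtype=float)
                x += np.linspace(-0.18, 0.18, len(s.residuals_norm))
                ax1.scatter(x, s.residuals_norm, s=10, alpha=0.6)
                ax1.add_patch(
                    plt.Rectangle((i - 0.3, s.q1), 0.6, s.iqr, alpha=0.2, color="C0")
                )
                ax1.hlines([s.lower_fence, s.upper_fence], i - 0.3, i + 0.3, linestyles=":", color="C3", lw=1)
            ax1.axhline(0, color="k", lw=0.8)
            ax1.set_xticks(range(len(labels)), labels, rotation=45, fontsize=8)
            ax1.set_ylabel("normalized residual")
            ax1.set_title("residuals with IQR band and 1.5*IQR fences", fontsize=9)
            ax2.boxplot([s.residuals_norm for s in summaries], tick_labels=labels)
            ax2.axhline(0, color="k", lw=0.8)
            ax2.tick_params(axis="x", rotation=45, labelsize=8)
            ax2.set_title("residual distributions", fontsize=9)
            fig.tight_layout()
            p = outdir / "residual_summary.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            paths["residual_summary"] = p

    return paths
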