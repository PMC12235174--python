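"""End-to-end analysis of a plate recording.

Each well is preprocessed, its entrained and free-running segments are
period-analyzed (Lomb-Scargle peak, then free-period cosinor), classified
(Synchronized / Circadian / Arrhythmic), and its observed peak phases are
extracted. Per strain and condition the pipeline summarizes acrophases on
the circle (Rayleigh statistics), tallies percent rhythmic, and compares
free-running periods between strains (Welch and pooled t-tests, paired
within-strain comparisons, Shapiro-Wilk normality checks, optional Sidak
correction for >2 groups). Everything is deterministic given the inputs and
config; failures are logged per well and the run continues.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .circular import CircularSummary, circular_summary
from .preprocess import DeadWellError, PreprocessParams, run_preprocess
from .rhythm import (
    ConstantTraceError,
    PeriodogramSpec,
    RhythmError,
    classify,
    cosinor_fit,
    find_peak_phases,
    lomb_scargle,
)
from .traces import PlateRecording, TraceSeries, read_plate_csv


@dataclass
class RunConfig:
    """Everything a pipeline run depends on besides the input plate."""

    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    periodogram: PeriodogramSpec = field(default_factory=PeriodogramSpec)
    tol_24: float = 1.0
    r2_min: float = 0.5
    mode: Literal["per-well", "population-mean"] = "per-well"
    edge_exclude: float | None = None  # hours dropped from period fits at filter edges;
    # default: half the detrend window (where the moving average saw partial or
    # mixed-period windows and phase-distorts the residual)
    seed: int = 0
    outdir: Path | None = None

    @property
    def fit_edge_exclude(self) -> float:
        if self.edge_exclude is not None:
            return self.edge_exclude
        return self.preprocess.detrend_window / 2.0

    def digest(self) -> str:
        payload = json.dumps(
            {
                "preprocess": asdict(self.preprocess),
                "periodogram": asdict(self.periodogram),
                "tol_24": self.tol_24,
                "r2_min": self.r2_min,
                "mode": self.mode,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class GroupComparison:
    """Two-group period comparison with its supporting checks."""

    group_a: str
    group_b: str
    design: Literal["paired", "unpaired"]
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_welch: float | None
    p_welch: float | None
    df_welch: float | None
    t_pooled: float | None
    p_pooled: float | None
    df_pooled: float | None
    t_paired: float | None = None
    p_paired: float | None = None
    df_paired: float | None = None
    shapiro_p: float | None = None

    @property
    def t(self) -> float:
        return self.t_paired if self.design == "paired" else self.t_welch

    @property
    def p(self) -> float:
        return self.p_paired if self.design == "paired" else self.p_welch


def compare_periods(
    a: np.ndarray,
    b: np.ndarray,
    design: Literal["paired", "unpaired"] = "unpaired",
    label_a: str = "A",
    label_b: str = "B",
) -> GroupComparison:
    """Two-sided t comparison of per-well periods.

    Unpaired runs report both Welch (default) and pooled-variance statistics
    plus a Shapiro-Wilk check on the pooled residuals; paired runs require
    matched wells and check normality of the paired differences.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 periods per group")
    if design == "paired":
        if a.size != b.size:
            raise ValueError("paired design requires matched wells")
        diffs = a - b
        if np.ptp(diffs) == 0 and diffs[0] == 0:
            t_p, p_p = 0.0, 1.0  # identical pairs: zero mean difference, no evidence
        else:
            t_p, p_p = stats.ttest_rel(a, b)
        shp = stats.shapiro(diffs).pvalue if np.ptp(diffs) > 0 else None
        welch = stats.ttest_ind(a, b, equal_var=False)
        pooled = stats.ttest_ind(a, b, equal_var=True)
        return GroupComparison(
            group_a=label_a,
            group_b=label_b,
            design="paired",
            n_a=a.size,
            n_b=b.size,
            mean_a=float(a.mean()),
            mean_b=float(b.mean()),
            t_welch=float(welch.statistic),
            p_welch=float(welch.pvalue),
            df_welch=float(welch.df),
            t_pooled=float(pooled.statistic),
            p_pooled=float(pooled.pvalue),
            df_pooled=float(pooled.df),
            t_paired=float(t_p),
            p_paired=float(p_p),
            df_paired=float(a.size - 1),
            shapiro_p=float(shp) if shp is not None else None,
        )
    welch = stats.ttest_ind(a, b, equal_var=False)
    pooled = stats.ttest_ind(a, b, equal_var=True)
    resid = np.concatenate([a - a.mean(), b - b.mean()])
    shp = stats.shapiro(resid).pvalue if np.ptp(resid) > 0 else None
    return GroupComparison(
        group_a=label_a,
        group_b=label_b,
        design="unpaired",
        n_a=a.size,
        n_b=b.size,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_welch=float(welch.statistic),
        p_welch=float(welch.pvalue),
        df_welch=float(welch.df),
        t_pooled=float(pooled.statistic),
        p_pooled=float(pooled.pvalue),
        df_pooled=float(pooled.df),
        shapiro_p=float(shp) if shp is not None else None,
    )


def sidak_adjust(p_values: np.ndarray) -> np.ndarray:
    """Sidak multiple-comparison adjustment: 1 - (1-p)^m."""
    p = np.asarray(p_values, dtype=float)
    return 1.0 - (1.0 - p) ** p.size


@dataclass
class PipelineReport:
    results: pd.DataFrame  # one row per well x condition
    circular: pd.DataFrame  # per strain x condition phase summaries
    comparisons: pd.DataFrame  # group comparisons on free-running periods
    tallies: pd.DataFrame  # percent-rhythmic per strain x condition
    dead_wells: pd.DataFrame
    errors: pd.DataFrame
    manifest: dict


def _analyze_well(
    trace: TraceSeries, config: RunConfig
) -> tuple[list[dict], float | None, float | None]:
    """Preprocess one well and analyze each condition segment."""
    pre = run_preprocess(trace, config.preprocess)
    rows = []
    entrained_peak = None
    freerun_peak = None
    edge = config.fit_edge_exclude
    t0, t_end = float(pre.times[0]), float(pre.times[-1])
    release = pre.entrained_until
    for condition in ("entrained", "freerun"):
        seg = pre.segment(condition)
        if seg.n_samples == 0:
            continue
        # Period fits use only samples whose detrend window was complete and
        # single-period: the moving average phase-distorts the residual near
        # the trace edges and across the entrained->free-run switch, which
        # otherwise biases the fitted period. Peak phases use the full
        # segment (the first post-release peak can fall inside the zone).
        if condition == "entrained" or release is None:
            fit_seg = seg.slice_time(t0 + edge, np.inf)
        else:
            fit_seg = seg.slice_time(release + edge, t_end - edge + 1e-9)
        if fit_seg.n_samples < 8 or fit_seg.duration < config.periodogram.period_min:
            fit_seg = seg
        pgram = lomb_scargle(fit_seg, config.periodogram)
        fit = cosinor_fit(fit_seg, period_init=pgram.peak_period, spec=config.periodogram)
        call = classify(fit, condition, tol_24=config.tol_24, r2_min=config.r2_min)
        window = (float(seg.times[0]), float(seg.times[-1]))
        try:
            peaks = find_peak_phases(seg, window, first_only=(condition == "freerun"))
            peak_phase = peaks[0] if condition == "freerun" else circular_summary(peaks).mean_phase
        except RhythmError:
            peak_phase = np.nan
        if condition == "entrained":
            entrained_peak = peak_phase
        else:
            freerun_peak = peak_phase
        rows.append(
            {
                "well": trace.well_id,
                "strain": trace.strain,
                "condition": condition,
                "ls_peak_period_h": pgram.peak_period,
                "period_h": fit.period,
                "amplitude": fit.amplitude,
                "mesor": fit.mesor,
                "acrophase_cosinor_zt": fit.acrophase_zt,
                "peak_phase_zt": peak_phase,
                "r_squared": fit.r_squared,
                "label": call.label,
                "r2_min": config.r2_min,
                "tol_24": config.tol_24 if condition == "entrained" else np.nan,
            }
        )
    return rows, entrained_peak, freerun_peak


def run_full_pipeline(
    plate: PlateRecording | str | Path,
    config: RunConfig | None = None,
    dialect: str = "long",
) -> PipelineReport:
    """Analyze a plate end to end; see the module docstring for the stages.

    ``plate`` may be a PlateRecording or a CSV path. Per-well failures
    (dead wells, constant traces) are collected, not fatal; an empty plate
    is.
    """
    config = config or RunConfig()
    if not isinstance(plate, PlateRecording):
        plate = read_plate_csv(plate, dialect=dialect)
    if len(plate) == 0:
        raise ValueError("empty plate: nothing to analyze")

    traces = list(plate.traces)
    if config.mode == "population-mean":
        traces = _strain_mean_traces(traces)

    result_rows: list[dict] = []
    dead_rows: list[dict] = []
    error_rows: list[dict] = []
    for trace in traces:
        try:
            rows, _, _ = _analyze_well(trace, config)
            result_rows.extend(rows)
        except DeadWellError as exc:
            dead_rows.append({"well": trace.well_id, "strain": trace.strain, "reason": str(exc)})
        except (ConstantTraceError, RhythmError, ValueError) as exc:
            error_rows.append(
                {
                    "well": trace.well_id,
                    "strain": trace.strain,
                    "stage": type(exc).__name__,
                    "error": str(exc),
                }
            )

    results = pd.DataFrame(result_rows)
    circ_rows = []
    tally_rows = []
    if not results.empty:
        for (strain, condition), grp in results.groupby(["strain", "condition"]):
            rhythmic = grp[grp["label"] != "Arrhythmic"]
            phases = rhythmic["peak_phase_zt"].dropna().to_numpy()
            if phases.size:
                cs: CircularSummary = circular_summary(phases)
                circ_rows.append(
                    {
                        "strain": strain,
                        "condition": condition,
                        "mean_phase_zt": cs.mean_phase,
                        "sem_phase_h": cs.sem_phase,
                        "resultant_R": cs.resultant_R,
                        "rayleigh_p": cs.rayleigh_p,
                        "n": cs.n,
                        "dispersed": cs.dispersed,
                    }
                )
            tally_rows.append(
                {
                    "strain": strain,
                    "condition": condition,
                    "n_rhythmic": int(len(rhythmic)),
                    "n_total": int(len(grp)),
                    "percent_rhythmic": 100.0 * len(rhythmic) / len(grp),
                }
            )

    comp_rows = []
    if not results.empty:
        fr = results[(results["condition"] == "freerun") & (results["label"] == "Circadian")]
        strains = sorted(fr["strain"].unique())
        pairs = list(itertools.combinations(strains, 2))
        for s_a, s_b in pairs:
            pa = fr.loc[fr["strain"] == s_a, "period_h"].to_numpy()
            pb = fr.loc[fr["strain"] == s_b, "period_h"].to_numpy()
            if pa.size < 2 or pb.size < 2:
                continue
            cmp_res = compare_periods(pa, pb, "unpaired", s_a, s_b)
            comp_rows.append(
                {
                    "group_a": s_a,
                    "group_b": s_b,
                    "design": "unpaired",
                    "n_a": cmp_res.n_a,
                    "n_b": cmp_res.n_b,
                    "mean_period_a": cmp_res.mean_a,
                    "mean_period_b": cmp_res.mean_b,
                    "t_welch": cmp_res.t_welch,
                    "p_welch": cmp_res.p_welch,
                    "df_welch": cmp_res.df_welch,
                    "t_pooled": cmp_res.t_pooled,
                    "p_pooled": cmp_res.p_pooled,
                    "shapiro_p": cmp_res.shapiro_p,
                }
            )
        if len(comp_rows) > 1:
            padj = sidak_adjust(np.array([r["p_welch"] for r in comp_rows]))
            for row, adj in zip(comp_rows, padj):
                row["p_welch_sidak"] = float(adj)

    manifest = {
        "circalum_version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "mode": config.mode,
        "n_wells_in": len(traces),
        "n_wells_analyzed": int(results["well"].nunique()) if not results.empty else 0,
        "n_dead": len(dead_rows),
        "n_errors": len(error_rows),
        "thresholds": {"r2_min": config.r2_min, "tol_24": config.tol_24},
    }
    report = PipelineReport(
        results=results,
        circular=pd.DataFrame(circ_rows),
        comparisons=pd.DataFrame(comp_rows),
        tallies=pd.DataFrame(tally_rows),
        dead_wells=pd.DataFrame(dead_rows),
        errors=pd.DataFrame(error_rows),
        manifest=manifest,
    )
    if config.outdir is not None:
        write_report(report, config.outdir)
    return report


def _strain_mean_traces(traces: list[TraceSeries]) -> list[TraceSeries]:
    """Average wells per strain onto their (shared) time grid."""
    out = []
    by_strain: dict[str, list[TraceSeries]] = {}
    for tr in traces:
        by_strain.setdefault(tr.strain, []).append(tr)
    for strain, group in sorted(by_strain.items()):
        ref = group[0]
        mat = np.vstack([tr.values for tr in group])
        out.append(
            TraceSeries(
                well_id=f"{strain}-mean",
                strain=strain,
                times=ref.times.copy(),
                values=mat.mean(axis=0),
                zt_offset=ref.zt_offset,
                entrained_until=ref.entrained_until,
            )
        )
    return out


def write_report(report: PipelineReport, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.results.to_csv(outdir / "results.csv", index=False)
    report.circular.to_csv(outdir / "circular_summaries.csv", index=False)
    report.comparisons.to_csv(outdir / "group_comparisons.csv", index=False)
    report.tallies.to_csv(outdir / "percent_rhythmic.csv", index=False)
    report.dead_wells.to_csv(outdir / "dead_wells.csv", index=False)
    report.errors.to_csv(outdir / "errors.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2, sort_keys=True)


__all__ = [
    "RunConfig",
    "GroupComparison",
    "PipelineReport",
    "compare_periods",
    "sidak_adjust",
    "run_full_pipeline",
    "write_report",
]
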