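"""qPCR rhythm analysis: 2^-ddCt relative quantification and JTK_CYCLE.

Relative expression of a target transcript is computed against a reference
housekeeping gene (default Y45F10D.4) by the standard 2^-ddCt method
under the perfect-doubling assumption. Rhythmicity of the resulting time
course is then tested with JTK_CYCLE: ranked expression values are compared
by Kendall's tau against cosine reference waveforms over a grid of candidate
periods and phase lags; the best (period, lag) is reported with a
Bonferroni-adjusted p-value over the whole grid. The null distribution of
Kendall's S is exact (full permutation enumeration) for short series and a
tie-corrected normal approximation with continuity correction otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

TWO_PI = 2.0 * np.pi
EXACT_NULL_MAX_N = 10  # full enumeration up to here, normal approximation beyond
_TIE_EPS = 1e-9


class QpcrError(ValueError):
    pass


@dataclass
class ExpressionSeries:
    """Relative expression (fold change vs calibrator) over a time course."""

    timepoints: np.ndarray  # ZT/CT hours (may exceed 24 across days)
    rel_expression: np.ndarray  # 2^-ddCt from replicate-mean Cts; calibrator = 1
    sem: np.ndarray  # SEM of per-replicate fold changes
    n_replicates: np.ndarray
    replicate_rel: pd.DataFrame | None = None  # long: timepoint_h, sample, rel

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.rel_expression = np.asarray(self.rel_expression, dtype=float)


@dataclass
class JtkResult:
    best_period: float
    best_lag: float
    tau: float  # Kendall tau-b at the best (period, lag); NaN for flat input
    p_value: float  # unadjusted p at the best combination
    p_adj: float  # Bonferroni over the period x lag family, capped at 1
    n_tests: int
    table: pd.DataFrame | None = field(default=None, repr=False)
    flagged_constant: bool = False


# --------------------------------------------------------------------------
# 2^-ddCt


def ddct(
    table: pd.DataFrame,
    target: str,
    reference: str = "Y45F10D.4",
    calibrator_timepoint: float | None = None,
) -> ExpressionSeries:
    """Relative expression by 2^-ddCt.

    ``table`` is long-form with columns ``sample, timepoint_h, gene, ct``.
    Replicate Cts are averaged per (timepoint, gene); dCt = Ct_target -
    Ct_reference per timepoint, ddCt = dCt - dCt at the calibrator timepoint
    (default: the earliest), and fold change = 2^-ddCt, exactly 1 at the
    calibrator. Per-replicate fold changes (replicate target Ct against the
    mean reference Ct) give the SEM.
    """
    required = {"sample", "timepoint_h", "gene", "ct"}
    if not required.issubset(table.columns):
        raise QpcrError(f"Ct table needs columns {sorted(required)}")
    timepoints = np.sort(table["timepoint_h"].unique())
    if calibrator_timepoint is None:
        calibrator_timepoint = float(timepoints[0])
    if calibrator_timepoint not in set(timepoints):
        raise QpcrError(f"calibrator timepoint {calibrator_timepoint} not in table")

    mean_ct = table.groupby(["timepoint_h", "gene"])["ct"].mean().unstack()
    for gene in (target, reference):
        if gene not in mean_ct.columns or mean_ct[gene].isna().any():
            raise QpcrError(f"gene {gene!r} missing at some timepoint")
    dct = mean_ct[target] - mean_ct[reference]
    ddct_vals = dct - dct.loc[calibrator_timepoint]
    rel = np.power(2.0, -ddct_vals.to_numpy())

    tgt = table[table["gene"] == target]
    rep_rows = []
    for tp, grp in tgt.groupby("timepoint_h"):
        ref_mean = mean_ct.loc[tp, reference]
        for _, row in grp.iterrows():
            d = row["ct"] - ref_mean - dct.loc[calibrator_timepoint]
            rep_rows.append(
                {"timepoint_h": tp, "sample": row["sample"], "rel": 2.0 ** (-d)}
            )
    rep = pd.DataFrame(rep_rows)
    g = rep.groupby("timepoint_h")["rel"]
    sem = g.sem().reindex(timepoints).to_numpy()
    n_rep = g.size().reindex(timepoints).to_numpy()
    return ExpressionSeries(
        timepoints=timepoints,
        rel_expression=rel,
        sem=sem,
        n_replicates=n_rep,
        replicate_rel=rep,
    )


# --------------------------------------------------------------------------
# Kendall statistics


def _pair_signs(v: np.ndarray) -> np.ndarray:
    """Upper-triangle pairwise difference signs with a tie tolerance."""
    d = v[None, :] - v[:, None]
    s = np.where(np.abs(d) < _TIE_EPS, 0, np.sign(d))
    iu = np.triu_indices(v.size, k=1)
    return s[iu].astype(np.int64)


def kendall_s(x: np.ndarray, y: np.ndarray) -> int:
    """Kendall's S: concordant minus discordant pairs (tied pairs drop out)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise QpcrError("need two equal-length vectors of size >= 2")
    return int(np.sum(_pair_signs(x) * _pair_signs(y)))


def _tie_group_sizes(v: np.ndarray) -> tuple[int, ...]:
    r = np.round(np.asarray(v, dtype=float) / _TIE_EPS).astype(np.int64)
    _, counts = np.unique(r, return_counts=True)
    return tuple(sorted(int(c) for c in counts))


def kendall_tau(x: np.ndarray, y: np.ndarray) -> float:
    """Kendall's tau-b with the standard tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    s = kendall_s(x, y)
    n = x.size
    n0 = n * (n - 1) // 2
    n1 = sum(t * (t - 1) // 2 for t in _tie_group_sizes(x))
    n2 = sum(t * (t - 1) // 2 for t in _tie_group_sizes(y))
    denom = np.sqrt(float(n0 - n1) * float(n0 - n2))
    if denom == 0.0:
        raise QpcrError("tau-b undefined: one vector is entirely tied")
    return float(s / denom)


@lru_cache(maxsize=64)
def kendall_s_null(n: int, template_groups: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of S for an untied data vector of length n
    against a template with the given tie-group sizes.

    Enumerates all n! permutations (chunked, vectorized); feasible for
    n <= 10. Returns (support, probabilities); the distribution is symmetric
    about 0 and sums to 1. The distribution depends on the template only
    through its tie-group multiset, so results are cached on that key.
    """
    if n > EXACT_NULL_MAX_N:
        raise QpcrError(f"exact null enumeration limited to n <= {EXACT_NULL_MAX_N}")
    if sum(template_groups) != n:
        raise QpcrError("template group sizes must sum to n")
    template = np.repeat(np.arange(len(template_groups)), template_groups).astype(float)
    st = _pair_signs(template)
    iu, ju = np.triu_indices(n, k=1)
    counts: dict[int, int] = {}
    chunk = 200_000
    it = itertools.permutations(range(n))
    while True:
        block = list(itertools.islice(it, chunk))
        if not block:
            break
        P = np.asarray(block, dtype=np.int8)
        sp = np.sign(P[:, ju].astype(np.int16) - P[:, iu].astype(np.int16))
        S = sp @ st
        vals, cts = np.unique(S, return_counts=True)
        for v, c in zip(vals, cts):
            counts[int(v)] = counts.get(int(v), 0) + int(c)
    support = np.array(sorted(counts))
    probs = np.array([counts[int(s)] for s in support], dtype=float)
    probs /= probs.sum()
    return support, probs


def _kendall_s_variance(x: np.ndarray, y: np.ndarray) -> float:
    """Null variance of S with tie corrections in either vector."""
    n = x.size
    tx = _tie_group_sizes(x)
    ty = _tie_group_sizes(y)
    v0 = n * (n - 1) * (2 * n + 5)
    vt = sum(t * (t - 1) * (2 * t + 5) for t in tx)
    vu = sum(u * (u - 1) * (2 * u + 5) for u in ty)
    t2 = sum(t * (t - 1) for t in tx)
    u2 = sum(u * (u - 1) for u in ty)
    t3 = sum(t * (t - 1) * (t - 2) for t in tx)
    u3 = sum(u * (u - 1) * (u - 2) for u in ty)
    var = (v0 - vt - vu) / 18.0
    var += t2 * u2 / (2.0 * n * (n - 1))
    if n > 2:
        var += t3 * u3 / (9.0 * n * (n - 1) * (n - 2))
    return var


def kendall_s_p_value(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p for Kendall's S between data ``x`` and template ``y``.

    Exact by enumeration when n <= 10 and the data are untied; otherwise a
    normal approximation with continuity correction and tie-corrected
    variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    s = kendall_s(x, y)
    n = x.size
    data_untied = len(_tie_group_sizes(x)) == n
    if n <= EXACT_NULL_MAX_N and data_untied:
        support, probs = kendall_s_null(n, _tie_group_sizes(y))
        return float(min(probs[np.abs(support) >= abs(s)].sum(), 1.0))
    var = _kendall_s_variance(x, y)
    if var <= 0:
        return 1.0
    z = (abs(s) - 1.0) / np.sqrt(var)
    return float(min(2.0 * norm.sf(max(z, 0.0)), 1.0))


# --------------------------------------------------------------------------
# JTK_CYCLE


def _collapse_replicates(series: ExpressionSeries, how: str = "mean") -> np.ndarray:
    if series.replicate_rel is None or how == "as_is":
        return series.rel_expression
    g = series.replicate_rel.groupby("timepoint_h")["rel"]
    agg = g.mean() if how == "mean" else g.median()
    return agg.reindex(series.timepoints).to_numpy()


def jtk_cycle(
    series: ExpressionSeries,
    candidate_periods: tuple[float, ...] = (20.0, 24.0, 28.0),
    sampling: float | None = None,
    replicate_agg: str = "mean",
) -> JtkResult:
    """Nonparametric rhythm detection on an expression time course.

    For every candidate period and every phase lag on the sampling grid, the
    series is rank-correlated (Kendall tau-b) against a cosine reference
    peaking at that lag; the Kendall-S p-value is computed per combination
    and Bonferroni-adjusted over the whole family. Being rank-based, the
    result is invariant under strictly monotone transforms of the expression
    values. A constant series yields p_adj = 1 with tau undefined.
    """
    t = series.timepoints
    y = _collapse_replicates(series, replicate_agg)
    if sampling is None:
        sampling = float(np.median(np.diff(t)))
    if np.ptp(y) < _TIE_EPS:
        return JtkResult(
            best_period=float("nan"),
            best_lag=float("nan"),
            tau=float("nan"),
            p_value=1.0,
            p_adj=1.0,
            n_tests=0,
            flagged_constant=True,
        )
    rows = []
    for period in candidate_periods:
        for lag in np.arange(0.0, period, sampling):
            template = np.cos(TWO_PI * (t - lag) / period)
            tau = kendall_tau(y, template)
            p = kendall_s_p_value(y, template)
            rows.append({"period": period, "lag": lag, "tau": tau, "p": p})
    table = pd.DataFrame(rows)
    k = len(table)
    table["p_adj"] = np.minimum(table["p"] * k, 1.0)
    # minimal adjusted p; ties broken by the strongest positive correlation
    best = table.sort_values(["p_adj", "tau"], ascending=[True, False]).iloc[0]
    return JtkResult(
        best_period=float(best["period"]),
        best_lag=float(best["lag"]),
        tau=float(best["tau"]),
        p_value=float(best["p"]),
        p_adj=float(best["p_adj"]),
        n_tests=k,
        table=table,
    )


def daily_pattern_summary(
    series: ExpressionSeries, day_window: tuple[float, float] = (0.0, 12.0)
) -> pd.DataFrame:
    """Descriptive day-phase vs night-phase block means (+- SEM).

    Timepoints whose ZT/CT hour mod 24 falls inside ``day_window`` form the
    diurnal block; the rest the nocturnal block. Replicate-level fold changes
    are pooled per block when available. Blocks with a single value get an
    undefined (NaN) SEM and are flagged.
    """
    lo, hi = day_window
    if series.replicate_rel is not None:
        df = series.replicate_rel.rename(columns={"rel": "value"})[["timepoint_h", "value"]]
    else:
        df = pd.DataFrame({"timepoint_h": series.timepoints, "value": series.rel_expression})
    hours = np.mod(df["timepoint_h"].to_numpy(), 24.0)
    df = df.assign(block=np.where((hours >= lo) & (hours < hi), "diurnal", "nocturnal"))
    out = []
    for block, grp in df.groupby("block"):
        vals = grp["value"].to_numpy()
        out.append(
            {
                "block": block,
                "mean": float(vals.mean()),
                "sem": float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan"),
                "n": int(vals.size),
                "sem_defined": vals.size > 1,
            }
        )
    return pd.DataFrame(out).sort_values("block").reset_index(drop=True)
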