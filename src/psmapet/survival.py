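"""Survival stratification and supporting statistics.

Kaplan–Meier product-limit curves and the unweighted (Mantel–Haenszel)
log-rank test drive the biomarker stratification analyses; Wilcoxon
signed-rank, Spearman correlation and one-way ANOVA support the paired and
group comparisons.  Kaplan–Meier and log-rank computations are delegated to
``lifelines``; rank statistics to ``scipy.stats``.

Only baseline scans enter survival analysis; follow-up timepoints are
filtered out before stratification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .imaging import ParameterError

P_DISPLAY_FLOOR = 0.005


class DegenerateSplitError(ValueError):
    """Raised when a biomarker split cannot form two groups."""


class UndefinedTestError(ValueError):
    """Raised when a test's preconditions fail (e.g. zero events)."""


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time_months: float
    event: bool
    tlv_cm3: float = 0.0
    tlu: float = 0.0
    psma_status: str = "positive"
    timepoint: str = "baseline"

    def __post_init__(self) -> None:
        if self.time_months <= 0:
            raise ParameterError("follow-up time must be positive")


@dataclass(frozen=True)
class KMCurve:
    """Step-function survival estimate with at-risk bookkeeping."""

    times: np.ndarray  # distinct observed times, ascending
    survival: np.ndarray  # S(t) immediately after each time
    n_subjects: int

    def probability_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def at_risk_at(self, ticks: Sequence[float], raw_times: np.ndarray) -> list[int]:
        return [int((raw_times >= t).sum()) for t in ticks]


@dataclass(frozen=True)
class StratifiedComparison:
    biomarker: str
    rule: str  # {median_split, q1_vs_q4}
    subset: str  # {all, psma_positive}
    group_sizes: dict[str, int]
    statistic: float
    p_value: float
    curves: dict[str, KMCurve] = field(default_factory=dict)
    at_risk: pd.DataFrame | None = None

    @property
    def p_display(self) -> str:
        return format_p(self.p_value)


def format_p(p: float) -> str:
    """Report small p-values as '< 0.005', otherwise to three decimals."""
    return f"< {P_DISPLAY_FLOOR}" if p < P_DISPLAY_FLOOR else f"{p:.3f}"


# ---------------------------------------------------------------------------
# estimators and tests
# ---------------------------------------------------------------------------

def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    S(t) = Π over distinct event times t_i ≤ t of (1 − d_i/n_i); subjects
    censored at an event time remain in the risk set at that time.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ParameterError("need at least one subject")
    if np.any(t <= 0):
        raise ParameterError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = grid > 0
    return KMCurve(times=grid[keep], survival=surv[keep], n_subjects=t.size)


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[bool],
    times_b: Sequence[float],
    events_b: Sequence[bool],
) -> tuple[float, float]:
    """Two-group unweighted log-rank test: (chi-square statistic, p, 1 df)."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, bool)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, bool)
    if ta.size == 0 or tb.size == 0:
        raise ParameterError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise UndefinedTestError("log-rank test undefined with zero events")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def wilcoxon_signed_rank(differences: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; tied magnitudes are mid-ranked.  The exact
    null distribution is used for n ≤ 25 without ties, otherwise the normal
    approximation with continuity correction.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise UndefinedTestError("all paired differences are zero")
    if d.size < 5:
        raise ParameterError("need at least 5 non-zero differences")
    no_ties = np.unique(np.abs(d)).size == d.size
    method = "exact" if (d.size <= 25 and no_ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method, correction=True)
    return float(res.statistic), float(res.pvalue)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation: Pearson correlation of mid-ranks, t-based p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 4:
        raise ParameterError("need paired samples with n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ParameterError("inputs must be finite")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ParameterError("zero variance in ranks")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def anova_oneway(*groups: Sequence[float]) -> tuple[float, float]:
    """Classical one-way ANOVA F test with (k−1, N−k) degrees of freedom."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ParameterError("need >= 2 groups with >= 2 observations each")
    arrays = [np.asarray(g, float) for g in groups]
    if sum(np.var(a) for a in arrays) == 0:
        raise UndefinedTestError("zero within-group variance everywhere")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


# ---------------------------------------------------------------------------
# biomarker stratification
# ---------------------------------------------------------------------------

_BIOMARKER_COLUMNS = {"tlv": "tlv_cm3", "tlu": "tlu"}


def records_to_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "time_months": [r.time_months for r in records],
            "event": [r.event for r in records],
            "tlv_cm3": [r.tlv_cm3 for r in records],
            "tlu": [r.tlu for r in records],
            "psma_status": [r.psma_status for r in records],
            "timepoint": [r.timepoint for r in records],
        }
    )


def stratify(
    records: Sequence[SurvivalRecord] | pd.DataFrame,
    biomarker: str = "tlu",
    rule: str = "median_split",
    subset: str = "all",
    at_risk_ticks: Sequence[float] | None = None,
) -> StratifiedComparison:
    """Kaplan–Meier stratification of survival by a tumour-burden biomarker.

    ``median_split`` assigns values ≤ median to the low group; ``q1_vs_q4``
    compares the lowest against the highest quartile, with boundaries from
    linear-interpolation quantiles on the analysed subset.  Only baseline
    records are used; ``subset='psma_positive'`` further restricts to
    PSMA-positive scans.  Attaches per-group KM curves and at-risk tables.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df[df["timepoint"] == "baseline"]
    if subset == "psma_positive":
        df = df[df["psma_status"] == "positive"]
    elif subset != "all":
        raise ParameterError(f"unknown subset {subset!r}")
    col = _BIOMARKER_COLUMNS.get(biomarker, biomarker)
    if col not in df.columns:
        raise ParameterError(f"unknown biomarker {biomarker!r}")
    values = df[col].to_numpy(dtype=float)
    if values.size < 4:
        raise ParameterError("need at least 4 baseline records to stratify")
    if np.unique(values).size == 1:
        raise DegenerateSplitError("all biomarker values identical")

    if rule == "median_split":
        cut = float(np.median(values))
        low = df[df[col] <= cut]
        high = df[df[col] > cut]
    elif rule == "q1_vs_q4":
        q1 = float(np.quantile(values, 0.25))
        q3 = float(np.quantile(values, 0.75))
        low = df[df[col] <= q1]
        high = df[df[col] >= q3]
    else:
        raise ParameterError(f"unknown rule {rule!r}")
    if len(low) < 2 or len(high) < 2:
        raise DegenerateSplitError(
            f"split produced groups of sizes {len(low)}/{len(high)}"
        )

    stat, p = logrank_test(
        low["time_months"], low["event"], high["time_months"], high["event"]
    )
    curves = {
        "low": km_estimate(low["time_months"], low["event"]),
        "high": km_estimate(high["time_months"], high["event"]),
    }
    if at_risk_ticks is None:
        tmax = float(df["time_months"].max())
        at_risk_ticks = list(np.arange(0.0, tmax + 12.0, 12.0))
    at_risk = pd.DataFrame(
        {
            "time": list(at_risk_ticks),
            "low": curves["low"].at_risk_at(at_risk_ticks, low["time_months"].to_numpy()),
            "high": curves["high"].at_risk_at(at_risk_ticks, high["time_months"].to_numpy()),
        }
    )
    return StratifiedComparison(
        biomarker=biomarker,
        rule=rule,
        subset=subset,
        group_sizes={"low": len(low), "high": len(high)},
        statistic=stat,
        p_value=p,
        curves=curves,
        at_risk=at_risk,
    )
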