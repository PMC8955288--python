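"""Per-sample summaries and case-control comparisons.

Each distribution parameter (arrays per Gb of assembly, complete-array
spacer counts, ...) is compared between groups independently within each
sequencing series with Welch's t-test, preceded by Shapiro-Wilk normality
checks (recorded as warnings, never blocking) and confirmed with the
two-sided Mann-Whitney U test.  Series are pooled only when case-vs-case
and control-vs-control Welch tests both fail to reject at the chosen
level, for every pair inside the pooled combination.
"""

from __future__ import annotations

import itertools
import math
import warnings
from contextlib import contextmanager
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@contextmanager
def _quiet_precision_warnings():
    """Near-identical samples trip scipy's catastrophic-cancellation warning;
    the resulting p-values are recorded (and flagged degenerate/warned where
    applicable) rather than spamming the log."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield

from .models import GroupComparison, SampleSummary, ValidatedArray

DEFAULT_PARAMETERS = [
    "arrays_per_gb",
    "n_arrays",
    "n_complete_arrays",
    "n_cas_adjacent",
    "n_spacers",
    "spacers_per_complete_array",
    "protospacer_fraction_pct",
]


def summarize_sample(
    arrays: Sequence[ValidatedArray],
    assembly_size_nt: int,
    sample_id: str,
    group: str,
    series: str,
) -> SampleSummary:
    """Table-style per-sample parameters from the validated array set."""
    if assembly_size_nt <= 0:
        raise ValueError("assembly size must be positive")
    gb = assembly_size_nt / 1e9
    complete = [a for a in arrays if a.complete]
    n_spacers = sum(a.n_spacers for a in arrays)
    return SampleSummary(
        sample_id=sample_id,
        group=group,
        series=series,
        assembly_size_gb=gb,
        n_arrays=len(arrays),
        arrays_per_gb=len(arrays) / gb,
        n_complete_arrays=len(complete),
        n_cas_adjacent=sum(1 for a in arrays if "cas_adjacent" in a.support),
        n_spacers=n_spacers,
        spacers_per_complete_array=(
            float(np.mean([a.n_spacers for a in complete])) if complete else float("nan")
        ),
    )


def _clean(values: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    return arr[~np.isnan(arr)]


def compare_groups(
    values_case: Iterable[float],
    values_control: Iterable[float],
    alpha: float = 0.05,
    parameter: str = "",
    scope: str = "",
    pooled: bool = False,
) -> GroupComparison:
    """Welch's t-test with Shapiro-Wilk checks and Mann-Whitney confirmation.

    Degenerate input (both groups constant and equal) is reported as
    t = 0, p = 1 with the `degenerate` flag set.
    """
    case = _clean(values_case)
    control = _clean(values_control)
    if case.size < 2 or control.size < 2:
        raise ValueError("need at least two non-missing values per group")

    def _shapiro(x: np.ndarray) -> float:
        if x.size < 3 or np.ptp(x) == 0:
            return float("nan")
        with _quiet_precision_warnings():
            return float(sps.shapiro(x).pvalue)

    sw_case, sw_control = _shapiro(case), _shapiro(control)
    degenerate = np.ptp(case) == 0 and np.ptp(control) == 0 and case[0] == control[0]
    if degenerate:
        t, p = 0.0, 1.0
        u, mwp = case.size * control.size / 2.0, 1.0
    else:
        with _quiet_precision_warnings():
            t, p = sps.ttest_ind(case, control, equal_var=False)
            exact_ok = max(case.size, control.size) <= 8 and (
                np.unique(np.concatenate([case, control])).size
                == case.size + control.size
            )
            res = sps.mannwhitneyu(
                case, control, alternative="two-sided",
                method="exact" if exact_ok else "asymptotic",
            )
        u, mwp = float(res.statistic), float(res.pvalue)
    normality_warning = any(
        not math.isnan(v) and v <= alpha for v in (sw_case, sw_control)
    )
    return GroupComparison(
        parameter=parameter,
        scope=scope,
        n_case=int(case.size),
        n_control=int(control.size),
        mean_case=float(case.mean()),
        sd_case=float(case.std(ddof=1)),
        mean_control=float(control.mean()),
        sd_control=float(control.std(ddof=1)),
        shapiro_p_case=sw_case,
        shapiro_p_control=sw_control,
        welch_t=float(t),
        welch_p=float(p),
        mww_u=u,
        mww_p=mwp,
        alpha=alpha,
        degenerate=bool(degenerate),
        normality_warning=bool(normality_warning),
        pooled=pooled,
    )


def can_combine_series(
    series_a: dict[str, Iterable[float]],
    series_b: dict[str, Iterable[float]],
    alpha: float = 0.05,
) -> bool:
    """True iff Welch p > alpha for case-vs-case AND control-vs-control
    between the two series (each dict maps group -> values)."""
    for d in (series_a, series_b):
        if not {"case", "control"} <= set(d):
            raise ValueError("each series needs both 'case' and 'control' values")
    for group in ("case", "control"):
        a, b = _clean(series_a[group]), _clean(series_b[group])
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a.size and b.size and a[0] == b[0]:
            continue  # identical constants: p = 1, compatible
        with _quiet_precision_warnings():
            p = sps.ttest_ind(a, b, equal_var=False).pvalue
        if not p > alpha:
            return False
    return True


def summaries_to_frame(summaries: Sequence[SampleSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


def run_cohort_analysis(
    summaries: Sequence[SampleSummary] | pd.DataFrame,
    parameters: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> list[GroupComparison]:
    """One comparison per parameter per series, plus pooled comparisons for
    every series combination whose members are pairwise compatible for that
    parameter (all case-vs-case and control-vs-control Welch tests above
    alpha).  Deterministic ordering: parameter, then series, then pooled
    combinations by size and label."""
    df = summaries if isinstance(summaries, pd.DataFrame) else summaries_to_frame(summaries)
    parameters = [p for p in (parameters or DEFAULT_PARAMETERS) if p in df.columns]
    series_labels = sorted(df["series"].unique())
    out: list[GroupComparison] = []
    for param in parameters:
        values: dict[str, dict[str, np.ndarray]] = {}
        for s in series_labels:
            sub = df[df["series"] == s]
            values[s] = {
                g: _clean(sub.loc[sub["group"] == g, param]) for g in ("case", "control")
            }
        usable = [
            s for s in series_labels
            if values[s]["case"].size >= 2 and values[s]["control"].size >= 2
        ]
        for s in usable:
            out.append(
                compare_groups(values[s]["case"], values[s]["control"], alpha,
                               parameter=param, scope=s)
            )
        for size in range(2, len(usable) + 1):
            for combo in itertools.combinations(usable, size):
                ok = all(
                    can_combine_series(values[a], values[b], alpha)
                    for a, b in itertools.combinations(combo, 2)
                )
                if not ok:
                    continue
                case = np.concatenate([values[s]["case"] for s in combo])
                control = np.concatenate([values[s]["control"] for s in combo])
                out.append(
                    compare_groups(case, control, alpha, parameter=param,
                                   scope="+".join(combo), pooled=True)
                )
    return out


def comparisons_to_frame(comparisons: Sequence[GroupComparison],
                         bonferroni_m: int | None = None) -> pd.DataFrame:
    """Tabular report; optionally appends a Bonferroni-adjusted Welch p
    column for m tests (reported as an extension, not used for decisions)."""
    df = pd.DataFrame([vars(c) for c in comparisons])
    if bonferroni_m is None:
        bonferroni_m = len(comparisons)
    if len(df):
        df["welch_p_bonferroni"] = (df["welch_p"] * bonferroni_m).clip(upper=1.0)
    return df
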