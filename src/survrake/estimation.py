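"""Weighted prevalence estimation and weighting-effectiveness summaries.

Prevalence of a categorical characteristic under calibration weights is the
Hajek ratio estimator ``p = sum(w_i y_i) / sum(w_i)`` per category, with a
single-stage with-replacement Taylor linearisation variance

    var(p) = n/(n-1) * sum_i ( w_i (y_i - p) / sum(w) )^2

and a t-based 95% confidence interval — the estimator survey software
computes for a weighted proportion under one-stage WR sampling.  The margin of
error is the distance from the point estimate to a confidence limit.

Effectiveness of a weighting scheme is summarised against an external
benchmark survey by four descriptive measures: CI overlap, benchmark-in-CI,
point estimates moved closer, and the distribution of absolute differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .margins import MISSING, BenchmarkTable
from .weighting import WeightVector

logger = logging.getLogger(__name__)


@dataclass
class PrevalenceTable:
    """Per-category prevalence estimates (percent) for one characteristic.

    ``table`` columns: category, n, estimate, se, lower, upper,
    margin_of_error — all percentages except n.
    """

    characteristic: str
    scheme: str
    table: pd.DataFrame
    n: int = 0

    def row(self, category: str) -> pd.Series:
        sub = self.table[self.table["category"] == category]
        if sub.empty:
            raise KeyError(f"category {category!r} not in table")
        return sub.iloc[0]

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "characteristic", self.characteristic)
        out.insert(1, "scheme", self.scheme)
        out.to_csv(path, index=False)


def weighted_prevalence(
    sample: pd.DataFrame,
    weights: WeightVector | np.ndarray | None,
    characteristic: str,
    alpha: float = 0.05,
    use_t: bool = True,
    scheme: str | None = None,
) -> PrevalenceTable:
    """Weighted prevalence with linearised SEs and CIs for one characteristic.

    ``weights=None`` gives the unweighted (uniform-weight) estimates.  Missing
    values are reported as their own category.  CIs are truncated to
    [0, 100]%.
    """
    if characteristic not in sample.columns:
        raise KeyError(f"characteristic {characteristic!r} not in sample")
    n = len(sample)
    if n == 0:
        raise ValueError("empty sample")
    if weights is None:
        w = np.ones(n)
        scheme = scheme or "unweighted"
    else:
        w = weights.weights if isinstance(weights, WeightVector) else np.asarray(weights, float)
        scheme = scheme or (weights.method if isinstance(weights, WeightVector) else "weighted")
    if len(w) != n:
        raise ValueError(f"{len(w)} weights for {n} rows")
    wsum = float(w.sum())
    if wsum <= 0:
        raise ValueError("total weight must be positive")

    col = sample[characteristic].astype(str).where(~sample[characteristic].isna(), MISSING)
    cats = [c for c in col.unique() if c != MISSING]
    cats = sorted(cats) + ([MISSING] if (col == MISSING).any() else [])

    crit = stats.t.ppf(1 - alpha / 2, n - 1) if use_t else stats.norm.ppf(1 - alpha / 2)
    rows = []
    for cat in cats:
        y = (col == cat).to_numpy(float)
        p = float((w * y).sum() / wsum)
        resid = w * (y - p) / wsum
        var = n / (n - 1) * float((resid**2).sum()) if n > 1 else 0.0
        se = 100.0 * np.sqrt(var)
        est = 100.0 * p
        lower = max(0.0, est - crit * se)
        upper = min(100.0, est + crit * se)
        rows.append(
            {
                "category": cat,
                "n": int(y.sum()),
                "estimate": est,
                "se": se,
                "lower": lower,
                "upper": upper,
                "margin_of_error": max(est - lower, upper - est),
            }
        )
    return PrevalenceTable(characteristic, scheme, pd.DataFrame(rows), n=n)


def prevalence_to_benchmark(
    tables: list[PrevalenceTable], source: str
) -> BenchmarkTable:
    """Repackage prevalence tables as a BenchmarkTable (for cross-survey use)."""
    rows = []
    for t in tables:
        for r in t.table.itertuples():
            rows.append(
                {
                    "characteristic": t.characteristic,
                    "category": r.category,
                    "estimate": r.estimate,
                    "lower": r.lower,
                    "upper": r.upper,
                }
            )
    return BenchmarkTable(source, pd.DataFrame(rows))


def average_benchmarks(tables: list[BenchmarkTable]) -> BenchmarkTable:
    """Average benchmark estimates from repeated survey waves, category-wise.

    Point estimates are averaged arithmetically.  CI bounds are averaged
    bound-wise only when every input carries CIs; otherwise the output has
    points only and a notice is logged.
    """
    if not tables:
        raise ValueError("no benchmark tables to average")
    keys = ["characteristic", "category"]
    ref = tables[0].table[keys].sort_values(keys).reset_index(drop=True)
    for t in tables[1:]:
        other = t.table[keys].sort_values(keys).reset_index(drop=True)
        if not ref.equals(other):
            raise ValueError(
                f"benchmark tables {tables[0].source!r} and {t.source!r} "
                "cover different categories"
            )
    all_ci = all(t.has_ci for t in tables)
    if not all_ci and any(t.has_ci for t in tables):
        logger.info(
            "averaging benchmarks: not all inputs carry CIs; output has point "
            "estimates only"
        )
    merged = ref.copy()
    cols = ["estimate"] + (["lower", "upper"] if all_ci else [])
    for c in cols:
        stack = [
            t.table.sort_values(keys).reset_index(drop=True)[c].to_numpy(float)
            for t in tables
        ]
        merged[c] = np.mean(stack, axis=0)
    name = "+".join(t.source for t in tables)
    return BenchmarkTable(name, merged)


@dataclass
class EffectivenessSummary:
    """The four weighting-effectiveness measures against one benchmark.

    Per scheme (including ``"unweighted"`` where applicable):

    - ``overlap``: categories whose 95% CI overlaps the benchmark's
      (closed-interval overlap; only computed when the benchmark has CIs);
    - ``within_ci``: categories with the benchmark point inside the scheme CI;
    - ``moved_closer``: categories where the weighted point estimate is
      strictly closer to the benchmark than the unweighted one (weighted
      schemes only);
    - ``abs_diff_median`` / ``abs_diff_q1`` / ``abs_diff_q3``: distribution of
      absolute point-estimate differences from the benchmark.
    """

    benchmark: str
    n_categories: int
    measures: pd.DataFrame  # one row per scheme
    dropped_categories: list[tuple[str, str]] = field(default_factory=list)

    def row(self, scheme: str) -> pd.Series:
        sub = self.measures[self.measures["scheme"] == scheme]
        if sub.empty:
            raise KeyError(f"scheme {scheme!r} not summarised")
        return sub.iloc[0]

    def to_csv(self, path) -> None:
        out = self.measures.copy()
        out.insert(0, "benchmark", self.benchmark)
        out.to_csv(path, index=False)


def _match(benchmark: BenchmarkTable, tables: list[PrevalenceTable]) -> pd.DataFrame:
    """Long frame of matched (characteristic, category) rows, missing excluded."""
    study = pd.concat(
        [
            t.table.assign(characteristic=t.characteristic)
            for t in tables
        ],
        ignore_index=True,
    )
    study = study[study["category"] != MISSING]
    keys = ["characteristic", "category"]
    merged = study.merge(
        benchmark.table, on=keys, how="inner", suffixes=("", "_bm")
    )
    return merged


def effectiveness_summary(
    benchmark: BenchmarkTable,
    unweighted: list[PrevalenceTable],
    weighted: dict[str, list[PrevalenceTable]],
) -> EffectivenessSummary:
    """The four summary measures of weighting effectiveness.

    Comparisons use unrounded point estimates; "moved closer" is a strict
    inequality, so a scheme identical to unweighted scores zero.  Categories
    labelled missing are excluded; study categories absent from the benchmark
    are dropped with a logged notice.
    """
    un = _match(benchmark, unweighted)
    if un.empty:
        raise ValueError("no common categories between study tables and benchmark")
    keys = ["characteristic", "category"]
    all_study = pd.concat(
        [t.table.assign(characteristic=t.characteristic) for t in unweighted],
        ignore_index=True,
    )
    all_study = all_study[all_study["category"] != MISSING]
    dropped = (
        all_study.merge(benchmark.table[keys], on=keys, how="left", indicator=True)
        .query("_merge == 'left_only'")[keys]
        .itertuples(index=False)
    )
    dropped = [tuple(r) for r in dropped]
    if dropped:
        logger.info(
            "effectiveness: %d study categories absent from benchmark %r dropped: %s",
            len(dropped), benchmark.source, dropped,
        )

    has_ci = benchmark.has_ci
    n_cat = len(un)

    def summarise(matched: pd.DataFrame, scheme: str, un_diff: pd.Series | None):
        diff = (matched["estimate"] - matched["estimate_bm"]).abs()
        row = {
            "scheme": scheme,
            "within_ci": int(
                (
                    (matched["lower"] <= matched["estimate_bm"])
                    & (matched["estimate_bm"] <= matched["upper"])
                ).sum()
            ),
            "abs_diff_median": float(diff.median()),
            "abs_diff_q1": float(diff.quantile(0.25)),
            "abs_diff_q3": float(diff.quantile(0.75)),
        }
        if has_ci:
            row["overlap"] = int(
                (
                    (matched["lower"] <= matched["upper_bm"])
                    & (matched["lower_bm"] <= matched["upper"])
                ).sum()
            )
        else:
            row["overlap"] = np.nan
        if un_diff is not None:
            row["moved_closer"] = int((diff.to_numpy() < un_diff.to_numpy()).sum())
        else:
            row["moved_closer"] = np.nan
        return row

    un_sorted = un.sort_values(keys).reset_index(drop=True)
    un_diff = (un_sorted["estimate"] - un_sorted["estimate_bm"]).abs()
    rows = [summarise(un_sorted, "unweighted", None)]
    for scheme, tables in weighted.items():
        m = _match(benchmark, tables).sort_values(keys).reset_index(drop=True)
        if len(m) != n_cat or not m[keys].equals(un_sorted[keys]):
            raise ValueError(
                f"scheme {scheme!r} covers different categories than unweighted"
            )
        rows.append(summarise(m, scheme, un_diff))
    measures = pd.DataFrame(rows)
    return EffectivenessSummary(benchmark.source, n_cat, measures, dropped)


def margin_of_error_summary(
    tables_by_scheme: dict[str, list[PrevalenceTable]]
) -> pd.Series:
    """Mean margin of error across all categories per weighting scheme.

    Missing categories are excluded, matching how effectiveness comparisons
    count categories.
    """
    out = {}
    for scheme, tables in tables_by_scheme.items():
        if not tables:
            raise ValueError(f"no prevalence tables for scheme {scheme!r}")
        moes = np.concatenate(
            [
                t.table.loc[t.table["category"] != MISSING, "margin_of_error"].to_numpy(float)
                for t in tables
            ]
        )
        out[scheme] = float(moes.mean())
    return pd.Series(out, name="mean_margin_of_error")


def round_half_even(values, decimals: int = 1):
    """Reporting rounding (banker's rounding, 1 dp) for printed tables."""
    return np.round(np.asarray(values, dtype=float), decimals)
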