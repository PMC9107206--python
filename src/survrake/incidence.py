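"""Person-years, standardised incidence ratios and Fieller confidence intervals.

Cohort incidence is compared with a reference population by indirect
standardisation: the expected number of cases ``E`` applies reference
sex-age-specific rates to the cohort's person-years at risk, accumulated per
5-year age band by splitting each person's follow-up at band boundaries
(a Lexis expansion on the age axis).  The standardised incidence ratio is
``SIR = O / E`` with ``O`` the (possibly calibration-weighted) observed count.

Because ``O`` and ``E`` are estimated from the same weighted sample they are
correlated; the SIR confidence interval therefore uses Fieller's method for a
ratio of two correlated estimates: the bounds are the roots in ``theta`` of

    (E^2 - z^2 V_E) theta^2 - 2 (O E - z^2 C) theta + (O^2 - z^2 V_O) = 0

with ``V_O``, ``V_E`` and ``C`` the linearisation variances and covariance of
the weighted totals.  Direct age-standardised rates against a fixed standard
population are also provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .margins import RateTable, band_label, parse_age_bands
from .weighting import WeightVector

logger = logging.getLogger(__name__)

#: Default 5-year age-band labels for a 45+ cohort, top band open.
DEFAULT_BANDS = [
    "45-49", "50-54", "55-59", "60-64", "65-69", "70-74", "75-79", "80-84", "85+",
]


class IncidenceError(ValueError):
    """Invalid inputs to a person-time or standardisation computation."""


def person_years(
    sample: pd.DataFrame,
    window: tuple[float, float],
    cancer: str | None = None,
    bands: list[str] | None = None,
) -> pd.DataFrame:
    """Split each unit's follow-up into 5-year age bands (Lexis expansion).

    Follow-up runs from ``max(entry, window start)`` to
    ``min(diagnosis, death, window end)`` on a decimal-year time axis, and is
    split exactly at age-band boundaries, so summing ``py`` over bands
    reproduces each unit's raw follow-up time.  Bands are half-open
    ``[lower, upper)``: a diagnosis exactly on a boundary age belongs to the
    band being entered.

    Parameters
    ----------
    sample : DataFrame
        Needs columns ``sex``, ``entry`` (decimal year), ``age_at_entry``
        (decimal years) and ``death`` (decimal year, NaN if alive); with
        ``cancer`` given, also ``diag_<cancer>``.
    window : (start, end)
        Calendar window, decimal years; follow-up is clipped to it.
    cancer : str, optional
        Truncate follow-up at this cancer's diagnosis and emit an ``event``
        indicator in the band containing the age at diagnosis.

    Returns
    -------
    DataFrame with columns unit, sex, age_band, py, event — one row per unit
    x band with positive person-time (plus the event row when the event lands
    at a band boundary with zero time in the band).
    """
    start_cal, end_cal = window
    if not start_cal < end_cal:
        raise IncidenceError(f"window start {start_cal} must precede end {end_cal}")
    for col in ["sex", "entry", "age_at_entry"]:
        if col not in sample.columns:
            raise IncidenceError(f"sample lacks column {col!r}")
    labels = bands or DEFAULT_BANDS
    edges = parse_age_bands(labels)

    entry = sample["entry"].to_numpy(float)
    age_entry = sample["age_at_entry"].to_numpy(float)
    death = sample["death"].to_numpy(float) if "death" in sample.columns else np.full(len(sample), np.nan)

    t0 = np.maximum(entry, start_cal)
    t1 = np.fmin(death, end_cal)
    diag = np.full(len(sample), np.nan)
    if cancer is not None:
        col = f"diag_{cancer}"
        if col not in sample.columns:
            raise IncidenceError(f"sample lacks column {col!r}")
        diag = sample[col].to_numpy(float)
        if np.any(diag[np.isfinite(diag)] <= entry[np.isfinite(diag)]):
            raise IncidenceError(
                "prevalent cases (diagnosis at or before entry) must be "
                "excluded before person-years computation"
            )
        t1 = np.fmin(t1, diag)

    n_invalid = int((entry > end_cal).sum())
    if n_invalid:
        logger.info("%d units enter after the window end; they contribute 0 py", n_invalid)
    valid = t1 > t0
    event = np.isfinite(diag) & (diag <= end_cal) & (diag > t0)
    event &= ~(np.isfinite(death) & (diag > death))  # cannot be diagnosed after death
    keep = valid | event
    if not keep.any():
        return pd.DataFrame(columns=["unit", "sex", "age_band", "py", "event"])

    idx = np.flatnonzero(keep)
    a0 = age_entry[idx] + (t0[idx] - entry[idx])
    a1 = age_entry[idx] + (np.maximum(t1[idx], t0[idx]) - entry[idx])
    if np.any(a0 < edges[0] - 1e-9):
        raise IncidenceError(
            f"follow-up starts below the first age band ({edges[0]:.0f})"
        )
    age_diag = age_entry[idx] + (diag[idx] - entry[idx])
    ev = event[idx]
    # band of the event: half-open [lo, hi) => exact boundary -> entering band
    ev_band = np.searchsorted(edges, np.where(np.isfinite(age_diag), age_diag, edges[0]), side="right") - 1

    frames = []
    units = sample.index.to_numpy()[idx]
    sexes = sample["sex"].to_numpy()[idx]
    for b in range(len(labels)):
        lo, hi = edges[b], edges[b + 1]
        py = np.clip(np.minimum(a1, hi) - np.maximum(a0, lo), 0.0, None)
        e_here = ev & (ev_band == b)
        m = (py > 0) | e_here
        if not m.any():
            continue
        frames.append(
            pd.DataFrame(
                {
                    "unit": units[m],
                    "sex": sexes[m],
                    "age_band": band_label(edges, b),
                    "py": py[m],
                    "event": e_here[m].astype(int),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["unit", "age_band"], kind="stable").reset_index(drop=True)


def expected_cases(
    pt: pd.DataFrame,
    rates: RateTable,
    weights: WeightVector | np.ndarray | None = None,
    cancer: str | None = None,
    unit_index: pd.Index | None = None,
) -> tuple[float, pd.Series]:
    """Expected cases by indirect standardisation.

    Per-unit expectation ``e_i = sum_s lambda_s * py_is`` over the sex-age
    strata the unit traverses; the total is ``E = sum_i w_i e_i``.  Reference
    rates are treated as known constants.

    ``unit_index`` (default: unique units in ``pt``) fixes the order of the
    returned per-unit Series, so weights can be aligned positionally.
    """
    rt = rates.table
    if cancer is not None and "cancer" in rt.columns:
        rt = rt[rt["cancer"] == cancer]
    merged = pt.merge(rt[["sex", "age_band", "rate"]], on=["sex", "age_band"], how="left")
    occupied = merged["py"] > 0
    if merged.loc[occupied, "rate"].isna().any():
        bad = (
            merged.loc[occupied & merged["rate"].isna(), ["sex", "age_band"]]
            .drop_duplicates()
            .to_dict("records")
        )
        raise IncidenceError(f"no reference rate for occupied strata: {bad}")
    merged["rate"] = merged["rate"].fillna(0.0)
    e_by_unit = (merged["rate"] * merged["py"]).groupby(merged["unit"]).sum()
    if unit_index is not None:
        e_by_unit = e_by_unit.reindex(unit_index, fill_value=0.0)
    if weights is None:
        w = np.ones(len(e_by_unit))
    else:
        w = weights.weights if isinstance(weights, WeightVector) else np.asarray(weights, float)
        if len(w) != len(e_by_unit):
            raise IncidenceError(f"{len(w)} weights for {len(e_by_unit)} units")
    E = float((w * e_by_unit.to_numpy()).sum())
    return E, e_by_unit


def weighted_total_variance(
    values, weights=None
) -> tuple[float, float]:
    """Weighted total and its with-replacement linearisation variance.

    ``total = sum_i w_i v_i``;
    ``var = n/(n-1) * sum_i (w_i v_i - total/n)^2`` — the one-stage
    with-replacement variance of a weighted total.
    """
    v = np.asarray(values, float)
    n = len(v)
    if n < 2:
        raise IncidenceError("variance of a weighted total needs n >= 2")
    w = np.ones(n) if weights is None else _as_w(weights, n)
    z = w * v
    total = float(z.sum())
    var = n / (n - 1) * float(((z - total / n) ** 2).sum())
    return total, var


def weighted_total_covariance(values_a, values_b, weights=None) -> float:
    """Linearisation covariance of two weighted totals over the same units."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    n = len(a)
    if len(b) != n:
        raise IncidenceError("value vectors must align")
    if n < 2:
        raise IncidenceError("covariance of weighted totals needs n >= 2")
    w = np.ones(n) if weights is None else _as_w(weights, n)
    za, zb = w * a, w * b
    return n / (n - 1) * float(((za - za.mean()) * (zb - zb.mean())).sum())


def _as_w(weights, n: int) -> np.ndarray:
    w = weights.weights if isinstance(weights, WeightVector) else np.asarray(weights, float)
    if len(w) != n:
        raise IncidenceError(f"{len(w)} weights for {n} values")
    return w


@dataclass
class SIRResult:
    """A standardised incidence ratio with its Fieller confidence interval."""

    observed: float
    expected: float
    var_observed: float
    var_expected: float
    covariance: float
    sir: float
    lower: float
    upper: float
    z: float
    alpha: float
    method: str = "fieller"
    cancer: str | None = None
    scheme: str | None = None

    def covers(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    def to_dict(self) -> dict:
        return {
            "cancer": self.cancer,
            "scheme": self.scheme,
            "observed": self.observed,
            "expected": self.expected,
            "sir": self.sir,
            "lower": self.lower,
            "upper": self.upper,
            "method": self.method,
        }


def sir_fieller(
    O: float,
    E: float,
    var_O: float,
    var_E: float = 0.0,
    cov: float = 0.0,
    alpha: float = 0.05,
    cancer: str | None = None,
    scheme: str | None = None,
) -> SIRResult:
    """Fieller confidence interval for the ratio ``O/E`` of correlated totals.

    The bounds are the two real roots of

        (E^2 - z^2 V_E) t^2 - 2 (O E - z^2 C) t + (O^2 - z^2 V_O) = 0,

    which requires the denominator to be significantly positive
    (``E^2 > z^2 V_E``).  With all variances zero the interval collapses to
    the point estimate.
    """
    if not E > 0:
        raise IncidenceError(f"expected count must be positive, got {E}")
    if O < 0:
        raise IncidenceError(f"observed count must be non-negative, got {O}")
    z = float(stats.norm.ppf(1 - alpha / 2))
    sir = O / E
    if var_O == 0.0 and var_E == 0.0 and cov == 0.0:
        return SIRResult(O, E, 0.0, 0.0, 0.0, sir, sir, sir, z, alpha,
                         cancer=cancer, scheme=scheme)
    a = E**2 - z**2 * var_E
    if a <= 0:
        raise IncidenceError(
            "Fieller denominator not significantly positive "
            f"(E^2 = {E**2:.4g} <= z^2 V_E = {z**2 * var_E:.4g})"
        )
    b = -2.0 * (O * E - z**2 * cov)
    c = O**2 - z**2 * var_O
    disc = b**2 - 4 * a * c
    if disc < 0:
        raise IncidenceError(
            f"negative Fieller discriminant (a={a:.4g}, b={b:.4g}, c={c:.4g})"
        )
    root = np.sqrt(disc)
    lo, hi = sorted([(-b - root) / (2 * a), (-b + root) / (2 * a)])
    return SIRResult(O, E, var_O, var_E, cov, sir, lo, hi, z, alpha,
                     cancer=cancer, scheme=scheme)


def sir_pipeline(
    sample: pd.DataFrame,
    weights: WeightVector | np.ndarray | None,
    rates: RateTable,
    window: tuple[float, float],
    cancer: str,
    alpha: float = 0.05,
    bands: list[str] | None = None,
    fixed_expected: bool = False,
    max_age: float | None = None,
    scheme: str | None = None,
) -> SIRResult:
    """Observed/expected counts and Fieller CI for one cancer type.

    Restricts to the sexes carrying reference rates for the cancer (so
    breast/prostate analyses are sex-specific), computes per-unit event
    indicators and expectations, and propagates the linearisation variances
    and covariance of the weighted totals into the Fieller interval.

    ``fixed_expected=True`` treats E as a constant (V_E = C = 0).
    ``max_age`` truncates follow-up at that age — a sensitivity analysis for
    cohorts that deliberately over-sample the very old.
    """
    rt = rates.table
    if "cancer" in rt.columns:
        rt_c = rt[rt["cancer"] == cancer]
        if rt_c.empty:
            raise IncidenceError(f"no reference rates for cancer {cancer!r}")
    else:
        rt_c = rt
    sexes = set(rt_c["sex"].unique())
    mask = sample["sex"].isin(sexes).to_numpy()
    sub = sample.loc[mask]
    if sub.empty:
        raise IncidenceError(f"no units of the sexes {sorted(sexes)} in the sample")
    if weights is None:
        w = np.ones(mask.sum())
    else:
        w = _as_w(weights, len(sample))[mask]
        scheme = scheme or (weights.method if isinstance(weights, WeightVector) else None)

    band_labels = bands or DEFAULT_BANDS
    if max_age is not None:
        edges = parse_age_bands(band_labels)
        band_labels = [
            band_label(edges, i) for i in range(len(band_labels)) if edges[i] < max_age
        ]
        # truncate follow-up at max_age via an artificial censoring date
        sub = sub.copy()
        t_cap = sub["entry"] + (max_age - sub["age_at_entry"])
        sub["death"] = np.fmin(sub["death"].to_numpy(float), t_cap.to_numpy(float))
        keep = (sub["age_at_entry"] < max_age).to_numpy()
        sub, w = sub.loc[keep], w[np.asarray(keep)]

    pt = person_years(sub, window, cancer=cancer, bands=band_labels)
    unit_index = pd.Index(sub.index)
    E, e_i = expected_cases(pt, rates, weights=w, cancer=cancer, unit_index=unit_index)
    d_i = pt.groupby("unit")["event"].max().reindex(unit_index, fill_value=0).astype(float)

    O, var_O = weighted_total_variance(d_i.to_numpy(), w)
    if fixed_expected:
        var_E = cov = 0.0
    else:
        _, var_E = weighted_total_variance(e_i.to_numpy(), w)
        cov = weighted_total_covariance(d_i.to_numpy(), e_i.to_numpy(), w)
    return sir_fieller(O, E, var_O, var_E, cov, alpha=alpha, cancer=cancer, scheme=scheme)


def rates_from_cohort(
    sample: pd.DataFrame,
    window: tuple[float, float],
    cancers: list[str],
    bands: list[str] | None = None,
    name: str = "cohort rates",
) -> RateTable:
    """Registry-style sex-age-specific incidence rates from unit records.

    For each cancer, events divided by person-years per sex x age band.
    Applied to a whole (synthetic) population this yields the
    whole-of-population reference rates that indirect standardisation
    compares a cohort against.  Strata with no person-time get rate 0.
    """
    rows = []
    for cancer in cancers:
        pt = person_years(sample, window, cancer=cancer, bands=bands)
        g = pt.groupby(["sex", "age_band"])[["py", "event"]].sum().reset_index()
        g = g[g["py"] > 0]
        for r in g.itertuples():
            rows.append(
                {
                    "cancer": cancer,
                    "sex": r.sex,
                    "age_band": r.age_band,
                    "rate": r.event / r.py,
                }
            )
    return RateTable(pd.DataFrame(rows), name=name)


def direct_asr(
    events, person_years_by_band, standard_weights, per: float = 1e5
) -> float:
    """Directly age-standardised rate against a fixed standard population.

    ``ASR = sum_a (d_a / PY_a) W_a / sum_a W_a`` expressed per ``per``
    person-years; arrays align band-wise.
    """
    d = np.asarray(events, float)
    py = np.asarray(person_years_by_band, float)
    W = np.asarray(standard_weights, float)
    if not (len(d) == len(py) == len(W)):
        raise IncidenceError("band arrays must align")
    zero = (py == 0) & (W > 0)
    if zero.any():
        raise IncidenceError(
            f"zero person-years in bands with positive standard weight: {np.flatnonzero(zero)}"
        )
    rates = np.divide(d, py, out=np.zeros_like(d), where=py > 0)
    return float((rates * W).sum() / W.sum() * per)
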