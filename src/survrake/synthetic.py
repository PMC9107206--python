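"""Synthetic target populations, biased samples and cancer follow-up.

Calibration methods can only be validated end to end when the truth is known.
This module generates (i) a target population over categorical demographics
with a declared joint distribution and logistic outcome models, (ii) a
non-representative sample drawn with unit-level selection propensities that
can over-sample the old and rural and under-sample smokers and people in poor
health — the qualitative bias structure of volunteer cohorts — and (iii)
per-person cancer diagnosis, death and censoring histories from
piecewise-exponential hazards over a fixed calendar window.

The joint demographic distribution is an independence model perturbed by
declared pairwise log odds-ratios and then calibrated back to the declared
marginals by iterative proportional fitting of the joint cell table (the same
IPF engine used for raking).  Ages are continuous; 5-year bands are derived,
with the top band open.

All randomness flows through a single integer seed per operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .margins import MISSING, MarginSet, RateTable, band_label, parse_age_bands
from .weighting import Raker, RakingConfig

__all__ = [
    "PopulationSpec",
    "SelectionSpec",
    "IncidenceSpec",
    "generate_population",
    "draw_sample",
    "simulate_followup",
    "inject_missingness",
    "default_population_spec",
    "default_selection_spec",
    "demographic_selection_spec",
    "default_incidence_spec",
    "read_cohort",
    "write_cohort",
]


class SpecValidationError(ValueError):
    """A synthesis spec references undeclared fields or violates an invariant."""


@dataclass
class PopulationSpec:
    """Declarative description of a target population.

    characteristics
        Ordered mapping ``name -> {category: marginal probability}``; each
        characteristic's probabilities must sum to 1.
    pairwise_log_or
        ``{(char_a, cat_a, char_b, cat_b): log odds-ratio}`` perturbations of
        the independence model; the joint table is re-calibrated to the
        declared marginals afterwards, so these shape associations without
        moving margins.
    outcome_models
        ``{outcome: {"intercept": b0, "effects": {(char, cat): b}}}`` on the
        logit scale; outcomes are binary ("Yes"/"No").
    population_size
        Number of persons to realise.
    age_characteristic
        Which characteristic holds 5-year age bands (continuous ages are
        drawn within the realised band; the open top band gets an exponential
        tail with mean ``open_band_mean_years``).
    recruitment_period
        Calendar interval (decimal years) over which entry dates are drawn
        uniformly.
    """

    characteristics: dict[str, dict[str, float]]
    pairwise_log_or: dict[tuple[str, str, str, str], float] = field(default_factory=dict)
    outcome_models: dict[str, dict] = field(default_factory=dict)
    population_size: int = 100_000
    age_characteristic: str | None = "age_group"
    recruitment_period: tuple[float, float] = (2006.0, 2010.0)
    open_band_mean_years: float = 4.0

    def __post_init__(self) -> None:
        if not self.population_size > 0:
            raise SpecValidationError(
                f"population_size must be positive, got {self.population_size}"
            )
        for char, probs in self.characteristics.items():
            p = np.array(list(probs.values()), dtype=float)
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-8:
                raise SpecValidationError(
                    f"marginal probabilities of {char!r} must be non-negative "
                    f"and sum to 1 (sum {p.sum():.6f})"
                )
        for key in self.pairwise_log_or:
            ca, xa, cb, xb = key
            for c, x in [(ca, xa), (cb, xb)]:
                if c not in self.characteristics or x not in self.characteristics[c]:
                    raise SpecValidationError(
                        f"pairwise_log_or references undeclared category {c}={x!r}"
                    )
        for outcome, model in self.outcome_models.items():
            if "intercept" not in model:
                raise SpecValidationError(f"outcome {outcome!r} lacks an intercept")
            for (c, x) in model.get("effects", {}):
                if c not in self.characteristics or x not in self.characteristics[c]:
                    raise SpecValidationError(
                        f"outcome {outcome!r} references undeclared category {c}={x!r}"
                    )
        if self.age_characteristic is not None and (
            self.age_characteristic not in self.characteristics
        ):
            raise SpecValidationError(
                f"age_characteristic {self.age_characteristic!r} is not declared"
            )


@dataclass
class SelectionSpec:
    """Unit-level selection propensities on the logit scale.

    ``propensity_i = expit(logit(base_rate) + sum of logit_effects matching
    unit i's categories)``.  Effects may reference demographics or outcomes,
    so selection can depend on health/behaviour (the mechanism full raking
    cannot fully correct).
    """

    base_rate: float = 0.18
    logit_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.base_rate < 1.0:
            raise SpecValidationError(
                f"base_rate must be in (0, 1), got {self.base_rate}"
            )

    def propensities(self, table: pd.DataFrame) -> np.ndarray:
        lp = np.full(len(table), logit(self.base_rate))
        for (field_name, cat), eff in self.logit_effects.items():
            if field_name not in table.columns:
                raise SpecValidationError(
                    f"logit_effects references absent field {field_name!r}"
                )
            lp = lp + eff * (table[field_name].astype(str) == cat).to_numpy(float)
        p = expit(lp)
        if not ((p > 0) & (p < 1)).all():
            raise SpecValidationError("selection propensities must lie in (0, 1)")
        return p


@dataclass
class IncidenceSpec:
    """Hazards for the follow-up simulation.

    rate_table
        Reference incidence per person-year by sex x age band x cancer.
    frailty_effects
        ``{cancer: {(field, category): rate ratio}}`` multiplicative
        modifiers applied to a unit's hazard (e.g. smoking -> lung cancer).
    death_rate_table
        All-cause mortality per person-year by sex x age band.
    window
        Calendar window (decimal years): events are simulated from entry
        until the window end; diagnoses before the window start end up
        censored out by the person-years computation.
    """

    rate_table: RateTable
    death_rate_table: RateTable
    frailty_effects: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)
    window: tuple[float, float] = (2009.0, 2014.0)

    def __post_init__(self) -> None:
        if not self.window[0] < self.window[1]:
            raise SpecValidationError(f"window start must precede end: {self.window}")
        for cancer, effs in self.frailty_effects.items():
            for (f, c), rr in effs.items():
                if rr < 0:
                    raise SpecValidationError(
                        f"frailty rate ratio for {cancer}/{f}={c} is negative"
                    )

    @property
    def cancers(self) -> list[str]:
        if "cancer" in self.rate_table.table.columns:
            return sorted(self.rate_table.table["cancer"].unique())
        return ["cancer"]


# ---------------------------------------------------------------------------
# population generation

def _joint_cell_table(spec: PopulationSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Joint cell probabilities: perturbed independence, IPF'd to marginals."""
    chars = list(spec.characteristics)
    cats = {c: list(spec.characteristics[c]) for c in chars}
    grid = pd.MultiIndex.from_product(list(cats.values()), names=chars).to_frame(index=False)
    logp = np.zeros(len(grid))
    for c in chars:
        p = grid[c].map(spec.characteristics[c]).to_numpy(float)
        with np.errstate(divide="ignore"):
            logp += np.log(p)
    for (ca, xa, cb, xb), lor in spec.pairwise_log_or.items():
        hit = (grid[ca] == xa) & (grid[cb] == xb)
        logp += lor * hit.to_numpy(float)
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    if spec.pairwise_log_or:
        keep = prob > 0
        margins = MarginSet(
            "spec", 1.0,
            {c: pd.Series(spec.characteristics[c]) for c in chars},
            atol_per_category=1.0,
        )
        raker = Raker(
            margins,
            config=RakingConfig(tolerance=1e-10, max_iterations=500,
                                trim_and_rerake_cycles=0),
        )
        prob_pos = raker.fit(grid[keep], initial_weights=prob[keep]).weights_
        prob = np.zeros(len(grid))
        prob[np.flatnonzero(keep)] = prob_pos
    return grid, prob


def generate_population(spec: PopulationSpec, seed: int) -> pd.DataFrame:
    """Realise a full target population, one row per person.

    Categorical fields follow the spec's joint distribution; each binary
    outcome is drawn from its logistic model; continuous ``age_at_entry`` is
    drawn within the realised age band, and ``entry`` (decimal year) is
    uniform over the recruitment period.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    grid, prob = _joint_cell_table(spec)
    counts = rng.multinomial(spec.population_size, prob)
    table = grid.loc[grid.index.repeat(counts)].reset_index(drop=True)

    # continuous age inside the realised band
    if spec.age_characteristic is not None:
        bands = list(spec.characteristics[spec.age_characteristic])
        edges = parse_age_bands(bands)
        code = pd.Categorical(table[spec.age_characteristic], categories=bands).codes
        lo = edges[code]
        hi = edges[code + 1]
        u = rng.random(len(table))
        age = np.where(
            np.isinf(hi),
            lo + rng.exponential(spec.open_band_mean_years, len(table)),
            lo + u * np.where(np.isinf(hi), 1.0, hi - lo),
        )
        table["age_at_entry"] = age
    t0, t1 = spec.recruitment_period
    table["entry"] = t0 + rng.random(len(table)) * (t1 - t0)

    for outcome, model in spec.outcome_models.items():
        lp = np.full(len(table), float(model["intercept"]))
        for (c, x), b in model.get("effects", {}).items():
            lp += b * (table[c] == x).to_numpy(float)
        y = rng.random(len(table)) < expit(lp)
        table[outcome] = np.where(y, "Yes", "No")
    return table


def draw_sample(population: pd.DataFrame, sel: SelectionSpec) -> pd.DataFrame:
    """Bernoulli sample of the population under the selection propensities.

    Each person is included independently with their own propensity.  The
    output carries the true propensity in ``true_propensity`` for
    diagnostics, and a fresh RangeIndex.
    """
    p = sel.propensities(population)
    rng = np.random.default_rng(sel.seed)
    take = rng.random(len(population)) < p
    out = population.loc[take].copy()
    out["true_propensity"] = p[take]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# follow-up simulation

def _rate_matrix(rates: RateTable, sexes: np.ndarray, bands: list[str],
                 cancer: str | None) -> np.ndarray:
    """(n_units, n_bands) base rates for each unit's sex."""
    out = np.zeros((len(sexes), len(bands)))
    for sex in np.unique(sexes):
        lut = rates.lookup(sex=sex, cancer=cancer)
        row = np.array([float(lut.get(b, 0.0)) for b in bands])
        out[sexes == sex] = row
    return out


def _frailty(table: pd.DataFrame, effects: dict[tuple[str, str], float]) -> np.ndarray:
    rr = np.ones(len(table))
    for (field_name, cat), ratio in effects.items():
        if field_name not in table.columns:
            raise SpecValidationError(
                f"frailty_effects references absent field {field_name!r}"
            )
        rr *= np.where(table[field_name].astype(str) == cat, ratio, 1.0)
    return rr


def simulate_followup(sample: pd.DataFrame, inc: IncidenceSpec, seed: int) -> pd.DataFrame:
    """Simulate diagnosis, death and censoring over the calendar window.

    Event times are drawn from piecewise-exponential hazards: for each person
    the hazard of each cancer (and of death) is constant within a 5-year age
    band and multiplied by the person's frailty rate ratios.  For each cancer
    the first diagnosis between entry and the window end is recorded in
    ``diag_<cancer>`` (decimal year, NaN if none); death in ``death``; units
    with no event are censored at the window end.  Rows whose entry falls
    after the window end are flagged invalid in ``valid_followup``.
    """
    for col in ["sex", "entry", "age_at_entry"]:
        if col not in sample.columns:
            raise SpecValidationError(f"sample lacks column {col!r}")
    rng = np.random.default_rng(seed)
    out = sample.copy()
    n = len(out)
    end = inc.window[1]
    entry = out["entry"].to_numpy(float)
    age0 = out["age_at_entry"].to_numpy(float)
    sexes = out["sex"].to_numpy()
    out["valid_followup"] = entry <= end

    bands = inc.death_rate_table.age_bands
    edges = parse_age_bands(bands)
    if np.any(age0 < edges[0]):
        raise SpecValidationError(
            f"ages below the first rate band ({edges[0]:.0f}) are unsupported"
        )

    cancers = inc.cancers
    base = {
        c: _rate_matrix(inc.rate_table, sexes, bands, c if "cancer" in inc.rate_table.table.columns else None)
        * _frailty(out, inc.frailty_effects.get(c, {}))[:, None]
        for c in cancers
    }
    death_rate = _rate_matrix(inc.death_rate_table, sexes, bands, None)

    diag = {c: np.full(n, np.nan) for c in cancers}
    death = np.full(n, np.nan)

    t = entry.copy()          # current calendar time per unit
    alive = out["valid_followup"].to_numpy().copy()
    while alive.any():
        idx = np.flatnonzero(alive)
        age = age0[idx] + (t[idx] - entry[idx])
        # the 1e-9 nudge keeps ages an epsilon below a band edge from creating
        # infinitesimal segments
        band = np.clip(
            np.searchsorted(edges, age + 1e-9, side="right") - 1, 0, len(bands) - 1
        )
        next_edge = edges[band + 1]
        seg = np.minimum(next_edge - age, end - t[idx])
        seg = np.maximum(seg, 0.0)

        # death time within the segment (infinite when the hazard is zero)
        lam_d = death_rate[idx, band]
        td = np.where(
            lam_d > 0, rng.exponential(1.0, len(idx)) / np.maximum(lam_d, 1e-300), np.inf
        )
        dies = td < seg
        death_time = t[idx] + np.where(dies, td, np.inf)

        for c in cancers:
            lam = base[c][idx, band]
            open_risk = ~np.isfinite(diag[c][idx])
            tc = np.where(
                lam > 0, rng.exponential(1.0, len(idx)) / np.maximum(lam, 1e-300), np.inf
            )
            hit = open_risk & (tc < seg) & (t[idx] + tc <= death_time)
            diag[c][idx[hit]] = t[idx][hit] + tc[hit]

        death[idx[dies]] = death_time[dies]
        t[idx] += seg
        alive[idx] = ~dies & (t[idx] < end - 1e-12)

    out["death"] = death
    for c in cancers:
        out[f"diag_{c}"] = diag[c]
    return out


def inject_missingness(
    table: pd.DataFrame, rates: dict[str, float], seed: int
) -> pd.DataFrame:
    """Set fields to the missing sentinel independently at the given rates."""
    rng = np.random.default_rng(seed)
    out = table.copy()
    for field_name, rate in rates.items():
        if not 0 <= rate <= 1:
            raise SpecValidationError(f"missingness rate for {field_name!r} not in [0,1]")
        hit = rng.random(len(out)) < rate
        col = out[field_name].astype(object)
        col[hit] = MISSING
        out[field_name] = col
    return out


# ---------------------------------------------------------------------------
# CSV round trip (ISO-8601 dates at the file boundary, decimal years in memory)

_DATE_COLUMNS = ("entry", "death")


def decimal_year_to_date(t: float) -> str:
    """Decimal year -> ISO-8601 date (day resolution)."""
    year = int(np.floor(t))
    start = pd.Timestamp(year=year, month=1, day=1)
    days_in_year = 366 if start.is_leap_year else 365
    return (start + pd.Timedelta(days=(t - year) * days_in_year)).strftime("%Y-%m-%d")


def date_to_decimal_year(s: str) -> float:
    ts = pd.Timestamp(s)
    start = pd.Timestamp(year=ts.year, month=1, day=1)
    days_in_year = 366 if start.is_leap_year else 365
    return ts.year + (ts - start).days / days_in_year


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV with ISO-8601 dates for time columns."""
    out = table.copy()
    date_cols = [c for c in out.columns if c in _DATE_COLUMNS or c.startswith("diag_")]
    for c in date_cols:
        vals = out[c].to_numpy(float)
        out[c] = [decimal_year_to_date(v) if np.isfinite(v) else "" for v in vals]
    out.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, converting ISO-8601 date columns to decimal years."""
    df = pd.read_csv(path)
    date_cols = [c for c in df.columns if c in _DATE_COLUMNS or c.startswith("diag_")]
    for c in date_cols:
        df[c] = [
            date_to_decimal_year(v) if isinstance(v, str) and v else np.nan
            for v in df[c]
        ]
    return df


# ---------------------------------------------------------------------------
# default study conditions

def default_population_spec(population_size: int = 200_000) -> PopulationSpec:
    """A NSW-like 45+ population.

    Marginals are the published Census 2006 NSW category shares for the seven
    weighting characteristics; pairwise log odds-ratios encode well-known
    associations (older age with widowhood and lower formal education,
    non-Australian birth with speaking another language at home, remote
    residence with Australian birth); and three binary outcomes (current
    smoking, fair/poor self-rated health, obesity) load on age, education and
    marital status, so they correlate with — but are not determined by — the
    weighting demographics.
    """
    from .datasets import census_margins

    m = census_margins("NSW")
    characteristics = {
        c: (m.margins[c] / m.population_total).to_dict() for c in m.characteristics
    }
    pairwise = {
        ("age_group", "85+", "marital_status", "Widowed"): 1.6,
        ("age_group", "80-84", "marital_status", "Widowed"): 1.2,
        ("age_group", "85+", "education", "No School Certificate"): 0.8,
        ("age_group", "45-49", "education", "University degree or higher"): 0.5,
        ("birth_region", "Asia", "language_other_than_english", "Yes"): 3.5,
        ("birth_region", "Europe", "language_other_than_english", "Yes"): 2.5,
        ("birth_region", "Other", "language_other_than_english", "Yes"): 2.0,
        ("birth_region", "Australia", "language_other_than_english", "No"): 1.5,
        ("residence", "Remote/Very Remote", "birth_region", "Australia"): 1.0,
        ("residence", "Major City", "birth_region", "Asia"): 1.0,
    }
    outcomes = {
        "current_smoker": {
            # population prevalence around 14% as in national benchmark surveys
            "intercept": -2.0,
            "effects": {
                ("education", "No School Certificate"): 0.55,
                ("education", "School Certificate"): 0.35,
                ("education", "University degree or higher"): -0.6,
                ("age_group", "45-49"): 0.45,
                ("age_group", "50-54"): 0.3,
                ("age_group", "75-79"): -0.5,
                ("age_group", "80-84"): -0.8,
                ("age_group", "85+"): -1.1,
                ("marital_status", "Divorced"): 0.4,
                ("marital_status", "Separated"): 0.4,
            },
        },
        "fair_poor_health": {
            # rises steeply with age and lower education; ~18% overall
            "intercept": -2.1,
            "effects": {
                ("age_group", "70-74"): 0.5,
                ("age_group", "75-79"): 0.7,
                ("age_group", "80-84"): 0.9,
                ("age_group", "85+"): 1.2,
                ("education", "No School Certificate"): 0.6,
                ("education", "University degree or higher"): -0.5,
            },
        },
        "obese": {
            "intercept": -1.4,
            "effects": {
                ("education", "No School Certificate"): 0.3,
                ("education", "University degree or higher"): -0.3,
                ("age_group", "85+"): -0.5,
                ("residence", "Outer Regional"): 0.2,
                ("residence", "Remote/Very Remote"): 0.2,
            },
        },
    }
    return PopulationSpec(
        characteristics=characteristics,
        pairwise_log_or=pairwise,
        outcome_models=outcomes,
        population_size=population_size,
    )


def default_selection_spec(seed: int = 0, base_rate: float = 0.18) -> SelectionSpec:
    """Volunteer-cohort selection: over-samples the 80+ and remote/rural,
    under-samples current smokers and people in fair/poor health."""
    return SelectionSpec(
        base_rate=base_rate,
        logit_effects={
            ("age_group", "80-84"): 0.9,
            ("age_group", "85+"): 0.9,
            ("residence", "Remote/Very Remote"): 0.8,
            ("residence", "Outer Regional"): 0.5,
            ("residence", "Inner Regional"): 0.3,
            ("education", "University degree or higher"): 0.5,
            ("education", "No School Certificate"): -0.3,
            ("current_smoker", "Yes"): -0.7,
            ("fair_poor_health", "Yes"): -0.5,
        },
        seed=seed,
    )


def demographic_selection_spec(seed: int = 0, base_rate: float = 0.18) -> SelectionSpec:
    """Selection driven only by the seven weighting demographics.

    Under this mechanism full raking to the true margins can, in expectation,
    fully correct selection bias in outcomes that depend on those
    demographics; useful as the controlled condition in recovery experiments.
    """
    return SelectionSpec(
        base_rate=base_rate,
        logit_effects={
            ("age_group", "80-84"): 0.9,
            ("age_group", "85+"): 0.9,
            ("age_group", "45-49"): -0.3,
            ("residence", "Remote/Very Remote"): 0.8,
            ("residence", "Outer Regional"): 0.5,
            ("residence", "Inner Regional"): 0.3,
            ("education", "University degree or higher"): 0.6,
            ("education", "No School Certificate"): -0.5,
            ("marital_status", "Married"): 0.3,
            ("language_other_than_english", "Yes"): -0.4,
        },
        seed=seed,
    )


def default_incidence_spec(window: tuple[float, float] = (2009.0, 2014.0)) -> IncidenceSpec:
    """Plausible synthetic sex-age-specific cancer and mortality rates.

    Rates are synthetic stand-ins shaped like registry incidence for a 45+
    population: lung and colorectal rise steeply with age in both sexes,
    breast (female only) peaks in late middle age, prostate (male only) rises
    to a plateau.  Units: events per person-year.  Smoking multiplies the
    lung-cancer hazard (rate ratio 8) and, mildly, mortality; fair/poor
    health doubles mortality.
    """
    bands = ["45-49", "50-54", "55-59", "60-64", "65-69", "70-74", "75-79", "80-84", "85+"]
    per1e5 = {
        # cancer: {sex: rates per 100,000 py by band}
        "lung": {
            "Male": [10, 25, 55, 110, 190, 290, 380, 430, 420],
            "Female": [8, 18, 38, 70, 115, 165, 205, 215, 190],
        },
        "colorectal": {
            "Male": [30, 55, 95, 155, 230, 320, 410, 490, 540],
            "Female": [25, 42, 68, 105, 150, 210, 280, 360, 420],
        },
        "breast": {"Female": [190, 230, 255, 270, 280, 290, 295, 300, 290]},
        "prostate": {"Male": [25, 120, 330, 560, 750, 800, 720, 610, 480]},
    }
    rows = [
        {"cancer": cancer, "sex": sex, "age_band": b, "rate": r / 1e5}
        for cancer, by_sex in per1e5.items()
        for sex, rs in by_sex.items()
        for b, r in zip(bands, rs)
    ]
    death_per1e5 = {
        "Male": [250, 380, 600, 950, 1500, 2500, 4300, 7600, 14500],
        "Female": [150, 230, 370, 590, 950, 1600, 2900, 5600, 12500],
    }
    drows = [
        {"sex": sex, "age_band": b, "rate": r / 1e5}
        for sex, rs in death_per1e5.items()
        for b, r in zip(bands, rs)
    ]
    return IncidenceSpec(
        rate_table=RateTable(pd.DataFrame(rows), name="synthetic registry rates"),
        death_rate_table=RateTable(pd.DataFrame(drows), name="synthetic mortality"),
        frailty_effects={
            "lung": {("current_smoker", "Yes"): 8.0},
            "colorectal": {("obese", "Yes"): 1.4},
        },
        window=window,
    )
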