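"""Published summary tables from the 45 and Up Study generalisability analysis.

The unit-record data of the 45 and Up Study, the NSW Cancer Registry and the
benchmark surveys are access-restricted; what is public are the printed
summary tables: baseline category counts for the analysed cohort
(N = 255,365), the 2006 Census category percentages for the NSW and
Australian populations aged 45+, and benchmark survey prevalences (NDSHS,
with 95% CIs).  Those printed numbers are inputs here — they drive worked
examples and arithmetic cross-checks of the estimation machinery.

Counts are exact as printed; census margins are printed to one decimal
percent and are proportionally rescaled to the printed population totals.
"""

from __future__ import annotations

import io

import pandas as pd

from .margins import BenchmarkTable, MarginSet

#: Cohort accounting as published: recruited, excluded for missing weighting
#: characteristics, and analysed.
COHORT_RECRUITED = 267_153
COHORT_MISSING_EXCLUDED = 11_788
COHORT_ANALYSED = 255_365

#: Census 2006 totals for the populations aged >= 45 years.
NSW_POPULATION_TOTAL = 2_529_664
AUS_POPULATION_TOTAL = 7_599_570

# characteristic, category, cohort count, census NSW %, census Australia %
_TABLE1 = """\
characteristic,category,count,census_nsw_pct,census_aus_pct
sex,Male,117969,47.8,47.9
sex,Female,137396,52.2,52.1
age_group,45-49,33711,18.8,19.0
age_group,50-54,41504,17.0,17.3
age_group,55-59,43865,15.9,16.2
age_group,60-64,38710,12.6,12.6
age_group,65-69,32235,10.1,10.0
age_group,70-74,23168,8.3,8.1
age_group,75-79,16949,7.4,7.2
age_group,80-84,17621,5.6,5.3
age_group,85+,7602,4.4,4.2
residence,Major City,135389,69.0,66.1
residence,Inner Regional,90786,22.8,21.7
residence,Outer Regional,26704,7.7,10.1
residence,Remote/Very Remote,2486,0.6,1.9
education,No School Certificate,30327,22.8,22.3
education,School Certificate,57213,23.2,24.4
education,Trade/Certificate/Diploma,82527,28.0,27.7
education,Higher School Certificate,25364,12.4,12.7
education,University degree or higher,59934,13.7,12.8
birth_region,Australia,193250,66.0,66.4
birth_region,NZ and Oceania,5760,2.5,2.7
birth_region,Asia,8901,8.1,6.0
birth_region,UK and Ireland,25270,8.0,10.4
birth_region,Europe,14891,10.4,10.9
birth_region,Other,7293,5.1,3.6
language_other_than_english,No,231220,80.2,83.5
language_other_than_english,Yes,24145,19.8,16.5
marital_status,Never married,15975,8.4,7.9
marital_status,Widowed,22040,12.5,12.0
marital_status,Divorced,19059,11.9,12.3
marital_status,Separated,7124,3.8,3.8
marital_status,Married,191167,63.5,64.0
"""

# Cohort outcome counts (analysed N = 255,365) for two health characteristics,
# and the matching NDSHS NSW benchmark prevalences with 95% CIs.
_OUTCOME_COUNTS = """\
characteristic,category,count
smoking_status,Current regular smoker,18265
smoking_status,Former regular smoker,91398
smoking_status,Never regular smoker,145609
smoking_status,Missing,93
overall_health,Excellent,37394
overall_health,Very Good,91525
overall_health,Good,83318
overall_health,Fair,29281
overall_health,Poor,5327
overall_health,Missing,8520
"""

_NDSHS_NSW = """\
characteristic,category,estimate,lower,upper
smoking_status,Current regular smoker,13.9,12.7,15.2
smoking_status,Former regular smoker,35.3,33.6,37.0
smoking_status,Never regular smoker,50.6,48.8,52.4
overall_health,Excellent,10.8,9.7,12.0
overall_health,Very Good,33.0,31.3,34.7
overall_health,Good,37.1,35.4,38.9
overall_health,Fair,14.8,13.6,16.1
overall_health,Poor,3.1,2.5,3.8
"""

#: The seven weighting characteristics, in published sweep order.
FULL_RAKING_CHARACTERISTICS = [
    "sex",
    "age_group",
    "residence",
    "education",
    "birth_region",
    "language_other_than_english",
    "marital_status",
]

#: The basic scheme: sex, 5-year age group and place of residence
#: (2 x 9 x 4 = 72 post-stratification cells).
BASIC_CHARACTERISTICS = ["sex", "age_group", "residence"]


def table1() -> pd.DataFrame:
    """The published baseline table: counts and census percentages."""
    return pd.read_csv(io.StringIO(_TABLE1))


def cohort_counts() -> pd.DataFrame:
    """Cohort category counts for the seven weighting characteristics."""
    return table1()[["characteristic", "category", "count"]]


def cohort_outcome_counts() -> pd.DataFrame:
    """Cohort counts for two published health characteristics."""
    return pd.read_csv(io.StringIO(_OUTCOME_COUNTS))


def census_margins(population: str = "NSW") -> MarginSet:
    """Census 2006 control totals for the NSW or Australian population 45+.

    Rebuilt from the printed one-decimal percentages and population totals,
    with each characteristic rescaled to the total exactly.
    """
    pop = population.upper()
    col, total = {
        "NSW": ("census_nsw_pct", NSW_POPULATION_TOTAL),
        "AUS": ("census_aus_pct", AUS_POPULATION_TOTAL),
        "AUSTRALIA": ("census_aus_pct", AUS_POPULATION_TOTAL),
    }[pop]
    t1 = table1()
    pct = {
        char: dict(zip(sub["category"], sub[col]))
        for char, sub in t1.groupby("characteristic", sort=False)
    }
    return MarginSet.from_percentages(population, float(total), pct)


def ndshs_benchmark_nsw() -> BenchmarkTable:
    """NDSHS NSW benchmark prevalences (with 95% CIs) for two characteristics."""
    return BenchmarkTable("NDSHS NSW", pd.read_csv(io.StringIO(_NDSHS_NSW)))


def expand_counts(counts: pd.DataFrame, characteristic: str) -> pd.DataFrame:
    """Unit-level one-column table reproducing the printed category counts.

    Category percentages and their CIs depend on the counts only, so a table
    with each category repeated ``count`` times reproduces the printed
    unweighted estimates exactly.
    """
    sub = counts[counts["characteristic"] == characteristic]
    col = sub["category"].repeat(sub["count"]).reset_index(drop=True)
    return pd.DataFrame({characteristic: col})
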