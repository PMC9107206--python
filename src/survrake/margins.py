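"""Target-population margin tables, joint cell tables, benchmark and rate tables.

Calibration weighting needs external control data: census category totals
(margins), joint cross-classification counts (for post-stratification),
benchmark survey prevalences (for effectiveness comparisons) and reference
sex-age-specific incidence rates (for indirect standardisation).  This module
holds those containers, validates their accounting identities, and reads and
writes them as plain CSV.

All counts are stored as floats: weighted survey benchmarks legitimately carry
non-integer "counts".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Reserved category label for missing values.  Units carrying it are excluded
#: from weighting but still reportable as their own row in prevalence tables.
MISSING = "Missing"


class MarginValidationError(ValueError):
    """A margin or cell table violates one of its accounting identities."""


@dataclass
class MarginSet:
    """Per-characteristic category totals for a named target population.

    ``margins`` maps each characteristic name to a Series of person counts
    indexed by category label, in the order characteristics should be swept
    during raking.  Every characteristic must account for the same population
    total (each person falls in exactly one category of each characteristic).

    Parameters
    ----------
    population_name : str
        Label for the target population (e.g. ``"NSW"``).
    population_total : float
        Total person count the margins must sum to.
    margins : dict[str, pandas.Series]
        Category totals per characteristic, insertion-ordered.
    atol_per_category : float
        Allowed absolute slack per category when checking that each
        characteristic sums to ``population_total`` (default 0.5, i.e. counts
        rounded to integers).
    """

    population_name: str
    population_total: float
    margins: dict[str, pd.Series] = field(default_factory=dict)
    atol_per_category: float = 0.5

    def __post_init__(self) -> None:
        self.margins = {k: pd.Series(v, dtype=float) for k, v in self.margins.items()}
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if not self.population_total > 0:
            raise MarginValidationError(
                f"population_total must be positive, got {self.population_total}"
            )
        bad_sum = []
        for char, totals in self.margins.items():
            if (totals < 0).any():
                neg = totals[totals < 0].index.tolist()
                raise MarginValidationError(
                    f"negative category totals for {char!r}: {neg}"
                )
            tol = self.atol_per_category * len(totals)
            if abs(totals.sum() - self.population_total) > tol:
                bad_sum.append(char)
        if bad_sum:
            raise MarginValidationError(
                "characteristic totals disagree with the population total "
                f"beyond tolerance: {','.join(bad_sum)}"
            )

    # -- accessors ----------------------------------------------------------

    @property
    def characteristics(self) -> list[str]:
        return list(self.margins)

    def categories(self, characteristic: str) -> list[str]:
        return list(self.margins[characteristic].index)

    def subset(self, characteristics: list[str]) -> "MarginSet":
        """A new MarginSet restricted to the given characteristics, in order."""
        missing = [c for c in characteristics if c not in self.margins]
        if missing:
            raise KeyError(f"characteristics not in margin set: {missing}")
        return MarginSet(
            self.population_name,
            self.population_total,
            {c: self.margins[c] for c in characteristics},
            atol_per_category=self.atol_per_category,
        )

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_percentages(
        cls,
        population_name: str,
        population_total: float,
        percentages: dict[str, dict[str, float]],
        normalise: bool = True,
    ) -> "MarginSet":
        """Build a MarginSet from printed category percentages.

        Census tables typically print one-decimal percentages, so the implied
        counts for a characteristic can miss the population total by up to
        0.05% of it per category.  With ``normalise=True`` each
        characteristic's counts are proportionally rescaled to hit
        ``population_total`` exactly, which raking requires.
        """
        margins: dict[str, pd.Series] = {}
        for char, cats in percentages.items():
            s = pd.Series(cats, dtype=float) / 100.0 * population_total
            if normalise:
                s = s * (population_total / s.sum())
            margins[char] = s
        return cls(population_name, population_total, margins)

    @classmethod
    def from_sample(
        cls, table: pd.DataFrame, characteristics: list[str], population_name: str = "sample"
    ) -> "MarginSet":
        """Ground-truth margins of a (synthetic) population table."""
        n = len(table)
        margins = {
            c: table[c].value_counts().sort_index().astype(float) for c in characteristics
        }
        return cls(population_name, float(n), margins)

    # -- I/O ----------------------------------------------------------------

    def to_csv(self, path) -> None:
        rows = [
            {"characteristic": char, "category": cat, "count": cnt}
            for char, totals in self.margins.items()
            for cat, cnt in totals.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def read_margins(
    path, population_name: str = "target", atol_per_category: float = 0.5
) -> MarginSet:
    """Read a ``characteristic,category,count`` CSV into a validated MarginSet.

    Characteristics keep the order of first appearance in the file (this order
    is the raking sweep order).  The population total is taken from the first
    characteristic; any characteristic whose total disagrees beyond tolerance
    triggers a hard error naming the offenders.
    """
    df = pd.read_csv(path)
    required = {"characteristic", "category", "count"}
    if not required.issubset(df.columns):
        raise MarginValidationError(
            f"margin file must have columns {sorted(required)}, got {list(df.columns)}"
        )
    margins: dict[str, pd.Series] = {}
    for char in df["characteristic"].drop_duplicates():
        sub = df[df["characteristic"] == char]
        if sub["category"].duplicated().any():
            dups = sub.loc[sub["category"].duplicated(), "category"].tolist()
            raise MarginValidationError(f"duplicate categories for {char!r}: {dups}")
        margins[char] = pd.Series(
            sub["count"].to_numpy(float), index=sub["category"].astype(str).tolist()
        )
    if not margins:
        raise MarginValidationError("margin file is empty")
    first = next(iter(margins))
    total = float(margins[first].sum())
    return MarginSet(population_name, total, margins, atol_per_category=atol_per_category)


@dataclass
class JointCellTable:
    """Population counts for every cell of a cross-classification.

    ``cells`` has one column per characteristic plus a ``count`` column, one
    row per cell of the full Cartesian product of categories.
    """

    characteristics: list[str]
    cells: pd.DataFrame
    population_total: float

    def __post_init__(self) -> None:
        missing = [c for c in self.characteristics + ["count"] if c not in self.cells.columns]
        if missing:
            raise MarginValidationError(f"cell table lacks columns: {missing}")
        if (self.cells["count"] < 0).any():
            raise MarginValidationError("negative cell counts")
        n_cells = int(np.prod([self.cells[c].nunique() for c in self.characteristics]))
        if len(self.cells) != n_cells:
            raise MarginValidationError(
                f"cell table has {len(self.cells)} rows but the Cartesian product "
                f"of categories has {n_cells} cells"
            )
        tol = 0.5 * len(self.cells)
        if abs(self.cells["count"].sum() - self.population_total) > tol:
            raise MarginValidationError(
                f"cell counts sum to {self.cells['count'].sum():.1f}, "
                f"not the population total {self.population_total:.1f}"
            )

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @classmethod
    def from_sample(
        cls, table: pd.DataFrame, characteristics: list[str]
    ) -> "JointCellTable":
        """Joint cell counts of a (synthetic) population table.

        The Cartesian product is completed with zero-count cells so the table
        is structurally full even when some combinations are unobserved.
        """
        counts = (
            table.groupby(characteristics, observed=False)
            .size()
            .rename("count")
            .reset_index()
        )
        full = _cartesian(
            {c: sorted(table[c].unique().tolist()) for c in characteristics}
        )
        cells = full.merge(counts, how="left", on=characteristics).fillna({"count": 0})
        cells["count"] = cells["count"].astype(float)
        return cls(list(characteristics), cells, float(len(table)))

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)


def read_cell_table(path, characteristics: list[str] | None = None) -> JointCellTable:
    df = pd.read_csv(path)
    chars = characteristics or [c for c in df.columns if c != "count"]
    df[chars] = df[chars].astype(str)
    return JointCellTable(chars, df, float(df["count"].sum()))


def _cartesian(categories: dict[str, list]) -> pd.DataFrame:
    idx = pd.MultiIndex.from_product(list(categories.values()), names=list(categories))
    return idx.to_frame(index=False)


def cell_table_from_margins_product(
    margins: MarginSet,
    characteristics: list[str],
    joint_counts: pd.DataFrame | None = None,
) -> JointCellTable:
    """Build the post-stratification cell structure for selected characteristics.

    The cells are the full Cartesian product of the characteristics' category
    lists (e.g. sex x 9 age bands x 4 remoteness levels = 72 cells).  Margins
    alone cannot determine joint cell counts, so ``joint_counts`` — a frame
    with one row per cell and a ``count`` column — must be supplied; no
    independence assumption is ever applied silently.
    """
    if joint_counts is None:
        raise MarginValidationError(
            "joint cell counts are required: marginal totals alone do not "
            "determine a joint distribution and no independence assumption is made"
        )
    full = _cartesian({c: margins.categories(c) for c in characteristics})
    merged = full.merge(joint_counts, how="left", on=characteristics)
    if merged["count"].isna().any():
        absent = merged[merged["count"].isna()][characteristics].to_dict("records")
        raise MarginValidationError(
            f"joint_counts missing {len(absent)} cells, e.g. {absent[:3]}"
        )
    return JointCellTable(
        list(characteristics), merged, float(merged["count"].sum())
    )


@dataclass
class BenchmarkTable:
    """External benchmark prevalences (percent) with optional 95% CIs.

    ``table`` columns: characteristic, category, estimate, and optionally
    lower/upper (all in percent).
    """

    source: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"characteristic", "category", "estimate"}
        if not req.issubset(self.table.columns):
            raise MarginValidationError(
                f"benchmark table needs columns {sorted(req)}"
            )
        est = self.table["estimate"]
        if ((est < 0) | (est > 100)).any():
            raise MarginValidationError("benchmark estimates must lie in [0, 100]")
        if self.has_ci:
            bad = (self.table["lower"] > est) | (est > self.table["upper"])
            if bad.any():
                raise MarginValidationError(
                    "benchmark CI bounds must bracket the point estimate"
                )

    @property
    def has_ci(self) -> bool:
        cols = self.table.columns
        return (
            "lower" in cols
            and "upper" in cols
            and self.table[["lower", "upper"]].notna().all().all()
        )

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def read_benchmarks(path, source: str = "benchmark") -> BenchmarkTable:
    return BenchmarkTable(source, pd.read_csv(path))


@dataclass
class RateTable:
    """Reference incidence (or mortality) rates per person-year.

    ``table`` columns: sex, age_band, rate and optionally cancer.  Age bands
    are labels like ``"45-49"`` with an open top band ``"85+"``; bands must be
    contiguous.
    """

    table: pd.DataFrame
    name: str = "rates"

    def __post_init__(self) -> None:
        req = {"sex", "age_band", "rate"}
        if not req.issubset(self.table.columns):
            raise MarginValidationError(f"rate table needs columns {sorted(req)}")
        if (self.table["rate"] < 0).any():
            raise MarginValidationError("rates must be non-negative")
        # contiguity of the band grid shared by all sexes/cancers
        parse_age_bands(sorted(self.table["age_band"].unique(), key=_band_lower))

    @property
    def age_bands(self) -> list[str]:
        return sorted(self.table["age_band"].unique(), key=_band_lower)

    def lookup(self, sex=None, cancer=None) -> pd.Series:
        """Rates indexed by age band for one sex (and cancer, if present)."""
        t = self.table
        if sex is not None:
            t = t[t["sex"] == sex]
        if cancer is not None and "cancer" in t.columns:
            t = t[t["cancer"] == cancer]
        return t.set_index("age_band")["rate"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def read_rates(path, name: str = "rates") -> RateTable:
    return RateTable(pd.read_csv(path), name=name)


def _band_lower(label: str) -> float:
    return float(str(label).rstrip("+").split("-")[0])


def parse_age_bands(labels: list[str]) -> np.ndarray:
    """Edges of contiguous 5-year-style age bands, last band open.

    ``["45-49", "50-54", ..., "85+"]`` -> ``[45, 50, ..., 85, inf]``.
    Raises if the bands leave gaps or overlap.
    """
    lowers, uppers = [], []
    for lab in labels:
        lab = str(lab)
        if lab.endswith("+"):
            lowers.append(float(lab[:-1]))
            uppers.append(np.inf)
        else:
            lo, hi = lab.split("-")
            lowers.append(float(lo))
            uppers.append(float(hi) + 1.0)  # "45-49" covers ages [45, 50)
    order = np.argsort(lowers)
    lowers = np.asarray(lowers)[order]
    uppers = np.asarray(uppers)[order]
    if not np.all(lowers[1:] == uppers[:-1]):
        raise MarginValidationError(f"age bands are not contiguous: {labels}")
    return np.append(lowers, uppers[-1])


def band_label(edges: np.ndarray, idx: int) -> str:
    lo = edges[idx]
    hi = edges[idx + 1]
    if np.isinf(hi):
        return f"{lo:.0f}+"
    return f"{lo:.0f}-{hi - 1:.0f}"


def harmonise_categories(
    table: pd.DataFrame, mapping: dict[str, dict[str, str]]
) -> pd.DataFrame:
    """Recode categorical fields onto a harmonised category scheme.

    ``mapping`` maps field name -> {source category -> target category}.
    Values observed in a mapped field but absent from its map are recoded to
    the :data:`MISSING` sentinel and the recode counts are logged.  Row count
    is never changed.
    """
    out = table.copy()
    for field_name, fmap in mapping.items():
        if field_name not in out.columns:
            raise KeyError(f"field {field_name!r} not in table")
        if len(set(fmap)) != len(fmap):  # dict literals cannot trigger this...
            raise MarginValidationError(f"duplicate source keys for {field_name!r}")
        col = out[field_name].astype(str)
        observed = set(col.unique())
        unmapped = observed - set(fmap)
        recoded = col.map(fmap)
        n_missing = int(recoded.isna().sum())
        if unmapped:
            logger.info(
                "harmonise %s: %d values in unmapped categories %s -> %r",
                field_name, n_missing, sorted(unmapped), MISSING,
            )
        out[field_name] = recoded.fillna(MISSING)
        for src, tgt in fmap.items():
            n = int((col == src).sum())
            if n and src != tgt:
                logger.debug("harmonise %s: %r -> %r (%d rows)", field_name, src, tgt, n)
    return out


def read_category_map(path) -> dict[str, dict[str, str]]:
    """Read a ``field,source,target`` CSV into a harmonisation mapping.

    Duplicate (field, source) pairs are an error: a source category must have
    a single target.
    """
    df = pd.read_csv(path, dtype=str)
    req = {"field", "source", "target"}
    if not req.issubset(df.columns):
        raise MarginValidationError(f"category map needs columns {sorted(req)}")
    if df.duplicated(subset=["field", "source"]).any():
        dups = df[df.duplicated(subset=["field", "source"], keep=False)]
        raise MarginValidationError(
            f"duplicate source keys in category map: {dups.to_dict('records')}"
        )
    mapping: dict[str, dict[str, str]] = {}
    for row in df.itertuples():
        mapping.setdefault(row.field, {})[row.source] = row.target
    return mapping
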