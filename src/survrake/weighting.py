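"""Calibration weights: post-stratification and raking (IPF) with trimming.

Both methods assign each sampled unit a weight interpretable as the number of
target-population persons it represents.  Post-stratification weights one
cross-classification cell at a time (``w_i = N_c / n_c``); raking (iterative
proportional fitting, IPF) instead matches the weighted *marginal* totals of
several characteristics simultaneously, which allows many more characteristics
before cells run empty.

Extreme weights are trimmed at ``median + multiplier * IQR`` (default
multiplier 6) and the sample is re-raked after trimming, cycling until stable
or a cycle cap is reached.

The estimators follow the scikit-learn protocol: configure in ``__init__``,
learn per-unit weights in ``fit`` (exposed as ``weights_``), and compose with
``get_params``/``set_params``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .margins import MISSING, JointCellTable, MarginSet

logger = logging.getLogger(__name__)


class RakingError(ValueError):
    """Raking or post-stratification cannot proceed or did not converge."""


@dataclass
class RakingConfig:
    """Tuning knobs for iterative proportional fitting.

    tolerance
        Convergence threshold on the maximum relative margin error
        ``max_kj |weighted total - T_kj| / T_kj``.
    max_iterations
        Cap on full sweeps through the characteristics.
    trim_multiplier
        The trim bound is ``median(w) + trim_multiplier * IQR(w)``.
    trim_and_rerake_cycles
        How many trim -> re-rake cycles to run after initial convergence.
        0 disables trimming.
    """

    tolerance: float = 1e-6
    max_iterations: int = 200
    trim_multiplier: float = 6.0
    trim_and_rerake_cycles: int = 10

    def __post_init__(self) -> None:
        if not self.tolerance > 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not self.trim_multiplier > 0:
            raise ValueError("trim_multiplier must be positive")


@dataclass
class WeightVector:
    """Per-unit calibration weights with provenance.

    ``weights`` aligns positionally with the sample the weights were fitted
    on.  ``method`` is one of ``"post-stratification"``, ``"raking"`` or
    ``"uniform"``.
    """

    weights: np.ndarray
    method: str
    characteristics: list[str] = field(default_factory=list)
    population_total: float = np.nan
    iterations: int = 0
    margin_error: float = 0.0
    trim_count: int = 0
    trim_bound: float | None = None
    converged: bool = True
    within_trim_bound: bool = True

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights <= 0).any():
            raise RakingError("all weights must be positive")

    def __len__(self) -> int:
        return len(self.weights)

    def to_frame(self, ids=None) -> pd.DataFrame:
        ids = np.arange(len(self.weights)) if ids is None else ids
        return pd.DataFrame({"unit": ids, "weight": self.weights, "method": self.method})


def uniform_weights(n: int, population_total: float | None = None) -> WeightVector:
    """Equal weights; with a population total they sum to it, else to n."""
    total = float(n) if population_total is None else float(population_total)
    return WeightVector(np.full(n, total / n), "uniform", population_total=total)


# ---------------------------------------------------------------------------
# trimming

def trim_bounds(weights: np.ndarray, multiplier: float = 6.0) -> tuple[float, float]:
    """Two-sided trim bounds ``median ± multiplier * IQR``.

    Quartiles use linear interpolation between order statistics (numpy's
    default, the "type 7" convention); the bound value depends on this choice
    so it is fixed here.
    """
    med = float(np.median(weights))
    q1, q3 = np.quantile(weights, [0.25, 0.75])
    iqr = float(q3 - q1)
    return med - multiplier * iqr, med + multiplier * iqr


def trim_weights(weights: WeightVector, multiplier: float = 6.0) -> WeightVector:
    """Cap weights beyond ``median ± multiplier * IQR``.

    The upper rule caps extreme large weights; the symmetric lower rule raises
    weights below ``median - multiplier*IQR`` and is inert whenever that bound
    is non-positive (weights are positive).
    """
    w = weights.weights.copy()
    lo, hi = trim_bounds(w, multiplier)
    n_trim = int((w > hi).sum() + (w < lo).sum())
    w = np.clip(w, max(lo, np.finfo(float).tiny), hi)
    return WeightVector(
        w,
        weights.method,
        characteristics=weights.characteristics,
        population_total=weights.population_total,
        iterations=weights.iterations,
        margin_error=weights.margin_error,
        trim_count=weights.trim_count + n_trim,
        trim_bound=hi,
        converged=weights.converged,
    )


# ---------------------------------------------------------------------------
# missing-value exclusion

def exclude_missing(
    sample: pd.DataFrame, characteristics: list[str]
) -> tuple[pd.DataFrame, int]:
    """Drop rows with a missing weighting characteristic; report the count.

    A value is missing when it is the reserved :data:`~survrake.margins.MISSING`
    sentinel or a genuine NA.
    """
    bad = pd.Series(False, index=sample.index)
    for c in characteristics:
        if c not in sample.columns:
            raise KeyError(f"characteristic {c!r} not in sample")
        col = sample[c]
        bad |= col.isna() | (col.astype(str) == MISSING)
    n_excluded = int(bad.sum())
    if n_excluded:
        logger.info(
            "excluded %d of %d units with missing values in %s",
            n_excluded, len(sample), characteristics,
        )
    return sample.loc[~bad].reset_index(drop=True), n_excluded


# ---------------------------------------------------------------------------
# estimators

class PostStratifier(BaseEstimator):
    """Post-stratification weights from a joint population cell table.

    Each unit in cell ``c`` receives ``w_i = N_c / n_c`` where ``N_c`` is the
    population count of the cell and ``n_c`` the number of sampled units in
    it, so the weighted joint distribution over the cell characteristics
    matches the population exactly.

    Attributes (after ``fit``)
    --------------------------
    weights_ : ndarray of shape (n_units,)
    characteristics_ : list of str
    n_cells_ : int
    """

    def __init__(self, cells: JointCellTable | None = None):
        self.cells = cells

    def fit(self, X: pd.DataFrame, y=None) -> "PostStratifier":
        if self.cells is None:
            raise RakingError("PostStratifier requires a JointCellTable")
        cells = self.cells
        chars = cells.characteristics
        _check_no_missing(X, chars)
        # align on string labels to be robust to dtype differences
        cell_df = cells.cells[chars + ["count"]].copy()
        cell_df[chars] = cell_df[chars].astype(str)
        Xk = X[chars].astype(str)
        n_c = Xk.groupby(chars, observed=False).size().rename("n_c").reset_index()
        occupancy = cell_df.merge(n_c, on=chars, how="outer")
        unknown = occupancy[occupancy["count"].isna()]
        if len(unknown):
            raise RakingError(
                "sampled units fall in cells absent from the table: "
                f"{unknown[chars].to_dict('records')[:5]}"
            )
        empty_pos = occupancy[(occupancy["count"] > 0) & occupancy["n_c"].isna()]
        if len(empty_pos):
            raise RakingError(
                f"{len(empty_pos)} population cells have no sampled units, "
                f"e.g. {empty_pos[chars].to_dict('records')[:5]}; "
                "post-stratification weights are undefined"
            )
        occupancy["w"] = occupancy["count"] / occupancy["n_c"]
        self.weights_ = Xk.merge(occupancy, on=chars, how="left")["w"].to_numpy(float)
        self.characteristics_ = list(chars)
        self.n_cells_ = cells.n_cells
        self.population_total_ = cells.population_total
        return self

    def fit_transform(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).weights_


class Raker(BaseEstimator):
    """Raking (iterative proportional fitting) to marginal control totals.

    Starting from uniform weights ``population_total / n``, characteristics
    are swept in the order they appear in the margin set; within a sweep the
    weights of category ``j`` of characteristic ``k`` are multiplied by
    ``T_kj / (current weighted total of category j)``.  Convergence is reached
    when the maximum relative margin error falls below ``tolerance``.  After
    convergence, weights beyond ``median + trim_multiplier * IQR`` are capped
    and the sample is re-raked, cycling up to ``trim_and_rerake_cycles`` times;
    if weights still exceed a freshly computed bound after the final cycle the
    estimator records this and warns rather than failing.

    Parameters
    ----------
    margins : MarginSet
        Control totals; the sweep order is the margin set's order.
    characteristics : list of str, optional
        Subset of the margin set to rake on (default: all of it).
    config : RakingConfig, optional

    Attributes (after ``fit``)
    --------------------------
    weights_ : ndarray of shape (n_units,)
    n_iter_ : int
        Total sweeps run, across trim cycles.
    margin_error_ : float
        Maximum relative margin error at exit.
    trim_count_ : int
        Number of weights capped, summed over cycles.
    trim_bound_ : float or None
        The last upper trim bound applied.
    converged_ : bool
    within_trim_bound_ : bool
        False when the cycle cap was reached with weights above the bound.
    """

    def __init__(
        self,
        margins: MarginSet | None = None,
        characteristics: list[str] | None = None,
        config: RakingConfig | None = None,
    ):
        self.margins = margins
        self.characteristics = characteristics
        self.config = config

    # -- internals ----------------------------------------------------------

    def _prepare(self, X: pd.DataFrame):
        if self.margins is None:
            raise RakingError("Raker requires a MarginSet")
        chars = self.characteristics or self.margins.characteristics
        margins = self.margins.subset(chars)
        _check_no_missing(X, chars)
        codes, targets = [], []
        for c in chars:
            t = margins.margins[c]
            cats = list(t.index)
            code = pd.Categorical(X[c].astype(str), categories=[str(x) for x in cats]).codes
            if (code < 0).any():
                bad = sorted(set(X.loc[code < 0, c].astype(str)))
                raise RakingError(
                    f"sample categories of {c!r} absent from the margins: {bad}"
                )
            present = np.bincount(code, minlength=len(cats)) > 0
            empty = [cats[i] for i in range(len(cats)) if t.iloc[i] > 0 and not present[i]]
            if empty:
                raise RakingError(
                    f"target categories of {c!r} with no sampled units: {empty}"
                )
            codes.append(code)
            targets.append(t.to_numpy(float))
        return chars, margins, codes, targets

    @staticmethod
    def _max_rel_error(w, codes, targets) -> float:
        err = 0.0
        for code, t in zip(codes, targets):
            tot = np.bincount(code, weights=w, minlength=len(t))
            pos = t > 0
            err = max(err, float(np.max(np.abs(tot[pos] - t[pos]) / t[pos])))
        return err

    def _ipf(self, w, codes, targets, cfg, sweeps_done):
        """Sweep until converged; returns (weights, sweeps, error)."""
        for it in range(cfg.max_iterations - sweeps_done):
            for code, t in zip(codes, targets):
                tot = np.bincount(code, weights=w, minlength=len(t))
                factor = np.ones_like(t)
                np.divide(t, tot, out=factor, where=tot > 0)
                w = w * factor[code]
            err = self._max_rel_error(w, codes, targets)
            if err < cfg.tolerance:
                return w, sweeps_done + it + 1, err
        raise RakingError(
            f"raking did not converge in {cfg.max_iterations} sweeps; "
            f"worst relative margin error {self._max_rel_error(w, codes, targets):.3e}"
        )

    # -- API ----------------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None, initial_weights=None) -> "Raker":
        """Fit raked weights.

        ``initial_weights`` overrides the uniform start (used e.g. when the
        rows are cells of a joint table whose perturbed counts are to be
        calibrated to marginal totals rather than survey units).
        """
        cfg = self.config or RakingConfig()
        chars, margins, codes, targets = self._prepare(X)
        n = len(X)
        if n == 0:
            raise RakingError("cannot rake an empty sample")
        total = margins.population_total
        if initial_weights is None:
            w = np.full(n, total / n)
        else:
            w = np.asarray(initial_weights, dtype=float).copy()
            if len(w) != n or (w <= 0).any():
                raise RakingError("initial_weights must be positive and align with X")

        trim_count = 0
        bound: float | None = None
        w, sweeps, err = self._ipf(w, codes, targets, cfg, 0)
        for _cycle in range(cfg.trim_and_rerake_cycles):
            lo, hi = trim_bounds(w, cfg.trim_multiplier)
            over = (w > hi) | (w < max(lo, 0.0))
            if not over.any():
                break
            trim_count += int(over.sum())
            bound = hi
            w = np.clip(w, max(lo, np.finfo(float).tiny), hi)
            w, sweeps, err = self._ipf(w, codes, targets, cfg, sweeps)
        if cfg.trim_and_rerake_cycles > 0:
            lo, hi = trim_bounds(w, cfg.trim_multiplier)
            within = bool(not ((w > hi) | (w < max(lo, 0.0))).any())
        else:
            within = True
        if not within:
            warnings.warn(
                "weights still exceed the trim bound after "
                f"{cfg.trim_and_rerake_cycles} trim/re-rake cycles",
                RuntimeWarning,
                stacklevel=2,
            )

        self.weights_ = w
        self.characteristics_ = chars
        self.n_iter_ = sweeps
        self.margin_error_ = err
        self.trim_count_ = trim_count
        self.trim_bound_ = bound
        self.converged_ = True
        self.within_trim_bound_ = within
        self.population_total_ = total
        return self

    def fit_transform(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).weights_


def _check_no_missing(X: pd.DataFrame, characteristics) -> None:
    for c in characteristics:
        if c not in X.columns:
            raise KeyError(f"characteristic {c!r} not in sample")
        col = X[c]
        if col.isna().any() or (col.astype(str) == MISSING).any():
            raise RakingError(
                f"sample has missing values in weighting characteristic {c!r}; "
                "run exclude_missing first"
            )


# ---------------------------------------------------------------------------
# functional wrappers

def poststratify(sample: pd.DataFrame, cells: JointCellTable) -> WeightVector:
    """Post-stratification weights ``N_c / n_c`` as a WeightVector."""
    est = PostStratifier(cells).fit(sample)
    return WeightVector(
        est.weights_,
        "post-stratification",
        characteristics=est.characteristics_,
        population_total=est.population_total_,
    )


def rake(
    sample: pd.DataFrame,
    margins: MarginSet,
    config: RakingConfig | None = None,
    characteristics: list[str] | None = None,
) -> WeightVector:
    """Raked weights matching the sample's margins to the control totals."""
    est = Raker(margins, characteristics=characteristics, config=config).fit(sample)
    return WeightVector(
        est.weights_,
        "raking",
        characteristics=est.characteristics_,
        population_total=est.population_total_,
        iterations=est.n_iter_,
        margin_error=est.margin_error_,
        trim_count=est.trim_count_,
        trim_bound=est.trim_bound_,
        converged=est.converged_,
        within_trim_bound=est.within_trim_bound_,
    )


def weight_diagnostics(weights: WeightVector | np.ndarray) -> dict[str, float]:
    """Distributional summary of a weight vector.

    The design effect ``1 + CV^2`` (CV the coefficient of variation of the
    weights) approximates the variance inflation of estimates caused by
    unequal weighting.
    """
    w = weights.weights if isinstance(weights, WeightVector) else np.asarray(weights, float)
    if (w <= 0).any():
        raise RakingError("weights must be positive")
    q1, q3 = np.quantile(w, [0.25, 0.75])
    cv = float(np.std(w) / np.mean(w))
    return {
        "n": int(len(w)),
        "min": float(np.min(w)),
        "max": float(np.max(w)),
        "median": float(np.median(w)),
        "iqr": float(q3 - q1),
        "cv": cv,
        "design_effect": 1.0 + cv**2,
        "sum": float(np.sum(w)),
    }
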