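"""End-to-end orchestration: cohort -> weights -> prevalence -> SIR tables.

A single :class:`RunConfig` drives the full study analogue: synthesise (or
load) a cohort, exclude units missing weighting characteristics, build the
three weighting schemes (post-stratification, basic raking, full raking),
estimate prevalence for weighting characteristics and outcomes under every
scheme, summarise effectiveness against a benchmark, and compute weighted and
unweighted standardised incidence ratios per cancer.  Outputs are CSV files
plus a plain-text run log carrying the seed and a config hash, so a run is
reproducible from its artefacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import datasets
from .estimation import (
    effectiveness_summary,
    margin_of_error_summary,
    prevalence_to_benchmark,
    weighted_prevalence,
)
from .incidence import rates_from_cohort, sir_pipeline
from .margins import JointCellTable, MarginSet, read_margins, read_rates
from .synthetic import (
    default_incidence_spec,
    default_population_spec,
    default_selection_spec,
    draw_sample,
    generate_population,
    inject_missingness,
    read_cohort,
    simulate_followup,
)
from .weighting import (
    RakingConfig,
    WeightVector,
    exclude_missing,
    poststratify,
    rake,
    uniform_weights,
    weight_diagnostics,
)

logger = logging.getLogger(__name__)


@dataclass
class SchemeConfig:
    name: str
    method: str  # "poststratification" | "raking"
    characteristics: list[str]


@dataclass
class RunConfig:
    """Configuration for a full run.

    With ``sample_path`` unset, a synthetic population of
    ``population_size`` persons is generated and sampled under the default
    volunteer-cohort selection model; otherwise the cohort CSV is loaded.
    ``margins_path`` overrides the synthetic ground-truth margins.
    """

    seed: int = 0
    population_size: int = 100_000
    sample_path: str | None = None
    margins_path: str | None = None
    rates_path: str | None = None
    outcomes: list[str] = field(
        default_factory=lambda: ["current_smoker", "fair_poor_health", "obese"]
    )
    schemes: list[SchemeConfig] = field(
        default_factory=lambda: [
            SchemeConfig("poststrat", "poststratification", list(datasets.BASIC_CHARACTERISTICS)),
            SchemeConfig("basic_raking", "raking", list(datasets.BASIC_CHARACTERISTICS)),
            SchemeConfig("full_raking", "raking", list(datasets.FULL_RAKING_CHARACTERISTICS)),
        ]
    )
    raking: RakingConfig = field(default_factory=RakingConfig)
    window: tuple[float, float] = (2009.0, 2014.0)
    cancers: list[str] = field(default_factory=lambda: ["lung", "colorectal", "breast", "prostate"])
    missingness: dict[str, float] = field(default_factory=dict)
    output_dir: str = "survrake_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "schemes" in kwargs:
            kwargs["schemes"] = [SchemeConfig(**s) for s in kwargs["schemes"]]
        if "raking" in kwargs:
            kwargs["raking"] = RakingConfig(**kwargs["raking"])
        if "window" in kwargs:
            kwargs["window"] = tuple(kwargs["window"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window"] = list(self.window)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def validate(config: RunConfig, margins: MarginSet | None = None) -> list[str]:
    """List configuration problems without running anything."""
    problems: list[str] = []
    if config.sample_path and not Path(config.sample_path).exists():
        problems.append(f"sample_path does not exist: {config.sample_path}")
    if config.margins_path:
        if not Path(config.margins_path).exists():
            problems.append(f"margins_path does not exist: {config.margins_path}")
        else:
            try:
                margins = read_margins(config.margins_path)
            except Exception as exc:  # surfaced as a problem, not an abort
                problems.append(f"margins file invalid: {exc}")
    known = (
        margins.characteristics
        if margins is not None
        else datasets.FULL_RAKING_CHARACTERISTICS
    )
    for scheme in config.schemes:
        if scheme.method not in {"poststratification", "raking"}:
            problems.append(f"scheme {scheme.name!r}: unknown method {scheme.method!r}")
        for c in scheme.characteristics:
            if c not in known:
                problems.append(
                    f"scheme {scheme.name!r}: characteristic {c!r} not in the margin set"
                )
    if not config.population_size > 0 and not config.sample_path:
        problems.append("population_size must be positive for a synthetic run")
    return problems


@dataclass
class RunResult:
    """In-memory bundle of one run's outputs."""

    config: RunConfig
    sample: pd.DataFrame
    weights: dict[str, WeightVector]
    prevalence: dict[str, list]  # scheme -> list[PrevalenceTable]
    effectiveness: object
    moe: pd.Series
    sirs: pd.DataFrame
    log_lines: list[str]


def run(config: RunConfig, write: bool = True) -> RunResult:
    """Execute the full pipeline; deterministic given ``config.seed``."""
    problems = validate(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    log: list[str] = [f"config_hash={config.config_hash()}", f"seed={config.seed}"]

    def stage(msg: str) -> None:
        logger.info(msg)
        log.append(msg)

    seed = int(config.seed)
    inc = default_incidence_spec(window=config.window)

    if config.sample_path:
        stage(f"load sample from {config.sample_path}")
        sample = read_cohort(config.sample_path)
        benchmark = None
        margins = read_margins(config.margins_path) if config.margins_path else None
        cells_source = None
        reference_rates = read_rates(config.rates_path) if config.rates_path else None
        if margins is None:
            raise ValueError("margins_path is required when loading a sample")
    else:
        stage(f"synthesise population of {config.population_size}")
        pop_spec = default_population_spec(population_size=config.population_size)
        population = generate_population(pop_spec, seed=seed)
        margins = MarginSet.from_sample(
            population, datasets.FULL_RAKING_CHARACTERISTICS, population_name="truth"
        )
        cells_source = population
        # whole-of-population follow-up: the registry analogue that supplies
        # the reference incidence rates for indirect standardisation
        population = simulate_followup(population, inc, seed=seed + 2)
        reference_rates = rates_from_cohort(
            population, config.window, config.cancers, name="population registry"
        )
        sample = draw_sample(population, default_selection_spec(seed=seed + 1))
        stage(f"sampled {len(sample)} of {len(population)}")
        if config.missingness:
            sample = inject_missingness(sample, config.missingness, seed=seed + 3)
        # population truth as the benchmark (point estimates only by design:
        # the truth is a census of the synthetic population)
        bench_tables = [
            weighted_prevalence(population, None, out, scheme="truth")
            for out in config.outcomes
        ]
        benchmark = prevalence_to_benchmark(bench_tables, "population truth")
        benchmark.table = benchmark.table.drop(columns=["lower", "upper"])

    raking_chars = sorted(
        {c for s in config.schemes for c in s.characteristics},
        key=lambda c: margins.characteristics.index(c),
    )
    sample, n_excluded = exclude_missing(sample, raking_chars)
    stage(f"excluded {n_excluded} units with missing weighting characteristics; "
          f"analysed n={len(sample)}")

    weights: dict[str, WeightVector] = {}
    for scheme in config.schemes:
        if scheme.method == "poststratification":
            if cells_source is None:
                raise ValueError(
                    "post-stratification requires a joint cell source (synthetic run)"
                )
            cells = JointCellTable.from_sample(cells_source, scheme.characteristics)
            wv = poststratify(sample, cells)
        else:
            wv = rake(
                sample,
                margins.subset(scheme.characteristics),
                config=config.raking,
            )
        weights[scheme.name] = wv
        diag = weight_diagnostics(wv)
        stage(
            f"scheme {scheme.name}: method={scheme.method} iterations={wv.iterations} "
            f"margin_error={wv.margin_error:.2e} trims={wv.trim_count} "
            f"deff={diag['design_effect']:.3f}"
        )

    report_fields = raking_chars + [o for o in config.outcomes if o in sample.columns]
    prevalence: dict[str, list] = {
        "unweighted": [weighted_prevalence(sample, None, f) for f in report_fields]
    }
    for name, wv in weights.items():
        prevalence[name] = [
            weighted_prevalence(sample, wv, f, scheme=name) for f in report_fields
        ]
    stage(f"prevalence tables for {len(report_fields)} characteristics, "
          f"{len(prevalence)} schemes")

    effectiveness = None
    if benchmark is not None:
        outcome_idx = [report_fields.index(o) for o in config.outcomes if o in report_fields]
        effectiveness = effectiveness_summary(
            benchmark,
            [prevalence["unweighted"][i] for i in outcome_idx],
            {
                name: [prevalence[name][i] for i in outcome_idx]
                for name in weights
            },
        )
        stage(f"effectiveness vs {benchmark.source}: {effectiveness.n_categories} categories")
    moe = margin_of_error_summary(prevalence)

    sir_rows = []
    followup_ready = (
        reference_rates is not None
        and all(f"diag_{c}" in sample.columns for c in config.cancers)
        and "death" in sample.columns
    )
    if followup_ready:
        uw = uniform_weights(len(sample))
        for cancer in config.cancers:
            for name, wv in [("unweighted", uw), *weights.items()]:
                res = sir_pipeline(
                    sample, wv, reference_rates, config.window, cancer, scheme=name
                )
                sir_rows.append(res.to_dict())
        stage(f"SIRs for {len(config.cancers)} cancers x {1 + len(weights)} schemes")
    sirs = pd.DataFrame(sir_rows)

    result = RunResult(config, sample, weights, prevalence, effectiveness, moe, sirs, log)
    if write:
        _write_bundle(result)
    return result


def _write_bundle(result: RunResult) -> None:
    outdir = Path(result.config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# config_hash={result.config.config_hash()} seed={result.config.seed}\n"

    for name, wv in result.weights.items():
        path = outdir / f"weights_{name}.csv"
        with open(path, "w") as fh:
            fh.write(header)
            wv.to_frame().to_csv(fh, index=False)
    for scheme, tables in result.prevalence.items():
        frames = []
        for t in tables:
            f = t.table.copy()
            f.insert(0, "characteristic", t.characteristic)
            frames.append(f)
        path = outdir / f"prevalence_{scheme}.csv"
        with open(path, "w") as fh:
            fh.write(header)
            pd.concat(frames, ignore_index=True).to_csv(fh, index=False)
    if result.effectiveness is not None:
        with open(outdir / "effectiveness.csv", "w") as fh:
            fh.write(header)
            result.effectiveness.measures.to_csv(fh, index=False)
    with open(outdir / "margin_of_error.csv", "w") as fh:
        fh.write(header)
        result.moe.rename_axis("scheme").to_csv(fh)
    if len(result.sirs):
        with open(outdir / "sir.csv", "w") as fh:
            fh.write(header)
            result.sirs.to_csv(fh, index=False)
    (outdir / "run.log").write_text("\n".join(result.log_lines) + "\n")
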