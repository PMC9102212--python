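"""End-to-end orchestration: read, harmonize, estimate, meta-analyze, report.

A run is described by a :class:`RunConfig` (usually loaded from a YAML
file): one exposure summary-statistics table, a list of outcome cohorts
grouped by outcome name, a significance level, and an output directory.
For each cohort the pipeline harmonizes the instruments, forms per-SNP
Wald ratios and pools them by fixed-effects IVW; for each outcome with at
least two cohorts it adds a fixed-effects meta-analysis row (label
``META``) with between-cohort Cochran's Q. Outcomes are analyzed
independently with no multiplicity adjustment across them.

The run writes three artifacts into the output directory: ``results.tsv``
(one row per cohort plus one META row per multi-cohort outcome),
``exclusions.tsv`` (every excluded instrument with its reason, exactly
once) and ``run.log``. If any cohort ends with zero usable instruments
the run fails with a named-cohort error and writes no partial results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

from . import simulate as sim
from .errors import ConfigurationError, NoUsableInstrumentsError
from .harmonize import (
    DEFAULT_PALINDROME_EAF_WINDOW,
    HarmonizedInstrument,
    harmonize_all,
    harmonize_pair,
)
from .mr import PooledEstimate, chisq_upper_p, fixed_effects_meta, ivw_pool, wald_ratio
from .sumstats import (
    CohortSpec,
    SummaryStatRecord,
    read_sumstats,
    write_exclusion_report,
    write_results_table,
    write_sumstats,
)

logger = logging.getLogger("tsmr")


def _package_version() -> str:
    try:
        return version("tsmr")
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


class RunConfig(BaseModel):
    """Everything needed to reproduce one analysis run."""

    exposure_path: Path
    cohorts: list[CohortSpec] = Field(min_length=1)
    alpha: float = 0.05
    palindrome_eaf_window: float = DEFAULT_PALINDROME_EAF_WINDOW
    output_dir: Path = Path(".")
    exposure_column_map: Optional[dict[str, str]] = None
    outcome_column_map: Optional[dict[str, str]] = None
    seed: Optional[int] = None  # used only by the simulate subcommand
    log_level: str = "INFO"

    @field_validator("alpha")
    @classmethod
    def _alpha_open_unit(cls, v: float) -> float:
        if not (0 < v < 1):
            raise ValueError("alpha must lie strictly between 0 and 1")
        return v

    @field_validator("cohorts")
    @classmethod
    def _unique_cohorts(cls, v: list[CohortSpec]) -> list[CohortSpec]:
        names = [c.cohort_name for c in v]
        if len(set(names)) != len(names):
            raise ValueError("cohort_name values must be unique within a run")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        try:
            payload = yaml.safe_load(path.read_text(encoding="utf-8"))
            return cls(**payload)
        except Exception as exc:
            raise ConfigurationError(f"bad config {path}: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        payload = self.model_dump(mode="json")
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")


@dataclass(frozen=True)
class AnalysisResult:
    """Outputs of one completed run."""

    results: list[PooledEstimate]
    instruments: list[HarmonizedInstrument]
    results_path: Path
    exclusions_path: Path
    log_path: Path


def _configure_file_log(log_path: Path, level: str) -> logging.Handler:
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, level.upper(), logging.INFO))
    return handler


def run_analysis(config: RunConfig) -> AnalysisResult:
    """Execute the full analysis described by ``config``.

    All estimation happens before any file is written, so a failing cohort
    (for example one with no usable instruments) leaves no partial output.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = _configure_file_log(log_path, config.log_level)
    try:
        logger.info("tsmr version %s", _package_version())
        exposure = read_sumstats(config.exposure_path, config.exposure_column_map)
        logger.info(
            "exposure table %s: %d instruments", config.exposure_path, len(exposure)
        )

        all_instruments: list[HarmonizedInstrument] = []
        per_outcome: dict[str, list[PooledEstimate]] = {}
        for cohort in config.cohorts:
            outcome_records = read_sumstats(cohort.path, config.outcome_column_map)
            try:
                instruments = harmonize_all(
                    exposure,
                    outcome_records,
                    config.palindrome_eaf_window,
                    cohort=cohort.cohort_name,
                )
            except NoUsableInstrumentsError as exc:
                raise NoUsableInstrumentsError(
                    f"cohort {cohort.cohort_name!r} ({cohort.outcome_name}): {exc}"
                ) from exc
            all_instruments.extend(instruments)
            usable = [i for i in instruments if not i.excluded]
            for inst in instruments:
                if inst.excluded:
                    logger.warning(
                        "excluded %s in cohort %s: %s",
                        inst.variant_id,
                        cohort.cohort_name,
                        inst.exclusion_reason,
                    )
            logger.info(
                "cohort %s (%s): %d/%d usable instruments",
                cohort.cohort_name,
                cohort.outcome_name,
                len(usable),
                len(instruments),
            )
            ratios = [wald_ratio(i) for i in usable]
            pooled = ivw_pool(
                ratios,
                alpha=config.alpha,
                label=cohort.cohort_name,
                outcome_name=cohort.outcome_name,
            )
            per_outcome.setdefault(cohort.outcome_name, []).append(pooled)

        results: list[PooledEstimate] = []
        for outcome_name, cohort_estimates in per_outcome.items():
            results.extend(cohort_estimates)
            if len(cohort_estimates) > 1:
                meta = fixed_effects_meta(cohort_estimates, alpha=config.alpha)
                results.append(meta)
                logger.info(
                    "%s meta-analysis of %d cohorts: OR %.2f [%.2f, %.2f], "
                    "p = %.3g, Q = %.2f (df %d, p = %.2f)",
                    outcome_name,
                    meta.n_units,
                    meta.or_,
                    meta.ci_low,
                    meta.ci_high,
                    meta.pvalue,
                    meta.Q,
                    meta.Q_df,
                    meta.Q_p,
                )

        results_path = out_dir / "results.tsv"
        exclusions_path = out_dir / "exclusions.tsv"
        write_results_table(results, results_path)
        write_exclusion_report(all_instruments, exclusions_path)
        logger.info("wrote %s and %s", results_path, exclusions_path)
        return AnalysisResult(
            results=results,
            instruments=all_instruments,
            results_path=results_path,
            exclusions_path=exclusions_path,
            log_path=log_path,
        )
    finally:
        logger.removeHandler(handler)
        handler.close()


def run_simulation(
    output_dir: str | Path,
    seed: int = 0,
    truth_path: str | Path | None = None,
) -> RunConfig:
    """Generate simulated run inputs and a ready-to-run config.

    Without a truth file this writes the canonical study-shaped fixture
    (two instruments, 3 + 2 cohorts over two outcomes). With one, it reads
    a JSON mapping of outcome name to generating truth (or a single truth
    object) and simulates each scenario. Outputs: one exposure table, one
    table per cohort, ``truth.json`` and ``config.yaml``; all byte-stable
    for a fixed seed.
    """
    out_dir = Path(output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if truth_path is None:
        fixture = sim.make_paper_shaped_fixture(seed)
        exposure = fixture.exposure
        outcome_tables = fixture.outcome_tables
        outcome_of = fixture.outcome_of
        truths = fixture.truths
    else:
        truths = sim.read_truth_sidecar(truth_path)
        seeds = np.random.SeedSequence(seed).generate_state(len(truths)) % (2**31)
        exposure = None
        outcome_tables, outcome_of = {}, {}
        for (outcome_name, truth), child in zip(sorted(truths.items()), seeds):
            exp, tables = sim.simulate_sumstats(truth, seed=int(child))
            exposure = exposure or exp  # shared two-sample exposure study
            for c, table in enumerate(tables, start=1):
                name = f"{outcome_name}_cohort_{c}"
                outcome_tables[name] = table
                outcome_of[name] = outcome_name

    exposure_path = out_dir / "exposure.tsv"
    write_sumstats(exposure, exposure_path)
    cohorts = []
    for name, table in outcome_tables.items():
        path = out_dir / f"{name}.tsv"
        write_sumstats(table, path)
        cohorts.append(
            CohortSpec(cohort_name=name, outcome_name=outcome_of[name], path=path)
        )
    sim.write_truth_sidecar(truths, out_dir / "truth.json")

    config = RunConfig(
        exposure_path=exposure_path,
        cohorts=cohorts,
        output_dir=out_dir / "analysis",
        seed=seed,
    )
    config.to_yaml(out_dir / "config.yaml")
    return config


# ---------------------------------------------------------------------------
# built-in analytic self-checks (CLI `selftest`)
# ---------------------------------------------------------------------------


def run_selftest(seed: int = 0) -> list[tuple[str, bool, str]]:
    """Fast analytic checks of the statistical core.

    Returns (name, passed, detail) triples: chi-square tail probabilities
    against the published heterogeneity statistics, IVW against a
    least-squares oracle, harmonization invariants, and a small
    parameter-recovery simulation.
    """
    from .mr import RatioEstimate  # local to keep module surface tidy

    checks: list[tuple[str, bool, str]] = []

    p_ad = chisq_upper_p(0.59, 2)
    p_pd = chisq_upper_p(1.73, 1)
    checks.append(
        (
            "chi-square tails (Q=0.59 df=2, Q=1.73 df=1)",
            round(p_ad, 2) == 0.74 and round(p_pd, 2) == 0.19,
            f"p = {p_ad:.4f}, {p_pd:.4f}",
        )
    )

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(1000):
        k = int(rng.integers(1, 8))
        thetas = rng.normal(0, 1, size=k)
        ses = rng.uniform(0.05, 2.0, size=k)
        pooled = ivw_pool(
            [RatioEstimate(f"rs{i}", t, s) for i, (t, s) in enumerate(zip(thetas, ses))]
        )
        w = np.sqrt(1.0 / ses**2)
        oracle, *_ = np.linalg.lstsq(
            (w * np.ones(k)).reshape(-1, 1), w * thetas, rcond=None
        )
        worst = max(worst, abs(pooled.beta - oracle[0]) / max(abs(oracle[0]), 1e-300))
    checks.append(
        ("IVW vs weighted least-squares oracle", worst < 1e-10, f"max rel err {worst:.2e}")
    )

    exp = SummaryStatRecord(
        variant_id="rs1", effect_allele="C", other_allele="T",
        beta=0.05, se=0.01, pvalue=1e-6, eaf=0.3,
    )
    out_swapped = SummaryStatRecord(
        variant_id="rs1", effect_allele="T", other_allele="C",
        beta=-0.02, se=0.01, pvalue=0.05, eaf=0.7,
    )
    h = harmonize_pair(exp, out_swapped)
    rearmonized = harmonize_pair(
        exp,
        SummaryStatRecord(
            variant_id="rs1", effect_allele=h.effect_allele,
            other_allele=h.other_allele, beta=h.beta_outcome,
            se=h.se_outcome, pvalue=0.05, eaf=h.eaf_outcome,
        ),
    )
    pal_exp = SummaryStatRecord(
        variant_id="rs2", effect_allele="A", other_allele="T",
        beta=0.05, se=0.01, pvalue=1e-6, eaf=0.5,
    )
    pal_out = SummaryStatRecord(
        variant_id="rs2", effect_allele="A", other_allele="T",
        beta=0.01, se=0.01, pvalue=0.3, eaf=0.5,
    )
    pal = harmonize_pair(pal_exp, pal_out)
    checks.append(
        (
            "harmonization invariants",
            h.action_taken == "sign_flip"
            and h.beta_outcome == 0.02
            and rearmonized.action_taken == "as_is"
            and pal.excluded
            and pal.exclusion_reason == "palindromic_ambiguous",
            f"sign_flip beta {h.beta_outcome}, re-harmonized {rearmonized.action_taken}, "
            f"palindrome {pal.exclusion_reason}",
        )
    )

    truth = sim.fixture_truth("AD", seed=seed)
    reps = sim.replicate_meta(truth, n_replicates=200, seed=seed)
    bias = reps["beta"].mean() - truth.theta_true
    mc_se = reps["beta"].std(ddof=1) / np.sqrt(len(reps))
    checks.append(
        (
            "parameter recovery (200 replicates)",
            abs(bias) < 3 * mc_se,
            f"bias {bias:.4f}, MC se {mc_se:.4f}",
        )
    )
    return checks
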