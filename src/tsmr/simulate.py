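"""Synthetic two-sample GWAS summary statistics with known ground truth.

Summary statistics are simulated directly at the estimate level: each
reported beta is a normal draw around its true value with the stated
standard error. This is exactly the sampling model under which the
fixed-effects IVW estimator is derived, so the generator supports
end-to-end checks of estimation bias, confidence-interval coverage and
Cochran's-Q calibration without individual-level genotypes.

The generating truth is: per-allele instrument effects ``gamma_j`` on a
continuous exposure, a causal log-odds effect ``theta_true`` of the
exposure on a binary outcome, and optional per-instrument direct
(pleiotropic) outcome effects ``pleiotropy_j``, so that cohort ``c``
reports ``beta_y_jc ~ Normal(theta_true * gamma_j + pleiotropy_j,
se_y_jc^2)``, independently of the exposure draws (two-sample design).
One global seed governs all streams; the exposure and each cohort get
deterministic child streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .harmonize import harmonize_all
from .mr import fixed_effects_meta, ivw_pool, normal_two_sided_p, wald_ratio
from .sumstats import SummaryStatRecord

#: non-palindromic allele pairs cycled over instruments, so harmonization
#: never faces strand ambiguity unless the caller opts in
_ALLELE_CYCLE = (("C", "T"), ("T", "C"), ("A", "G"), ("G", "A"), ("C", "A"), ("G", "T"))

_MIN_P = 5e-324  # smallest positive subnormal; p-values are never zero


class SimulationTruth(BaseModel):
    """Generating parameters of one synthetic two-sample MR scenario.

    ``se_y`` is a matrix (one row per outcome cohort, one column per
    instrument). ``pleiotropy`` defaults to all zeros (valid instruments).
    """

    model_config = ConfigDict(frozen=True)

    theta_true: float
    gamma: list[float] = Field(min_length=1)
    se_x: list[float] = Field(min_length=1)
    se_y: list[list[float]] = Field(min_length=1)
    pleiotropy: Optional[list[float]] = None
    eaf: Optional[list[float]] = None
    variant_ids: Optional[list[str]] = None
    n_exposure: Optional[int] = Field(default=None, gt=0)
    seed: int = Field(default=0, ge=0, lt=2**31)

    @model_validator(mode="after")
    def _check_shapes(self) -> "SimulationTruth":
        k = len(self.gamma)
        if len(self.se_x) != k:
            raise ValueError("se_x length must match gamma")
        if any(s <= 0 for s in self.se_x):
            raise ValueError("all exposure SEs must be > 0")
        for row in self.se_y:
            if len(row) != k:
                raise ValueError("each se_y row must have one SE per instrument")
            if any(s <= 0 for s in row):
                raise ValueError("all outcome SEs must be > 0")
        if self.pleiotropy is not None and len(self.pleiotropy) != k:
            raise ValueError("pleiotropy length must match gamma")
        if self.eaf is not None:
            if len(self.eaf) != k:
                raise ValueError("eaf length must match gamma")
            if any(not (0 < f < 1) for f in self.eaf):
                raise ValueError("eaf must lie in (0, 1)")
        if self.variant_ids is not None and len(self.variant_ids) != k:
            raise ValueError("variant_ids length must match gamma")
        return self

    @property
    def n_instruments(self) -> int:
        return len(self.gamma)

    @property
    def n_cohorts(self) -> int:
        return len(self.se_y)


def _records(
    betas: np.ndarray,
    ses: Sequence[float],
    ids: Sequence[str],
    alleles: Sequence[tuple[str, str]],
    eafs: Sequence[Optional[float]],
    n: Optional[int],
) -> list[SummaryStatRecord]:
    out = []
    for b, s, vid, (ea, oa), f in zip(betas, ses, ids, alleles, eafs):
        p = max(normal_two_sided_p(float(b) / float(s)), _MIN_P)
        out.append(
            SummaryStatRecord(
                variant_id=vid,
                effect_allele=ea,
                other_allele=oa,
                beta=float(b),
                se=float(s),
                pvalue=p,
                eaf=f,
                n=n,
            )
        )
    return out


def simulate_sumstats(
    truth: SimulationTruth, seed: Optional[int] = None
) -> tuple[list[SummaryStatRecord], list[list[SummaryStatRecord]]]:
    """Draw one exposure table and one outcome table per cohort.

    Exposure betas are Normal(gamma_j, se_x_j^2); cohort-c outcome betas
    are Normal(theta_true * gamma_j + pleiotropy_j, se_y_cj^2), drawn from
    independent streams (two-sample design). P-values are computed from
    the simulated estimates. Identical seed, identical output.
    """
    ss = np.random.SeedSequence(truth.seed if seed is None else seed)
    streams = [np.random.default_rng(child) for child in ss.spawn(1 + truth.n_cohorts)]

    k = truth.n_instruments
    ids = truth.variant_ids or [f"rs{1000 + j}" for j in range(k)]
    alleles = [_ALLELE_CYCLE[j % len(_ALLELE_CYCLE)] for j in range(k)]
    eafs: list[Optional[float]] = list(truth.eaf) if truth.eaf else [None] * k
    gamma = np.asarray(truth.gamma, dtype=float)
    pleio = np.asarray(truth.pleiotropy or [0.0] * k, dtype=float)

    beta_x = streams[0].normal(gamma, truth.se_x)
    exposure = _records(beta_x, truth.se_x, ids, alleles, eafs, truth.n_exposure)

    outcome_tables = []
    for c in range(truth.n_cohorts):
        mean_y = truth.theta_true * gamma + pleio
        beta_y = streams[1 + c].normal(mean_y, truth.se_y[c])
        outcome_tables.append(_records(beta_y, truth.se_y[c], ids, alleles, eafs, None))
    return exposure, outcome_tables


def replicate_meta(
    truth: SimulationTruth,
    n_replicates: int,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Run the full harmonize/ratio/IVW/meta chain on many replicates.

    Returns one row per replicate with the cohort-combined estimate
    (the meta row when the truth has several cohorts, the single IVW row
    otherwise): ``beta, se, pvalue, or_, ci_low, ci_high, Q, Q_df, Q_p``.
    Used for bias, coverage and calibration checks.
    """
    base = np.random.SeedSequence(truth.seed if seed is None else seed)
    rep_seeds = base.generate_state(n_replicates, dtype=np.uint32) % (2**31)
    rows = []
    for rep_seed in rep_seeds:
        exposure, outcomes = simulate_sumstats(truth, seed=int(rep_seed))
        per_cohort = []
        for c, table in enumerate(outcomes):
            insts = harmonize_all(exposure, table, cohort=f"cohort_{c}")
            ratios = [wald_ratio(i) for i in insts if not i.excluded]
            per_cohort.append(
                ivw_pool(ratios, alpha=alpha, label=f"cohort_{c}", outcome_name="sim")
            )
        est = (
            fixed_effects_meta(per_cohort, alpha=alpha)
            if len(per_cohort) > 1
            else per_cohort[0]
        )
        rows.append(
            {
                "beta": est.beta,
                "se": est.se,
                "pvalue": est.pvalue,
                "or_": est.or_,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "Q": est.Q,
                "Q_df": est.Q_df,
                "Q_p": est.Q_p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study-shaped fixture: two unequally strong caffeine-metabolism instruments,
# three cohorts for one outcome and two for the other
# ---------------------------------------------------------------------------

# exposure side: a plasma-caffeine GWAS of n = 9876 with instruments near
# CYP1A2 and AHR; mean effects are placed so the expected two-sided p-values
# are ~1e-20 and ~1.8e-13 (z of about 9.3 and 7.4), strongly unequal strength
_FIXTURE_N_EXPOSURE = 9876
_FIXTURE_IDS = ["rs2472297", "rs4410790"]
_FIXTURE_EAF = [0.27, 0.37]
_FIXTURE_SE_X = [0.0160, 0.0147]
_FIXTURE_GAMMA = [9.262 * 0.0160, 7.379 * 0.0147]

# outcome side: log-OR causal effects on the scale of the study's findings
# (OR ~0.87 for outcome A, ~0.92 for outcome B); per-SNP outcome SEs sized so
# the combined estimate has roughly 50% power at the 5% level, making both
# significant and non-significant runs reachable by seed
_FIXTURE_THETA = {"AD": -0.139, "PD": -0.083}
_FIXTURE_SE_Y = {"AD": [[0.0227, 0.0227]] * 3, "PD": [[0.0237, 0.0237]] * 2}
_FIXTURE_COHORTS = {
    "AD": ["AD_cohort_1", "AD_cohort_2", "AD_cohort_3"],
    "PD": ["PD_cohort_1", "PD_cohort_2"],
}


@dataclass(frozen=True)
class StudyFixture:
    """A complete synthetic run input: one exposure table, five outcome
    cohort tables across two outcomes, and the generating truth."""

    exposure: list[SummaryStatRecord]
    outcome_tables: dict[str, list[SummaryStatRecord]]  # cohort name -> records
    outcome_of: dict[str, str]  # cohort name -> outcome name
    truths: dict[str, SimulationTruth]  # outcome name -> generating truth


def fixture_truth(outcome: str, seed: int = 0) -> SimulationTruth:
    """The generating truth used by :func:`make_paper_shaped_fixture` for
    one outcome ('AD'-shaped: 3 cohorts; 'PD'-shaped: 2 cohorts)."""
    return SimulationTruth(
        theta_true=_FIXTURE_THETA[outcome],
        gamma=_FIXTURE_GAMMA,
        se_x=_FIXTURE_SE_X,
        se_y=_FIXTURE_SE_Y[outcome],
        eaf=_FIXTURE_EAF,
        variant_ids=_FIXTURE_IDS,
        n_exposure=_FIXTURE_N_EXPOSURE,
        seed=seed,
    )


def make_paper_shaped_fixture(seed: int = 0) -> StudyFixture:
    """Generate the canonical synthetic study: two genome-wide-significant
    instruments of unequal strength, three cohorts for outcome AD and two
    for outcome PD, deterministic given the seed.

    The exposure table is drawn once and shared by both outcomes (the
    two-sample design measures the exposure in a single study).
    """
    ss = np.random.SeedSequence(seed)
    seed_a, seed_b = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    truth_a = fixture_truth("AD", seed_a)
    truth_b = fixture_truth("PD", seed_b)

    exposure, tables_a = simulate_sumstats(truth_a)
    _, tables_b = simulate_sumstats(truth_b)

    outcome_tables: dict[str, list[SummaryStatRecord]] = {}
    outcome_of: dict[str, str] = {}
    for outcome, tables in (("AD", tables_a), ("PD", tables_b)):
        for name, table in zip(_FIXTURE_COHORTS[outcome], tables):
            outcome_tables[name] = table
            outcome_of[name] = outcome
    return StudyFixture(
        exposure=exposure,
        outcome_tables=outcome_tables,
        outcome_of=outcome_of,
        truths={"AD": truth_a, "PD": truth_b},
    )


def write_truth_sidecar(truths: dict[str, SimulationTruth], path: str | Path) -> None:
    """Write the generating parameters beside simulated tables, as JSON."""
    payload = {name: t.model_dump() for name, t in truths.items()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_truth_sidecar(path: str | Path) -> dict[str, SimulationTruth]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return {name: SimulationTruth(**t) for name, t in payload.items()}
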