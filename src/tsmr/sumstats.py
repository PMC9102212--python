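"""Reading, validating and writing GWAS summary-statistics and result tables.

A summary-statistics table is a delimited text file (tab or comma, one header
line) with one row per variant. Columns are mapped onto the canonical names
``variant_id, effect_allele, other_allele, beta, se, pvalue, eaf, n`` via a
user-supplied column map; consortium files differ in naming, so no single
header convention is assumed. Only biallelic SNPs with single-base A/C/G/T
alleles are accepted — indels and multi-allelic records are rejected at read
time, with row-number diagnostics. Nothing is ever silently dropped.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .errors import ConfigurationError, DataValidationError

VALID_ALLELES = frozenset("ACGT")

#: canonical column names, also the default column map (identity)
CANONICAL_COLUMNS = (
    "variant_id",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
    "eaf",
    "n",
)

REQUIRED_COLUMNS = CANONICAL_COLUMNS[:6]

RESULT_COLUMNS = (
    "outcome",
    "cohort",
    "n_snps",
    "beta",
    "se",
    "or_",
    "ci_low",
    "ci_high",
    "pvalue",
    "Q",
    "Q_df",
    "Q_p",
)


class SummaryStatRecord(BaseModel):
    """One variant's association with one trait.

    ``beta`` is the per-effect-allele association estimate: log-odds for a
    binary outcome, trait units for a continuous exposure. ``eaf`` is the
    effect-allele frequency and ``n`` the sample size; both are optional
    because the core estimators never require them (palindromic-SNP
    orientation then degrades to exclusion, see :mod:`tsmr.harmonize`).
    """

    model_config = ConfigDict(frozen=True)

    variant_id: str = Field(min_length=1)
    effect_allele: str
    other_allele: str
    beta: float
    se: float = Field(gt=0)
    pvalue: float = Field(gt=0, le=1)
    eaf: Optional[float] = Field(default=None, gt=0, lt=1)
    n: Optional[int] = Field(default=None, gt=0)

    @field_validator("effect_allele", "other_allele", mode="before")
    @classmethod
    def _upper_allele(cls, v: str) -> str:
        v = str(v).strip().upper()
        if v not in VALID_ALLELES:
            raise ValueError(
                f"allele {v!r} is not a single base in A/C/G/T "
                "(indels and multi-allelic records are not supported)"
            )
        return v

    @field_validator("beta")
    @classmethod
    def _finite_beta(cls, v: float) -> float:
        if not math.isfinite(v):
            raise ValueError("beta must be finite")
        return v

    @model_validator(mode="after")
    def _distinct_alleles(self) -> "SummaryStatRecord":
        if self.effect_allele == self.other_allele:
            raise ValueError("effect_allele and other_allele must differ")
        return self

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.effect_allele, self.other_allele)


class CohortSpec(BaseModel):
    """One outcome cohort: a label, the outcome it measures, and the
    location of its summary-statistics table."""

    cohort_name: str = Field(min_length=1)
    outcome_name: str = Field(min_length=1)
    path: Path
    n_cases: Optional[int] = Field(default=None, gt=0)
    n_controls: Optional[int] = Field(default=None, gt=0)


def _detect_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[SummaryStatRecord]:
    """Read one summary-statistics table into validated records.

    Parameters
    ----------
    path
        Delimited text file; the delimiter (tab or comma) is auto-detected
        from the header line.
    column_map
        Mapping from canonical names (``variant_id``, ``effect_allele``,
        ``other_allele``, ``beta``, ``se``, ``pvalue``, optionally ``eaf``
        and ``n``) to the file's column names. Defaults to the identity.

    Raises
    ------
    ConfigurationError
        If the file is missing or a mapped required column is absent.
    DataValidationError
        If any row violates a record invariant (non-positive SE,
        out-of-range p-value, bad alleles, duplicated variant id). The
        message names every offending row.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"summary-statistics file not found: {path}")

    cmap = dict(zip(CANONICAL_COLUMNS, CANONICAL_COLUMNS))
    if column_map:
        cmap.update(column_map)

    table = pd.read_csv(path, sep=_detect_delimiter(path), dtype=str)

    missing = [cmap[c] for c in REQUIRED_COLUMNS if cmap[c] not in table.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: mapped column(s) {missing} not present in header "
            f"{list(table.columns)}"
        )
    optional_present = {
        c: cmap[c] for c in ("eaf", "n") if cmap[c] in table.columns
    }

    records: list[SummaryStatRecord] = []
    problems: list[str] = []
    seen: dict[str, int] = {}
    for i, row in enumerate(table.itertuples(index=False), start=2):  # 1 = header
        raw = dict(zip(table.columns, row))
        payload = {c: raw[cmap[c]] for c in REQUIRED_COLUMNS}
        for c, src in optional_present.items():
            v = raw[src]
            payload[c] = None if (v is None or str(v).strip() in ("", "NA", "nan")) else v
        try:
            rec = SummaryStatRecord(**payload)
        except Exception as exc:  # pydantic ValidationError
            problems.append(f"row {i}: {_summarize_validation(exc)}")
            continue
        if rec.variant_id in seen:
            problems.append(
                f"row {i}: duplicate variant_id {rec.variant_id!r} "
                f"(first seen at row {seen[rec.variant_id]})"
            )
            continue
        seen[rec.variant_id] = i
        records.append(rec)

    if problems:
        raise DataValidationError(f"{path}: " + "; ".join(problems))
    return records


def _summarize_validation(exc: Exception) -> str:
    errors = getattr(exc, "errors", None)
    if callable(errors):
        return "; ".join(
            f"{'.'.join(str(x) for x in e['loc'])}: {e['msg']}" for e in errors()
        )
    return str(exc)


def write_sumstats(records: Sequence[SummaryStatRecord], path: str | Path) -> None:
    """Write records as a tab-delimited summary-statistics table."""
    frame = pd.DataFrame([r.model_dump() for r in records], columns=CANONICAL_COLUMNS)
    frame["n"] = frame["n"].astype("Int64")
    frame.to_csv(path, sep="\t", index=False, na_rep="")


def write_results_table(results: Iterable, path: str | Path) -> pd.DataFrame:
    """Serialize pooled estimates (per-cohort IVW rows plus per-outcome
    ``META`` rows) as a tab-delimited table.

    ``Q_p`` is blank where heterogeneity is undefined (a single pooled
    element, df = 0). Returns the frame that was written.
    """
    rows = list(results)
    if not rows:
        raise ValueError("results must be non-empty")
    frame = pd.DataFrame(
        [
            {
                "outcome": r.outcome_name,
                "cohort": r.label,
                "n_snps": r.n_units,
                "beta": r.beta,
                "se": r.se,
                "or_": r.or_,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "pvalue": r.pvalue,
                "Q": r.Q,
                "Q_df": r.Q_df,
                "Q_p": r.Q_p,
            }
            for r in rows
        ],
        columns=RESULT_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False, na_rep="")
    return frame


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t")


def write_exclusion_report(instruments: Iterable, path: str | Path) -> pd.DataFrame:
    """Write the excluded-instrument report (variant_id, reason) for a run."""
    frame = pd.DataFrame(
        [
            {"variant_id": inst.variant_id, "cohort": inst.cohort, "reason": inst.exclusion_reason}
            for inst in instruments
            if inst.excluded
        ],
        columns=("variant_id", "cohort", "reason"),
    )
    frame.to_csv(path, sep="\t", index=False)
    return frame
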