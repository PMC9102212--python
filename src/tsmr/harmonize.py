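"""Allele harmonization of exposure/outcome summary-statistic pairs.

Before a Wald ratio can be formed, the variant-outcome association must be
expressed on the same effect allele as the variant-exposure association.
Consortium files may report the opposite allele (requiring a sign flip of
the outcome beta), the opposite DNA strand (requiring A<->T / C<->G
complementation of the allele labels but no sign change), or both.

Palindromic variants (A/T or C/G) are special: their two alleles are each
other's complements, so strand orientation cannot be resolved from allele
labels alone. Such variants are oriented by allele frequency when both
files report an effect-allele frequency safely away from 0.5, and excluded
as ambiguous otherwise. Exclusions are recorded with a reason, never raised
as exceptions and never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .errors import NoUsableInstrumentsError
from .sumstats import SummaryStatRecord

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default half-width of the frequency window around 0.5 inside which a
#: palindromic variant is considered unorientable
DEFAULT_PALINDROME_EAF_WINDOW = 0.08

ACTIONS = ("as_is", "sign_flip", "strand_flip", "strand_flip_and_sign_flip")


def _complement_pair(a: str, b: str) -> tuple[str, str]:
    return COMPLEMENT[a], COMPLEMENT[b]


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for A/T and C/G variants, whose strand is label-ambiguous."""
    return COMPLEMENT[effect_allele] == other_allele


@dataclass(frozen=True)
class HarmonizedInstrument:
    """A variant's exposure and outcome associations on a common effect
    allele (the exposure file's), plus the harmonization action taken.

    For excluded instruments the outcome-side fields are carried through
    unharmonized (or absent) and must not be used for estimation.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: Optional[float]
    se_outcome: Optional[float]
    action_taken: Optional[str] = None
    eaf_exposure: Optional[float] = None
    eaf_outcome: Optional[float] = None
    excluded: bool = False
    exclusion_reason: Optional[str] = None
    cohort: str = ""

    def __post_init__(self) -> None:
        if not self.excluded:
            if self.se_exposure is None or self.se_exposure <= 0:
                raise ValueError(f"{self.variant_id}: se_exposure must be > 0")
            if self.se_outcome is None or self.se_outcome <= 0:
                raise ValueError(f"{self.variant_id}: se_outcome must be > 0")
            if self.action_taken not in ACTIONS:
                raise ValueError(
                    f"{self.variant_id}: action_taken {self.action_taken!r} "
                    f"not in {ACTIONS}"
                )


def _excluded(
    exposure: SummaryStatRecord, reason: str, outcome: SummaryStatRecord | None = None
) -> HarmonizedInstrument:
    return HarmonizedInstrument(
        variant_id=exposure.variant_id,
        effect_allele=exposure.effect_allele,
        other_allele=exposure.other_allele,
        beta_exposure=exposure.beta,
        se_exposure=exposure.se,
        beta_outcome=outcome.beta if outcome else None,
        se_outcome=outcome.se if outcome else None,
        eaf_exposure=exposure.eaf,
        eaf_outcome=outcome.eaf if outcome else None,
        excluded=True,
        exclusion_reason=reason,
    )


def harmonize_pair(
    exposure: SummaryStatRecord,
    outcome: SummaryStatRecord,
    palindrome_eaf_window: float = DEFAULT_PALINDROME_EAF_WINDOW,
) -> HarmonizedInstrument:
    """Align one outcome record onto the exposure record's effect allele.

    The exposure orientation is canonical. Four reconciliations are tried:
    identical alleles (``as_is``), swapped alleles (``sign_flip``: the
    outcome beta is negated and its frequency complemented), complemented
    alleles (``strand_flip``: labels change, beta does not), and
    complemented-and-swapped (``strand_flip_and_sign_flip``). Irreconcilable
    alleles yield an excluded instrument with reason ``allele_mismatch``.

    Palindromic variants are oriented by comparing minor/major allele
    frequency between the two files; with either frequency missing or
    within ``palindrome_eaf_window`` of 0.5 the variant is excluded with
    reason ``palindromic_ambiguous``.
    """
    if exposure.variant_id != outcome.variant_id:
        raise ValueError(
            f"variant mismatch: {exposure.variant_id} vs {outcome.variant_id}"
        )

    ea, oa = exposure.alleles
    if is_palindromic(ea, oa):
        return _harmonize_palindromic(exposure, outcome, palindrome_eaf_window)

    out_alleles = outcome.alleles
    if out_alleles == (ea, oa):
        action, flip_sign = "as_is", False
    elif out_alleles == (oa, ea):
        action, flip_sign = "sign_flip", True
    elif out_alleles == _complement_pair(ea, oa):
        action, flip_sign = "strand_flip", False
    elif out_alleles == _complement_pair(oa, ea):
        action, flip_sign = "strand_flip_and_sign_flip", True
    else:
        return _excluded(exposure, "allele_mismatch", outcome)

    return _build(exposure, outcome, action, flip_sign)


def _harmonize_palindromic(
    exposure: SummaryStatRecord,
    outcome: SummaryStatRecord,
    window: float,
) -> HarmonizedInstrument:
    ea, oa = exposure.alleles
    # for a palindrome the allele *set* is strand-invariant; anything else
    # cannot be the same variant
    if set(outcome.alleles) != {ea, oa}:
        return _excluded(exposure, "allele_mismatch", outcome)
    if exposure.eaf is None or outcome.eaf is None:
        return _excluded(exposure, "palindromic_ambiguous", outcome)
    # closed interval, robust to float representation of e.g. 0.42
    tol = window + 1e-9
    if abs(exposure.eaf - 0.5) <= tol or abs(outcome.eaf - 0.5) <= tol:
        return _excluded(exposure, "palindromic_ambiguous", outcome)

    # orient by frequency: the outcome's effect allele is identified with
    # whichever exposure allele has the matching minor/major status
    exp_eaf = exposure.eaf if outcome.effect_allele == ea else 1.0 - exposure.eaf
    same_side = (exp_eaf < 0.5) == (outcome.eaf < 0.5)
    labels_swapped = outcome.effect_allele != ea
    if same_side:
        # frequencies agree with the label reading
        action = "as_is" if not labels_swapped else "sign_flip"
        flip_sign = labels_swapped
    else:
        # frequencies contradict the labels: the file is on the other strand
        action = "strand_flip" if labels_swapped else "strand_flip_and_sign_flip"
        flip_sign = not labels_swapped
    return _build(exposure, outcome, action, flip_sign)


def _build(
    exposure: SummaryStatRecord,
    outcome: SummaryStatRecord,
    action: str,
    flip_sign: bool,
) -> HarmonizedInstrument:
    beta_out = -outcome.beta if flip_sign else outcome.beta
    eaf_out = outcome.eaf
    if flip_sign and eaf_out is not None:
        eaf_out = 1.0 - eaf_out
    return HarmonizedInstrument(
        variant_id=exposure.variant_id,
        effect_allele=exposure.effect_allele,
        other_allele=exposure.other_allele,
        beta_exposure=exposure.beta,
        se_exposure=exposure.se,
        beta_outcome=beta_out,
        se_outcome=outcome.se,
        action_taken=action,
        eaf_exposure=exposure.eaf,
        eaf_outcome=eaf_out,
    )


def harmonize_all(
    exposure_records: Sequence[SummaryStatRecord],
    outcome_records: Sequence[SummaryStatRecord],
    palindrome_eaf_window: float = DEFAULT_PALINDROME_EAF_WINDOW,
    cohort: str = "",
) -> list[HarmonizedInstrument]:
    """Harmonize every exposure instrument against one outcome table.

    Inner join on ``variant_id``, preserving the exposure file's order.
    Exposure variants absent from the outcome table are emitted as
    excluded instruments with reason ``missing_in_outcome``.

    Raises
    ------
    NoUsableInstrumentsError
        If no instrument survives harmonization.
    """
    by_id = {r.variant_id: r for r in outcome_records}
    out: list[HarmonizedInstrument] = []
    for exp in exposure_records:
        match = by_id.get(exp.variant_id)
        if match is None:
            inst = _excluded(exp, "missing_in_outcome")
        else:
            inst = harmonize_pair(exp, match, palindrome_eaf_window)
        if cohort:
            inst = replace(inst, cohort=cohort)
        out.append(inst)
    if not any(not i.excluded for i in out):
        label = f" for cohort {cohort!r}" if cohort else ""
        raise NoUsableInstrumentsError(f"no usable instruments{label}")
    return out
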