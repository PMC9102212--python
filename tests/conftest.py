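import pytest

from tsmr.sumstats import SummaryStatRecord


def record(
    variant_id="rs1",
    effect_allele="C",
    other_allele="T",
    beta=0.05,
    se=0.01,
    pvalue=1e-6,
    eaf=None,
    n=None,
):
    return SummaryStatRecord(
        variant_id=variant_id,
        effect_allele=effect_allele,
        other_allele=other_allele,
        beta=beta,
        se=se,
        pvalue=pvalue,
        eaf=eaf,
        n=n,
    )


@pytest.fixture
def two_instruments():
    """Two non-palindromic caffeine-instrument-shaped exposure records."""
    return [
        record("rs2472297", "C", "T", beta=0.148, se=0.016, pvalue=1e-20, eaf=0.27),
        record("rs4410790", "T", "C", beta=0.109, se=0.015, pvalue=1.8e-13, eaf=0.37),
    ]
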