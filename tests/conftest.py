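import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from smokemr.sumstats_io import SnpAssociation, SummaryStatsTable  # noqa: E402


def make_record(
    rsid="rs1",
    effect_allele="A",
    other_allele="G",
    beta=0.05,
    se=0.01,
    pvalue=None,
    eaf=0.3,
    n=1000,
):
    """A valid SnpAssociation with a p-value consistent with beta/se."""
    from scipy import stats

    if pvalue is None:
        pvalue = float(np.clip(2 * stats.norm.sf(abs(beta / se)), 1e-300, 1.0))
    return SnpAssociation(
        rsid=rsid, effect_allele=effect_allele, other_allele=other_allele,
        beta=beta, se=se, pvalue=pvalue, eaf=eaf, n=n,
    )


def make_table(records, trait_name="trait", **kw):
    return SummaryStatsTable(
        trait_name=trait_name, records={r.rsid: r for r in records}, **kw
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def table_factory():
    return make_table


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
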