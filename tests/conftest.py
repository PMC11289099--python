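import numpy as np
import pandas as pd
import pytest

from pgnet.synthetic import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def demo_cohort():
    """One small cohort shared by read-only tests."""
    return simulate_cohort(CohortSpec(seed=7))


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no genetic effects anywhere (null calibration)."""
    spec = CohortSpec(
        seed=11,
        h2_liability=0.0,
        cis_effect_sd=0.0,
        trans_effect_sd=0.0,
        n_samples=800,
    )
    return simulate_cohort(spec)


def make_sumstats(
    variant_ids,
    beta,
    se,
    eaf=None,
    effect_allele="A",
    other_allele="G",
    chrom="1",
    pos=None,
    n=1000,
):
    """Helper to build a well-formed summary-statistics frame."""
    from scipy.stats import norm

    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    m = len(variant_ids)
    if eaf is None:
        eaf = np.full(m, 0.3)
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    p = 2 * norm.sf(np.abs(beta / se))
    return pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chrom": [chrom] * m,
            "pos": pos,
            "effect_allele": [effect_allele] * m if isinstance(effect_allele, str) else effect_allele,
            "other_allele": [other_allele] * m if isinstance(other_allele, str) else other_allele,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "p": np.maximum(p, 1e-300),
            "n": [n] * m,
        }
    )
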