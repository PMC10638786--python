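import numpy as np
import pytest

from pubertwin.synthetic import (CohortConfig, CpgSpec, generate_cohort,
                                 generate_methylation)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(n_families=150), seed=11)


@pytest.fixture(scope="session")
def paired_cohort():
    """Larger cohort with no singletons, for correlation checks."""
    cfg = CohortConfig(n_families=4000, singleton_fraction=0.0)
    return generate_cohort(cfg, seed=7)


def ace_spec(cpg_id="cg_test", a2=0.5, c2=0.3, e2=0.2, **kw):
    return CpgSpec(cpg_id=cpg_id, baseline_mean=0.5, a2=a2, c2=c2, e2=e2,
                   total_sd=0.05, **kw)


def pair_values(cohort, mat, cpg_id):
    """(y1, y2, zygosity) arrays for the complete pairs of one CpG."""
    pairs = cohort.pairs
    vals = mat.values.loc[cpg_id]
    y1 = vals.reindex(pairs.id1).values
    y2 = vals.reindex(pairs.id2).values
    return y1, y2, pairs.zygosity.values


def intrapair_corr(y1, y2, zyg, which):
    m = zyg == which
    return float(np.corrcoef(y1[m], y2[m])[0, 1])


@pytest.fixture(scope="session")
def ace_methylation(paired_cohort):
    mat = generate_methylation(paired_cohort, [ace_spec()], seed=3)
    return mat
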