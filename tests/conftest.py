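import numpy as np
import pandas as pd
import pytest

from snpenrich.cohort import (
    CohortDesign,
    VariantSpec,
    default_design,
    generate_cohort,
    generate_gene_catalog,
)


@pytest.fixture(scope="session")
def small_cohort():
    """n=140 cohort over 18 training / 20 case / 80 control genes, no effects."""
    design = default_design(n_case_genes=20, n_control_genes=80, snps_per_gene=3, seed=11)
    return generate_cohort(design)


@pytest.fixture(scope="session")
def catalog():
    return generate_gene_catalog(n_case=30, n_control=120, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_design(**kw) -> CohortDesign:
    kw.setdefault("variant_specs", [VariantSpec("snp1", 0.3, "GENE1", "1")])
    return CohortDesign(**kw)
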