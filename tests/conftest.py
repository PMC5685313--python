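import numpy as np
import pandas as pd
import pytest

from remission_rank.config import StudyConfig
from remission_rank.datatypes import CohortTable, GenotypeMatrix
from remission_rank.synthetic_cohort import simulate_study


@pytest.fixture(scope="session")
def bundle():
    """Small coherent synthetic study: genotypes, cohort, annotation,
    interaction network, planted effects."""
    gm, cohort, ann, ppi, spec = simulate_study(n_samples=150, n_snps=40,
                                                seed=11)
    return {"genotypes": gm, "cohort": cohort, "annotation": ann,
            "ppi": ppi, "effects": spec}


@pytest.fixture
def tiny_genotypes():
    dosage = np.array([[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 2, np.nan]],
                      dtype=float)
    return GenotypeMatrix(sample_ids=["s1", "s2", "s3", "s4"],
                          snp_ids=["snpA", "snpB", "snpC"],
                          dosage=dosage,
                          allele_labels={"snpA": ("a", "A"),
                                         "snpB": ("t", "T"),
                                         "snpC": ("g", "G")})


@pytest.fixture
def tiny_cohort():
    data = pd.DataFrame({
        "remission": [1, 0, 1, 0],
        "age": [45.0, 60.0, 38.0, 55.0],
        "hba1c": [6.5, 8.9, 6.1, np.nan],
        "insulin_medication": [0.0, 1.0, 0.0, 1.0],
    }, index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"))
    return CohortTable(data, dichotomous=("insulin_medication",),
                       continuous=("age", "hba1c"))


@pytest.fixture
def fast_config():
    """Protocol constants with a small nested-CV schedule for speed."""
    return StudyConfig(outer_folds=3, inner_folds=2, inner_repeats=1,
                       min_total_clinical=2, min_total_snp=1,
                       max_iterations=200)
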