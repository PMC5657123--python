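import numpy as np
import pandas as pd
import pytest

import sexqtl
from sexqtl.genio import GenotypeMatrix


@pytest.fixture(scope="session")
def cohort():
    """One seeded study-scale cohort shared by read-only tests."""
    cfg = sexqtl.default_config(seed=11)
    gm, em, sex = sexqtl.simulate_cohort(cfg)
    return cfg, gm, em, sex


def toy_genotypes(calls: dict[str, list[str]], samples: list[str],
                  chromosome: str = "2", alleles: str = "A/G",
                  risk: str = "A", positions: dict[str, int] | None = None
                  ) -> GenotypeMatrix:
    """Hand-built genotype matrix with uniform annotation."""
    annot = pd.DataFrame({
        "chromosome": [chromosome] * len(calls),
        "position": [positions.get(s, 1_000_000) if positions else 1_000_000
                     for s in calls],
        "alleles": [alleles] * len(calls),
        "risk_allele": [risk] * len(calls),
    }, index=pd.Index(list(calls), name="rsid"))
    return GenotypeMatrix(calls=pd.DataFrame(calls, index=samples),
                          snp_annotation=annot)


def statsmodels_ols(X: np.ndarray, y: np.ndarray):
    """Independent OLS oracle: statsmodels params/bse/t/p."""
    import statsmodels.api as sm

    fit = sm.OLS(y, X).fit()
    return (np.asarray(fit.params), np.asarray(fit.bse),
            np.asarray(fit.tvalues), np.asarray(fit.pvalues))


def random_interaction_instance(rng: np.random.Generator, n: int):
    """A random testable (dosage, sex, expression) triple."""
    while True:
        maf = rng.uniform(0.2, 0.5)
        d = rng.binomial(2, maf, size=n).astype(float)
        s = (rng.random(n) < 0.55).astype(float)
        classes, counts = np.unique(d, return_counts=True)
        if classes.size >= 2 and counts.min() >= 3 and np.unique(s).size == 2:
            break
    y = (rng.normal(0, 1, n) + rng.uniform(-1, 1) * d
         + rng.uniform(-1, 1) * s + rng.uniform(-1, 1) * d * s)
    return d, s, y
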