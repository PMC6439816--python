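import numpy as np
import pytest

from twinprs.types import (
    BivariateTwinSpec,
    EtiologicCorrelations,
    PolygenicSpec,
    ThresholdSet,
    VarianceComponents,
    ZYGOSITY_GROUPS,
)
from twinprs.simulate import simulate_twin_pairs


def make_ae_spec(n_per_group=1000, seed=42, prevalence=0.05, a2_trait=0.6,
                 a2_liab=0.8, ra=0.5, re=0.3, **kwargs):
    return BivariateTwinSpec(
        trait=VarianceComponents(a2=a2_trait, e2=1 - a2_trait),
        liability=VarianceComponents(a2=a2_liab, e2=1 - a2_liab),
        corr=EtiologicCorrelations(rA=ra, rE=re),
        thresholds=ThresholdSet.from_prevalence(prevalence),
        n_pairs={g: n_per_group for g in ZYGOSITY_GROUPS},
        seed=seed,
        **kwargs,
    )


@pytest.fixture(scope="session")
def ae_spec():
    return make_ae_spec()


@pytest.fixture(scope="session")
def ae_table(ae_spec):
    """5000 twin pairs from a known AE generating model."""
    return simulate_twin_pairs(ae_spec)


@pytest.fixture(scope="session")
def poly_spec():
    return PolygenicSpec(m_variants=200, n_causal=20, n_discovery=50_000,
                         h2_score=0.1, ld_rho=0.4, seed=7)


@pytest.fixture(scope="session")
def poly_cohort(poly_spec):
    """Genotypes + discovery GWAS + outcomes for 800 twin pairs."""
    from twinprs.simulate import (
        attach_genetic_phenotype,
        draw_causal_effects,
        simulate_discovery_sumstats,
        simulate_genotypes,
    )

    table = simulate_twin_pairs(make_ae_spec(n_per_group=160, seed=5))
    geno, meta = simulate_genotypes(poly_spec, table)
    effects = draw_causal_effects(poly_spec)
    ss = simulate_discovery_sumstats(poly_spec, geno.variants, meta["maf"],
                                     effects)
    outcomes = attach_genetic_phenotype(geno, effects, poly_spec,
                                        subpop=meta["subpop"])
    return {"table": table, "geno": geno, "sumstats": ss,
            "outcomes": outcomes, "effects": effects, "meta": meta}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
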