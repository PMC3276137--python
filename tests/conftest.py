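import numpy as np
import pytest

from crgwas.core_data import GenotypeMatrix, PhenotypeTable
from crgwas.structure_adjust import estimate_kinship
from crgwas.synthetic_data import (
    SimulationSpec,
    simulate_annotations,
    simulate_genotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def small_panel():
    """A 96-line structured panel with one planted causal fragment."""
    spec = SimulationSpec(seed=42, n_samples=96, n_fragments=40, n_traits=2,
                          causal_fragments=1, effect_model="s_weighted")
    geno, labels, frag_ids = simulate_genotypes(spec)
    ann = simulate_annotations(geno, frag_ids, spec)
    kin = estimate_kinship(geno)
    pheno, truth = simulate_phenotypes(geno, labels, kin, frag_ids, spec)
    return {
        "spec": spec, "geno": geno, "labels": labels, "frag_ids": frag_ids,
        "annotations": ann, "kinship": kin, "pheno": pheno, "truth": truth,
    }


@pytest.fixture
def tiny_geno():
    """4 samples x 3 haploid SNPs, one missing call."""
    calls = np.array(
        [
            [0.0, 1.0, 0.0],
            [0.0, 1.0, np.nan],
            [1.0, 0.0, 1.0],
            [1.0, 0.0, 0.0],
        ]
    )
    return GenotypeMatrix(samples=["a", "b", "c", "d"],
                          snp_ids=["s1", "s2", "s3"], calls=calls)


@pytest.fixture
def toy_pheno():
    vals = np.array(
        [
            [1.0, 2.0],
            [2.0, 4.0],
            [3.0, 6.0],
            [4.0, np.nan],
        ]
    )
    return PhenotypeTable(samples=list("abcd"), traits=["t1", "t2"], values=vals)
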