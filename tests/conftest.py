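import numpy as np
import pytest

from selocus.synth import LocusTemplate, build_reference_locus
from selocus.transmission import (
    AlleleProfile,
    PlantGenotype,
    TransgeneGene,
    TransgeneLocus,
    parse_genotype,
)


@pytest.fixture(scope="session")
def reference_locus():
    """Default-scale synthetic reference locus, built once per session."""
    return build_reference_locus(LocusTemplate(seed=1))


@pytest.fixture
def te_heterozygote():
    return parse_genotype("T/E")


def random_allele_pool(rng: np.random.Generator) -> dict[str, AlleleProfile]:
    """A shared allele table: one functional profile per haplotype label."""
    return {
        label: AlleleProfile(
            label,
            has_functional_killer=bool(rng.integers(2)),
            has_functional_protector=bool(rng.integers(2)),
        )
        for label in ["T", "E", "A", "B", "C"]
    }


def random_genotype(
    rng: np.random.Generator, pool: dict[str, AlleleProfile] | None = None
) -> PlantGenotype:
    """A random diploid genotype over random allele profiles and transgenes."""
    if pool is None:
        pool = random_allele_pool(rng)
    labels = list(pool)
    pair = tuple(pool[l] for l in rng.choice(labels, size=2))
    transgenes = []
    if rng.random() < 0.5:
        transgenes.append(
            TransgeneLocus(
                gene=TransgeneGene.PROTECTOR, dosage=int(rng.integers(0, 3))
            )
        )
    if rng.random() < 0.3:
        transgenes.append(
            TransgeneLocus(gene=TransgeneGene.KILLER, dosage=int(rng.integers(0, 3)))
        )
    return PlantGenotype(se_alleles=pair, transgenes=tuple(transgenes))
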