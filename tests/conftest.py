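import numpy as np
import pytest

from geckomap.model import GenomeLayout, Genotype, Observation, Role, VariantClass, VariantObservation
from geckomap.simulate import CrossSimConfig, simulate_cross


def make_variant(
    chrom="chr1",
    start=999,
    ref="A",
    alt="G",
    qual=50.0,
    fa=(0, 25),
    mo=(13, 12),
    hom=(0, 25),
    het=(12, 13),
    gts=(Genotype.HOM_ALT, Genotype.HET, Genotype.HOM_ALT, Genotype.HET),
    vclass=VariantClass.SNP,
):
    """Hand-built variant record with sensible defaults for an informative,
    cosegregating site."""

    roles = (Role.FATHER_HOM, Role.MOTHERS_HET, Role.POOL_HOM, Role.POOL_HET)
    depths = (fa, mo, hom, het)
    obs = {r: Observation(d[0], d[1], g) for r, d, g in zip(roles, depths, gts)}
    return VariantObservation(
        chrom=chrom, start=start, ref=ref, alt=alt, variant_class=vclass, qual=qual, obs=obs
    )


SMALL_LAYOUT = GenomeLayout((("chr1", 2_000_000), ("chr2", 2_000_000)))


def small_config(**overrides):
    """A 2-chromosome 4 Mb cross: fast enough for per-test simulation."""

    defaults = dict(
        layout=SMALL_LAYOUT,
        causal_chrom="chr1",
        causal_pos=1_000_000,
        linked_core_bp=400_000,
        informative_density_near=300.0,
        informative_density_far=300.0,
        background_density=100.0,
        seed=7,
    )
    defaults.update(overrides)
    return CrossSimConfig(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    return simulate_cross(small_config())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240615)
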