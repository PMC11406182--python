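import numpy as np
import pytest

from censat_kit import synthetic_data as sd
from censat_kit.io_core import GenomeSequences


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def planted_genome(
    families: dict[str, tuple[int, float, int]],
    seed: int,
    background: int = 100_000,
    mutation_rate: float = 0.05,
    n_chroms: int = 1,
):
    """Genome with one array per family per chromosome plus background.

    families: family_id -> (monomer_length, at_content, copies).
    Returns (genome, truth, monomers).
    """
    specs = {
        fid: sd.SatelliteSpec(fid, monomer_length=ml, at_content=at,
                              mutation_rate=mutation_rate)
        for fid, (ml, at, _) in families.items()
    }
    monomers = {
        fid: sd.make_monomer(s.monomer_length, s.at_content, sd.derive_seed(seed, fid))
        for fid, s in specs.items()
    }
    chrom_specs = []
    for c in range(n_chroms):
        elements = [sd.BackgroundElement(background)]
        for fid, (_, _, copies) in families.items():
            elements.append(sd.ArrayElement(fid, copies))
            elements.append(sd.BackgroundElement(background))
        chrom_specs.append(sd.ChromosomeSpec(f"chr{c + 1}", elements))
    genome, _, truth = sd.simulate_species(
        chrom_specs, seed, family_monomers=monomers, family_specs=specs
    )
    return genome, truth, monomers


@pytest.fixture
def single_family_genome():
    return planted_genome({"fam1": (168, 0.68, 500)}, seed=1)


def random_genome(length: int, seed: int, at: float = 0.5) -> GenomeSequences:
    g = GenomeSequences()
    g.add("chr1", sd.random_background(length, at, np.random.default_rng(seed)))
    return g
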