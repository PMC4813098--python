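import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from richcompare.synthetic_world import (
    Block,
    SamplingDesign,
    gen_landscape,
    gen_virtual_species,
    simulate_sampling,
)


@pytest.fixture(scope="session")
def small_landscape():
    return gen_landscape(60, 60, seed=11)


@pytest.fixture(scope="session")
def small_world():
    """An 80x80 world with 8 species and 4 surveyed blocks — fast enough
    for unit tests, structured like the full default world."""
    landscape = gen_landscape(80, 80, seed=7)
    species, suits, occs = gen_virtual_species(landscape, 8, seed=7)
    blocks = [
        Block(55, 55, 16, 16),
        Block(55, 10, 16, 16),
        Block(32, 32, 16, 16),
        Block(10, 55, 16, 16),
    ]
    design = SamplingDesign(
        systematic_blocks=blocks,
        opportunistic_n_localities=150,
        seed=13,
    )
    records = simulate_sampling(
        {sp.species_id: occ for sp, occ in zip(species, occs)}, design
    )
    return {
        "landscape": landscape,
        "species": species,
        "suitabilities": suits,
        "occupancies": occs,
        "design": design,
        "records": records,
    }
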