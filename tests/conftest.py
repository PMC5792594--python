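import pytest

from clademiner.simulate import (
    FamilySpec,
    default_design,
    simulate_bundle,
)


@pytest.fixture(scope="session")
def small_bundle():
    """A compact study: 3+3 species, one shared family (2 subfamilies),
    one clade-specific family, 12 decoys."""
    design = default_design(n_ingroup=3, n_outgroup=3)
    specs = [
        FamilySpec("famA", n_subfamilies=2, domain_length=360),
        FamilySpec("famB", n_subfamilies=1, domain_length=360, clade_specific=True),
    ]
    return simulate_bundle(design=design, specs=specs, decoy_count=12, seed=11)


@pytest.fixture(scope="session")
def default_bundle():
    """The default study design: 13 species (5 ingroup + 8 outgroup), a
    shared and a clade-specific family, 40 decoys."""
    return simulate_bundle(seed=1)
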