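import numpy as np
import pytest

from mycopan.annotation_io import GeneFeature, GenomeAnnotation, RepeatFeature


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """One scaffold with two repeats and three genes at known distances."""
    return GenomeAnnotation(
        species_id="toy",
        scaffolds=[("scf1", 10_000), ("scf2", 5_000)],
        genes=[
            GeneFeature("g1", "scf1", 1_000, 2_000, "+"),
            GeneFeature("g2", "scf1", 5_000, 5_500, "-"),
            GeneFeature("g3", "scf2", 100, 700, "+"),
        ],
        repeats=[
            RepeatFeature("r1", "scf1", 100, 400, "LTR"),
            RepeatFeature("r2", "scf1", 3_000, 3_500, "DNA"),
        ],
    ).validate()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
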