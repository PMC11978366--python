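import pytest

from proteorefine.config import Config
from proteorefine.model_refinement import refine_all
from proteorefine.synthetic_data import generate_bundle


@pytest.fixture(scope="session")
def bundle():
    """The default 8-scenario synthetic study (seed 42)."""
    return generate_bundle(seed=42)


@pytest.fixture(scope="session")
def refined(bundle):
    """The refinement result for the default bundle."""
    return refine_all(
        bundle.genome,
        bundle.corrupted_models,
        bundle.peptides,
        bundle.truth_proteins,
        bundle.transcripts,
        Config(),
    )
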