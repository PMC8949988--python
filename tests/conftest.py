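import warnings

import pytest

from fiamrm import apply_threshold, parse_cfmid
from fiamrm.compound_db import organism_metabolome
from fiamrm.synthetic_fixtures import (
    FixtureSpec,
    gen_batch,
    gen_library,
    gen_predicted_spectra,
    gen_transition_tables,
)

# double 5-fold CV on 6-replicate classes inevitably puts <5 members of a
# class into some inner training split; sklearn warns, the CV stays valid
warnings.filterwarnings("ignore", message="The least populated class")


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec(seed=1)


@pytest.fixture(scope="session")
def library_fixture(spec):
    return gen_library(spec)


@pytest.fixture(scope="session")
def predicted_docs(spec, library_fixture):
    return gen_predicted_spectra(spec, library_fixture)


@pytest.fixture(scope="session")
def predicted_spectra(predicted_docs):
    """Parsed and 5%-thresholded predicted spectra per (kegg_id, mode)."""
    out = {}
    for (kegg, mode), text in predicted_docs.items():
        out[(kegg, mode)] = [apply_threshold(s, 5.0)
                             for s in parse_cfmid(text, kegg, mode)]
    return out


@pytest.fixture(scope="session")
def transition_tables(spec, library_fixture):
    return gen_transition_tables(spec, library_fixture)


@pytest.fixture(scope="session")
def organism_records(library_fixture):
    records, _ = organism_metabolome(library_fixture.model, library_fixture.library)
    return records


@pytest.fixture(scope="session")
def batch_fixture(spec):
    return gen_batch(spec, [f"M{i:03d}" for i in range(100)])
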