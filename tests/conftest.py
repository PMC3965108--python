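import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the sw_oracle helper

from scope_autoclass.fixtures import FixtureSpec, fig2_fixture, generate_release


@pytest.fixture(scope="session")
def worked_example():
    """The two-domain worked example (554-residue chain, observed 2-547)."""
    return fig2_fixture()


@pytest.fixture(scope="session")
def small_release():
    """Six domains over five chains, one of them a two-domain chain."""
    return generate_release(
        FixtureSpec(seed=7, n_superfamilies=3, domains_per_family=2,
                    multidomain_fraction=0.5)
    )


@pytest.fixture(scope="session")
def flat_release():
    """Eight single-domain whole chains across four superfamilies."""
    return generate_release(
        FixtureSpec(seed=11, n_superfamilies=4, domains_per_family=2)
    )
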