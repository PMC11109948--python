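import numpy as np
import pytest

from h4zip.motifs import build_network
from h4zip.synthetic import generate_dataset, get_preset


@pytest.fixture(scope="session")
def wt_network():
    """Wild-type 4-site acetylation lattice (16 motifs, 32 edges)."""
    return build_network()


@pytest.fixture(scope="session")
def k16r_network():
    """K16R 3-site lattice (8 motifs, 12 edges)."""
    return build_network(("K5", "K8", "K12"))


@pytest.fixture(scope="session")
def wt_bundle():
    """One noisy wild-type dataset, shared across tests (read-only)."""
    return generate_dataset(get_preset("wildtype"), seed=11)


def random_site_rates(rng, sites, lo=0.005, hi=0.5):
    """Admissible random per-site rates spanning the assay's time scale."""
    return {s: float(r) for s, r in zip(sites, rng.uniform(lo, hi, len(sites)))}
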