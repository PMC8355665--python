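import numpy as np
import pytest
from hypothesis import settings

from colchain.dayhoff import dayhoff_model
from colchain.records import CHAIN_ORDER, ConcatenatedAlignment
from colchain.simulate import sample_timetree, simulate_chain

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model():
    return dayhoff_model()


def simulate_rate_alignment(seed, n_taxa=20, root_age=430.0,
                            lengths=None, rates=None, model=None):
    """Alignment + chronogram simulated under the rate model itself.

    Used for parameter-recovery checks: sequences evolve with no structural
    mask, i.e. exactly under the generative model the ML estimator assumes.
    """
    lengths = lengths or {"alpha1": 1058, "alpha2": 1041, "alpha3": 1062}
    rates = rates or {"alpha1": 0.00067, "alpha2": 0.00088, "alpha3": 0.00094}
    model = model or dayhoff_model()
    rng = np.random.default_rng(seed)
    tree = sample_timetree(n_taxa, 0.015, 0.005, root_age, seed=rng)
    blocks = {}
    for chain in CHAIN_ORDER:
        tips, _, _ = simulate_chain(
            tree, chain, lengths[chain], rates[chain], model,
            invariant_mask={}, seed=rng,
        )
        blocks[chain] = tips
    taxa = sorted(blocks["alpha1"])
    rows = ["".join(blocks[c][t] for c in CHAIN_ORDER) for t in taxa]
    partitions = {}
    start = 1
    for chain in CHAIN_ORDER:
        partitions[chain] = (start, start + lengths[chain] - 1)
        start += lengths[chain]
    aln = ConcatenatedAlignment(taxa=taxa, matrix=rows, partitions=partitions)
    return aln, tree


@pytest.fixture(scope="session")
def small_rate_sim(model):
    """One seeded rate-model simulation shared across rates tests."""
    lengths = {"alpha1": 400, "alpha2": 400, "alpha3": 400}
    return simulate_rate_alignment(11, n_taxa=12, lengths=lengths, model=model)
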