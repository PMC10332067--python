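import pytest

from treccap.caller import index_reference
from treccap.pipeline import call_sample
from treccap.reference import ReferenceConfig, build_mini_reference
from treccap.simulate import DEFAULT_TRIM, NO_TRIM, simulate_cohort


@pytest.fixture(scope="session")
def ref():
    return build_mini_reference(ReferenceConfig(seed=0))


@pytest.fixture(scope="session")
def index(ref):
    return index_reference(ref)


@pytest.fixture(scope="session")
def noisy_cohort(ref):
    """100 simulated events (20 per type) at default junctional noise and
    0.002 substitution error, fully called and classified."""
    used, samples = simulate_cohort(
        ref, n_per_class=20, noise=DEFAULT_TRIM, err_rate=0.002, seed=5
    )
    idx = index_reference(used)
    results = {
        s.sample_id: call_sample(used, s.pairs, s.sample_id, index=idx)
        for s in samples
    }
    return used, samples, results


@pytest.fixture(scope="session")
def clean_cohort(ref):
    """20 events with zero junctional noise and error-free reads."""
    used, samples = simulate_cohort(
        ref, n_per_class=4, noise=NO_TRIM, err_rate=0.0, seed=11
    )
    idx = index_reference(used)
    results = {
        s.sample_id: call_sample(used, s.pairs, s.sample_id, index=idx)
        for s in samples
    }
    return used, samples, results


def junction_recall(samples, results, tol=5):
    found = total = 0
    for s in samples:
        calls = results[s.sample_id].calls
        pos = {
            (c.side_a[0], c.side_a[1], c.side_b[0], c.side_b[1]) for c in calls
        }
        for t in s.truth_junctions:
            total += 1
            found += any(
                ca == t.contig_a and cb == t.contig_b
                and abs(pa - t.pos_a) <= tol and abs(pb - t.pos_b) <= tol
                for ca, pa, cb, pb in pos
            )
    return found, total
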