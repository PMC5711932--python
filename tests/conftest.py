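import numpy as np
import pytest

from camconverge.core_io import CANONICAL_TIMES, DielProfile

TIMES = np.asarray(CANONICAL_TIMES)


def cosine_profile(gene_id, species, phase, baseline=2.0, amplitude=1.0, reps=1,
                   noise_sd=0.0, rng=None):
    """FPKM-scale cosinor profile peaking at `phase` hours after light onset."""
    log_mean = baseline + amplitude * np.cos(2 * np.pi * (TIMES - phase) / 24.0)
    if noise_sd > 0:
        assert rng is not None
        eps = rng.normal(0.0, noise_sd, size=(TIMES.size, reps))
    else:
        eps = np.zeros((TIMES.size, reps))
    return DielProfile(gene_id=gene_id, species=species, times=TIMES,
                       values=np.exp(log_mean[:, None] + eps))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_binary_tree_newick(leaf_labels, rng, with_lengths=True):
    """Random rooted binary topology over the given leaf labels."""
    nodes = [f"{l}" + (f":{rng.uniform(0.05, 0.3):.3f}" if with_lengths else "")
             for l in leaf_labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        merged = f"({a},{b})" + (f":{rng.uniform(0.05, 0.3):.3f}" if with_lengths else "")
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0].rsplit(":", 1)[0] + ";" if with_lengths else nodes[0] + ";"
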