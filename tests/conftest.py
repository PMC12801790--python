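import warnings

import numpy as np
import pytest

import fragclass as fc


@pytest.fixture(scope="session")
def toy_cfg():
    """Default study-shaped simulation config with a fixed seed and the
    1x analysis depth used throughout the test cohorts."""
    return fc.SimulationConfig(seed=7, depth=1.0)


@pytest.fixture(scope="session")
def toy_genome(toy_cfg):
    return fc.build_toy_genome(toy_cfg)


@pytest.fixture(scope="session")
def healthy_panel(toy_cfg, toy_genome):
    """Bin counts of four healthy samples, the panel-of-normals input."""
    from fragclass.cnv import count_fragments_per_bin

    panel = []
    for i in range(4):
        frags = fc.simulate_sample(toy_genome, toy_cfg, "healthy", 0.0, f"pon{i}", 900 + i)
        panel.append(count_fragments_per_bin(frags, toy_genome.bins))
    return panel


def make_fragments(reference: dict, triples, sample_id="s"):
    """SampleFragments from (chrom, start, end) triples over a dict
    reference, with motifs attached."""
    from fragclass.fragments import ReferenceGenome, from_arrays

    ref = ReferenceGenome(reference)
    names = tuple(reference)
    code_of = {c: i for i, c in enumerate(names)}
    codes = [code_of[c] for c, _, _ in triples]
    starts = [s for _, s, _ in triples]
    ends = [e for _, _, e in triples]
    return from_arrays(sample_id, names, codes, starts, ends, reference=ref), ref


@pytest.fixture(autouse=True)
def _quiet_known_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="fewer than 20 bins")
        warnings.filterwarnings("ignore", message="fewer than 10 arms")
        yield
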