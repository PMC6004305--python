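import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from bsmeth import simulate
from bsmeth.meth_extract import ExtractionConfig


SMALL_SIM = simulate.SimConfig(
    chrom_lengths={"chrA": 20_000, "chrB": 12_000},
    n_genes=4,
    n_tes=4,
    spikes=simulate.SpikeConfig(n_per_context={"CG": 3, "CHG": 2, "CHH": 2}),
    n_sirna_loci=60,
    seed=7,
)


@pytest.fixture(scope="session")
def small_bundle():
    """A 32-kb two-chromosome study used by most integration-style tests."""
    return simulate.simulate_bundle(SMALL_SIM)


@pytest.fixture(scope="session")
def default_bundle():
    """The default 200-kb study at the full configured conditions."""
    return simulate.simulate_bundle(simulate.SimConfig(seed=11))


def make_counts(sites: pd.DataFrame, n_meth, n_unmeth, **extract_kw) -> pd.DataFrame:
    """Hand-build a count table over a site frame."""
    from bsmeth.meth_extract import attach_calls

    counts = sites[["chrom", "pos", "strand", "context"]].copy()
    counts["n_meth"] = np.asarray(n_meth)
    counts["n_unmeth"] = np.asarray(n_unmeth)
    counts["n_other"] = 0
    return attach_calls(counts, ExtractionConfig(**extract_kw))
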