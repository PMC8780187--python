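import numpy as np
import pandas as pd
import pytest

from methylrad import synthio
from methylrad.digestion import enumerate_recognition_sites
from methylrad.model import GenomeAssembly
from methylrad.sitequant import SiteCountMatrix


@pytest.fixture(scope="session")
def small_genome() -> GenomeAssembly:
    """50-kb x 2 random genome, enough for a few hundred enzyme sites."""
    spec = synthio.SyntheticGenomeSpec(n_scaffolds=2, scaffold_length=50_000, gc_content=0.45, seed=11)
    return synthio.generate_genome(spec)


@pytest.fixture(scope="session")
def small_sites(small_genome):
    return enumerate_recognition_sites(small_genome)


@pytest.fixture(scope="session")
def small_methylome(small_sites):
    return synthio.generate_methylome(small_sites, synthio.MethylomeSpec(seed=7))


def make_matrix(depths: dict[str, list[int]], contexts=None, library_sizes=None,
                positions=None) -> SiteCountMatrix:
    """Construct a SiteCountMatrix from per-sample depth columns."""
    samples = sorted(depths)
    n = len(depths[samples[0]])
    pos = positions if positions is not None else list(range(0, 100 * n, 100))
    idx = pd.MultiIndex.from_arrays(
        [["chr1"] * n, pos, ["+"] * n], names=["scaffold", "position", "strand"]
    )
    data = {
        "context": contexts if contexts is not None else ["CG"] * n,
        "patterns": ["CCGG"] * n,
    }
    for s in samples:
        data[s] = depths[s]
    sizes = library_sizes or {s: max(1, int(np.sum(depths[s]))) for s in samples}
    return SiteCountMatrix(pd.DataFrame(data, index=idx), sizes)
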