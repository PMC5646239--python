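import numpy as np
import pytest

from evescreen.screen import (
    assign_taxon,
    filter_shadow_loci,
    merge_hits_to_loci,
    screen_assembly,
)
from evescreen.synthetic import (
    SimulationConfig,
    default_probe_library,
    generate_assembly_with_truth,
)


@pytest.fixture(scope="session")
def probe_library():
    return default_probe_library()


@pytest.fixture(scope="session")
def screened_default_assembly(probe_library):
    """One default synthetic assembly (seed 1), screened once and shared."""
    cfg = SimulationConfig(seed=1)
    contigs, truths, repeats = generate_assembly_with_truth(cfg)
    hits = screen_assembly(contigs, probe_library)
    loci = merge_hits_to_loci(hits)
    for locus in loci:
        assign_taxon(locus)
    loci = filter_shadow_loci(loci)
    return {
        "config": cfg,
        "contigs": contigs,
        "truths": truths,
        "repeats": repeats,
        "hits": hits,
        "loci": loci,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20251)
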