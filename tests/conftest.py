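import numpy as np
import pytest

from xdense import synthetic_data as sd
from xdense.genomic_io import Genome, Chromosome


@pytest.fixture(scope="session")
def shape_table():
    return sd.generate_shape_table(seed=0)


@pytest.fixture(scope="session")
def probe_set():
    """Default synthetic gcPBM-like probe set with planted (4,3) flanks."""
    probes, truth = sd.generate_probe_set(sd.ProbeSetConfig(), seed=5)
    return probes, truth


@pytest.fixture(scope="session")
def small_genome():
    """200 kb X + two 200 kb autosomes with planted (GA)k runs."""
    specs = [
        sd.ChromSpec("chrX", 200_000, "X", arm_label="Muller-A",
                     run_density_per_mb={4: 30.0, 6: 10.0}),
        sd.ChromSpec("chr2L", 200_000, "autosome", arm_label="Muller-B",
                     run_density_per_mb={4: 10.0, 6: 5.0}),
        sd.ChromSpec("chr2R", 200_000, "autosome", arm_label="Muller-C",
                     run_density_per_mb={4: 10.0, 6: 5.0}),
    ]
    return sd.generate_genome(specs, seed=17)


@pytest.fixture
def toy_genome():
    return Genome([
        Chromosome("chrX", "GAGAGAGA" + "T" * 92, "X"),
        Chromosome("chr2", "ACGT" * 25, "autosome"),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
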