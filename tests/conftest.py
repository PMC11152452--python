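import numpy as np
import pandas as pd
import pytest

from transinv.genotypes import GenotypeTable
from transinv.simulate import default_scenario, simulate_radiation


@pytest.fixture(scope="session")
def radiation():
    """One standard trans-species scenario shared by the pipeline tests."""
    scenario = default_scenario(seed=11, n_loci=800)
    return scenario, simulate_radiation(scenario)


def make_table(dosages, pops=None, positions=None, chrom="chr1", sex=None):
    """Small literal GenotypeTable for oracle tests."""
    d = np.asarray(dosages, dtype=np.int8)
    n, s = d.shape
    pops = pops or ["pop0"] * n
    sex = sex or ["U"] * n
    samples = pd.DataFrame(
        {"population": pops, "sex": sex},
        index=pd.Index([f"s{i}" for i in range(n)], name="sample"),
    )
    pos = np.arange(s) if positions is None else np.asarray(positions)
    return GenotypeTable(d, np.array([chrom] * s, dtype=object), pos, samples)
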