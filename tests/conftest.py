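import numpy as np
import pandas as pd
import pytest

from methylmem.simulate import SimulationParams, simulate_study


@pytest.fixture(scope="session")
def study():
    """Full-size default synthetic study (2 x 500 kb, 200 genes)."""
    return simulate_study(SimulationParams(), seed=11)


@pytest.fixture(scope="session")
def small_params():
    return SimulationParams(
        n_contigs=1, contig_len=60_000, n_genes=10,
        n_short=2, n_mid=2, n_long=1, n_rdt_only=1, n_plain_deg=1,
        n_mrg_short=1, n_mrg_mid=1, n_mrg_plain=1,
    )


@pytest.fixture(scope="session")
def small_study(small_params):
    """Desk-scale study for pipeline-level tests."""
    return simulate_study(small_params, seed=5)


def make_site_table(positions, meth, total, contig="c1", strand="+", context="CG"):
    """Small helper: single-contig site table from parallel lists."""
    return pd.DataFrame(
        {
            "contig": contig,
            "position": np.asarray(positions, dtype=int),
            "strand": strand,
            "context": context,
            "meth_count": np.asarray(meth, dtype=int),
            "total_count": np.asarray(total, dtype=int),
        }
    )
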