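import numpy as np
import pandas as pd
import pytest

from glycodelta.synthdata import SimConfig, simulate, write_simulation


@pytest.fixture(scope="session")
def small_sim():
    """A modest synthetic study reused across tests (deterministic)."""
    return simulate(SimConfig(n_proteins=120, seed=7))


@pytest.fixture(scope="session")
def small_sim_paths(small_sim, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("simdata")
    return write_simulation(small_sim, outdir)


@pytest.fixture()
def toy_design():
    """Two batches x (2 tumor + 2 NAT + reference)."""
    rows = []
    pair = 0
    for b in ("B1", "B2"):
        for _ in range(2):
            pair += 1
            rows.append((f"T{pair}", b, f"c{2 * pair - 1}", "Tumor", f"P{pair}", False))
            rows.append((f"N{pair}", b, f"c{2 * pair}", "NAT", f"P{pair}", False))
        rows.append((f"REF_{b}", b, "c_ref", "Reference", pd.NA, True))
    from glycodelta.quant import StudyDesign

    return StudyDesign(
        pd.DataFrame(
            rows,
            columns=["sample_id", "batch", "channel", "condition", "pair_id", "is_reference"],
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
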