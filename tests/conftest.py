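import numpy as np
import pytest

import hdxamend as hx
from hdxamend.synthetic_study import DEFAULT_TIMES

LABELING = hx.ExchangeConditions(ph_read=7.0, temperature=293.15)


@pytest.fixture(scope="session")
def labeling_conditions():
    return LABELING


@pytest.fixture(scope="session")
def small_protein():
    """One synthetic protein with truth, map, rates and a clean uptake table."""
    seq = hx.generate_sequence(60, seed=11)
    profile = hx.generate_protection_profile(60, seed=12, sequence=seq, protein_id="toy")
    pmap = hx.generate_peptide_map(seq, seed=13, n_peptides=30, protein_id="toy")
    rates = hx.compute_kint(seq, LABELING)
    table = hx.simulate_dataset(pmap, profile, rates, DEFAULT_TIMES)
    return {"sequence": seq, "profile": profile, "map": pmap, "rates": rates,
            "table": table}


@pytest.fixture(scope="session")
def sampled_controls(small_protein):
    back = hx.sample_control_library("back", 0.70, 0.08, 10_000, seed=21)
    fwd = hx.sample_control_library("fwd", 0.05, 0.02, 10_000, seed=22)
    return hx.assign_controls(small_protein["map"], back, fwd, seed=23)


def make_uptake(rfu, times=(15.0, 60.0), protein="p"):
    """Tiny uptake table around an explicit RFU matrix."""
    rfu = np.asarray(rfu, dtype=float)
    n = rfu.shape[0]
    seq = "ACDEFGHIKLMNQRSTVWY"[: n + 3]
    peptides = tuple(hx.Peptide(seq[i : i + 3], i + 1, i + 3) for i in range(n))
    pmap = hx.PeptideMap(protein, seq, peptides)
    return hx.UptakeTable(pmap, np.asarray(times, dtype=float)[: rfu.shape[1]], rfu)
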