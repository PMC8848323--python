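import numpy as np
import pytest

import synpaint as sp


def random_assembly(rng: np.random.Generator, n_records=3, min_len=50, max_len=400):
    """A small random assembly over {A,C,G,T,N} for round-trip tests."""
    records = []
    for i in range(n_records):
        length = int(rng.integers(min_len, max_len + 1))
        seq = "".join(rng.choice(list("ACGTN"), size=length, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        records.append(sp.SequenceRecord(id=f"scf_{i}", seq=seq))
    return sp.Assembly(records=records, name="random")


@pytest.fixture(scope="session")
def tiny_scenario():
    """A 6-Mb simulated genome shared by painting/dominance tests: 2 macros of
    2 Mb, 2 micros of 1 Mb, with markers and an identity-rearrangement truth."""
    spec = sp.KaryotypeSpec(macro_lengths=(2_000_000,) * 2, micro_lengths=(1_000_000,) * 2)
    assembly, genes, repeats = sp.simulate_query(spec, sp.CompositionParams(), seed=11)
    markers = sp.generate_markers(assembly)
    return {
        "spec": spec,
        "assembly": assembly,
        "genes": genes,
        "repeats": repeats,
        "markers": markers,
    }
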