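import dataclasses

import numpy as np
import pytest

from metafuse.synthetic_data import SMALL_PRESET, generate_sequence_dataset


@pytest.fixture(scope="session")
def seq_data(tmp_path_factory):
    """Small synthetic sequence dataset shared across tests (read-only)."""
    spec = dataclasses.replace(SMALL_PRESET, seed=202)
    return generate_sequence_dataset(spec, tmp_path_factory.mktemp("seq"))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def write_sam(path, sq, records):
    """Write a minimal SAM file: sq = {contig: length}, records = raw lines."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in sq.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for rec in records:
            fh.write(rec + "\n")
    return path
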