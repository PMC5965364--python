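import numpy as np
import pytest

from archaeome import simkit


@pytest.fixture(scope="session")
def pack():
    """Small mixed-community reference pack shared across tests."""
    return simkit.build_reference_pack(
        {"environmental": 4, "oral": 2, "gut_other": 2, "pathogen": 1,
         "virus": 1, "eukaryote": 1},
        genome_length=12_000,
        markers_per_taxon=5,
        marker_length=400,
        host_genome_length=20_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def ancient_params():
    return simkit.DamageParams(0.3, 0.01, 0.4, 0.001)


@pytest.fixture(scope="session")
def marker_index(pack):
    from archaeome import profiler

    tax = pack.marker_taxonomy()
    return profiler.build_marker_index(pack.marker_sequences(), tax)


def make_reads(seqs, quality=37, prefix="r"):
    """ReadRecords at constant quality from raw sequences."""
    from archaeome.records import ReadRecord

    q = chr(33 + quality)
    return [ReadRecord(f"{prefix}{i:05d}", s, q * len(s)) for i, s in enumerate(seqs)]
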