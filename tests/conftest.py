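"""Shared fixtures: a small two-chromosome genome and derived objects."""

import logging

import pytest

from semap import cnv_windows, core_io

# keep test output readable; the loggers are exercised implicitly
logging.getLogger("semap").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def genome():
    return core_io.GenomeTable({"chr1": 10_000_000, "chr2": 8_000_000})


@pytest.fixture(scope="session")
def grid(genome):
    return cnv_windows.tile_genome(genome, width=15_000)
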