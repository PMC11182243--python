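import pytest

from puffnull import CellSummary, Channel, Location, compute_deltas, generate_experiment
from puffnull.synthetic_data import TABLE1_DELTA_STATS


@pytest.fixture(scope="session")
def table1_cells() -> list[CellSummary]:
    """The study's printed per-cell summaries: 24 cells, n=4 each."""
    return [
        CellSummary(iop=iop, location=loc, channel=ch, n=4, mean=m, sd=s)
        for ch, by_loc in TABLE1_DELTA_STATS.items()
        for loc, by_iop in by_loc.items()
        for iop, (m, s) in by_iop.items()
    ]


@pytest.fixture(scope="session")
def upper_same_cells(table1_cells):
    """Per-channel upper-same cells (the location nearest the puff)."""
    return {
        ch: [
            c
            for c in table1_cells
            if c.location is Location.UPPER_SAME and c.channel is ch
        ]
        for ch in Channel
    }


@pytest.fixture(scope="session")
def default_records():
    """One seeded default experiment (96 records)."""
    return generate_experiment(seed=1)


@pytest.fixture(scope="session")
def default_deltas(default_records):
    return compute_deltas(default_records)
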