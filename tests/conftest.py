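"""Shared fixtures: the published summary-table values used across tests.

The column summary rows (replicate-group means with multiplicities), the
batch nitrate-reduction percentages, and the biomass-dose pairs are printed
experiment summaries and serve as inputs here.
"""

from __future__ import annotations

import pytest

from meorkit.columns import ColumnRecord
from meorkit.response import BiomassDose


@pytest.fixture(scope="session")
def dose_pairs_no_nitrate() -> list[BiomassDose]:
    return [
        BiomassDose(0.090, 6.9, False),
        BiomassDose(0.092, 5.5, False),
        BiomassDose(0.819, 11.1, False),
        BiomassDose(1.769, 14.2, False),
    ]


@pytest.fixture(scope="session")
def dose_pairs_with_nitrate() -> list[BiomassDose]:
    return [
        BiomassDose(0.096, 9.4, True),
        BiomassDose(0.105, 9.2, True),
        BiomassDose(0.634, 16.0, True),
        BiomassDose(1.238, 21.9, True),
    ]


@pytest.fixture(scope="session")
def column_summary_rows() -> list[ColumnRecord]:
    """Replicate-group column rows: (ids, n, ROIP/PV, %ROIP, substrates)."""
    raw = [
        ("1-2", 2, 0.53, 2.5, "T"),
        ("3-4", 2, 0.42, 5.4, "N"),
        ("5-6", 2, 0.39, 16.0, "EN"),
        ("7", 1, 0.58, 6.9, "E"),
        ("8", 1, 0.62, 5.5, "E"),
        ("9", 1, 0.47, 11.1, "T"),
        ("10", 1, 0.43, 14.2, "T"),
        ("11", 1, 0.60, 9.4, "EN"),
        ("12", 1, 0.54, 9.2, "EN"),
        ("13", 1, 0.47, 16.0, "TN"),
        ("14", 1, 0.42, 21.9, "TN"),
        ("15-17", 3, 0.48, 10.5, "TN"),
        ("18-20", 3, 0.51, 7.3, "TN"),
        ("21-23", 3, 0.51, 10.3, "TN"),
    ]
    return [
        ColumnRecord(id=i, n=n, roip_pv_fraction=f, percent_roip=p, substrates=s)
        for i, n, f, p, s in raw
    ]


@pytest.fixture(scope="session")
def nitrate_reduction_percent_20mM() -> list[float]:
    """Per-culture percent nitrate reduction at 20 mM nitrate (six cultures)."""
    return [95.3, 98.4, 98.3, 97.1, 99.4, 99.4]
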