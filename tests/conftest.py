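"""Shared fixtures: tiny hand-built screen datasets."""

import pandas as pd
import pytest

from screenscore.screen_data import REQUIRED_COLUMNS, ScreenDataset


def make_wells(rows):
    """Build a ScreenDataset from (plate, row, col, reagent, gene, cls, arm,
    rep, signal) tuples."""
    df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    return ScreenDataset(df)


def plate_rows(plate_id, specs, arms=(("selected", (1,)),)):
    """Expand (row, col, reagent, gene, cls, signal_by_rep) well specs.

    ``signal_by_rep`` is either a number (same signal in every replicate)
    or a dict {(arm, rep): signal}.
    """
    out = []
    for row, col, reagent, gene, cls, signal in specs:
        for arm, reps in arms:
            for rep in reps:
                if isinstance(signal, dict):
                    s = signal[(arm, rep)]
                else:
                    s = signal
                out.append((plate_id, row, col, reagent, gene, cls, arm, rep, s))
    return out


@pytest.fixture
def small_dataset():
    """One plate: 2 negative controls at 100, one candidate at 50% growth."""
    rows = plate_rows("P1", [
        ("A", 1, "shLUC", "", "negative_control", 100.0),
        ("A", 2, "shRFP", "", "negative_control", 100.0),
        ("B", 1, "shX_1", "GeneX", "candidate", 50.0),
    ], arms=(("selected", (1, 2)), ("unselected", (1, 2))))
    return make_wells(rows)
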