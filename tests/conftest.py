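"""Shared fixtures: printed-grid fixtures, synthetic cohorts, sessions."""

from pathlib import Path

import pandas as pd
import pytest

from corsinorm.session import SpanBlock, SpanSession, TrialScoreTable
from corsinorm.synthetic import HealthyCohortSpec, generate_healthy

DATA_DIR = Path(__file__).parent / "data"


def load_grid_fixture(name: str) -> pd.DataFrame:
    """Printed correction-grid cells transcribed from the published tables."""
    return pd.read_csv(DATA_DIR / name)


@pytest.fixture(scope="session")
def cs_grid_cells():
    return load_grid_fixture("table_cs_grid.csv")


@pytest.fixture(scope="session")
def cssl_grid_cells():
    return load_grid_fixture("table_cssl_grid.csv")


@pytest.fixture(scope="session")
def cssr_grid_cells():
    return load_grid_fixture("table_cssr_grid.csv")


@pytest.fixture(scope="session")
def healthy_cohort():
    """A normative-sized synthetic healthy cohort (n = 340)."""
    return generate_healthy(HealthyCohortSpec(n=340, seed=11))


@pytest.fixture(scope="session")
def score_table():
    return TrialScoreTable()


def passed_block(length: int, fail: int = 0) -> SpanBlock:
    """A span block with ``3 - fail`` exactly-correct responses."""
    targets = []
    for i in range(3):
        seq = [((i * 3 + j * 5) % 9) + 1 for j in range(length)]
        # make cube ids unique within the target
        seen, tgt = set(), []
        nxt = 1
        for c in seq:
            while c in seen:
                c = c % 9 + 1
            seen.add(c)
            tgt.append(c)
        targets.append(tuple(tgt))
    responses = [t if i >= fail else tuple(reversed(t)) for i, t in enumerate(targets)]
    return SpanBlock(length=length, targets=targets, responses=list(responses))


def span_session(passed_lengths, failed_length=None) -> SpanSession:
    blocks = [passed_block(n) for n in passed_lengths]
    if failed_length is not None:
        blocks.append(passed_block(failed_length, fail=2))
    return SpanSession(blocks=blocks)
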