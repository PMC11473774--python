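import numpy as np
import pandas as pd
import pytest

from irislib.activation import ActivityProfile, DeconvolvedCohort
from irislib.interaction_db import InteractionDatabase, LRInteraction
from irislib.synthetic import build_database


@pytest.fixture
def small_db() -> InteractionDatabase:
    """Six interactions over four cell-type pairs, one complex ligand."""
    return InteractionDatabase(
        (
            LRInteraction(("CD8A", "CD8B"), ("PDCD1",), "TCD8", "Mal", "checkpoint"),
            LRInteraction(("CXCL9",), ("CXCR3",), "skinDC", "TCD8", "chemotaxis"),
            LRInteraction(("CCL2",), ("CCR2",), "Mal", "Macrophage", "chemotaxis"),
            LRInteraction(("XCL1",), ("XCR1",), "NK", "skinDC", "chemotaxis"),
            LRInteraction(("CD274",), ("PDCD1",), "Mal", "TCD8", "checkpoint"),
            LRInteraction(("IL6",), ("IL6R", "IL6ST"), "CAF", "Mal", "stimulatory"),
        )
    )


@pytest.fixture
def demo_db() -> InteractionDatabase:
    """Bundled demo universe: 48 interactions across 8 cell-type pairs."""
    return build_database(48)


@pytest.fixture
def demo_db_path(tmp_path, demo_db):
    from irislib.interaction_db import write_database

    path = tmp_path / "db.tsv"
    write_database(demo_db, path)
    return path


def make_profile(values, interaction_ids, sample_ids, timepoints, responses, cohort="c0"):
    """Build an ActivityProfile from plain nested lists (NaN = non-measurable)."""
    matrix = pd.DataFrame(
        np.asarray(values, dtype=float), index=interaction_ids, columns=sample_ids
    )
    samples = pd.DataFrame(
        {"cohort_id": cohort, "timepoint": timepoints, "response": responses},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ActivityProfile(matrix, samples)


def make_cohort(cohort_id, expression, timepoints, responses):
    """Build a DeconvolvedCohort from {cell_type: DataFrame} and metadata lists."""
    first = next(iter(expression.values()))
    samples = pd.DataFrame(
        {"timepoint": timepoints, "response": responses},
        index=pd.Index(list(first.columns), name="sample_id"),
    )
    return DeconvolvedCohort(cohort_id, samples, expression)
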