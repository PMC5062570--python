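import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from offtarget import simulate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def default_config():
    return simulate.SimulationConfig(seed=1)


@pytest.fixture
def planted_silac_config():
    """Study-like layout: 200 background proteins, one competed target at 2.7."""
    return simulate.SimulationConfig(
        seed=1,
        n_proteins=200,
        planted_targets=[("CTSD_SYNTH", 2.7)],
        background_ratio_sigma=0.15,
        n_replicates=4,
    )


@pytest.fixture
def peptide_records():
    """Small hand-written oriented SILAC table."""
    rows = [
        # protein A: 3 peptides in rep1, competed
        ("A", "target", "PEPTIDEA", "rep1", "competitor_in_light", 2.5),
        ("A", "target", "PEPTIDEB", "rep1", "competitor_in_light", 2.7),
        ("A", "target", "PEPTIDEC", "rep2", "competitor_in_light", 2.9),
        # protein B: background
        ("B", "bg", "PEPTIDED", "rep1", "competitor_in_light", 1.0),
        ("B", "bg", "PEPTIDEE", "rep2", "competitor_in_heavy", 1.0),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "protein_accession",
            "protein_description",
            "peptide_sequence",
            "replicate_id",
            "orientation",
            "ratio_hl",
        ],
    )
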