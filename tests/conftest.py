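import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from tepuidiet.diet_io import DietDataset, derive_gut_status

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def build_dataset(spec_rows, prey_rows, vocabulary=None) -> DietDataset:
    """Assemble a validated in-memory dataset from plain tuples.

    ``spec_rows``: (specimen_id, species, sex); ``prey_rows``:
    (specimen_id, category, length_mm, width_mm, identifiable,
    fragmented).  Gut status is derived, as in the reader.
    """
    specimens = pd.DataFrame(spec_rows, columns=["specimen_id", "species", "sex"])
    specimens["site"] = pd.NA
    prey = pd.DataFrame(
        prey_rows,
        columns=["specimen_id", "category", "length_mm", "width_mm",
                 "identifiable", "fragmented"],
    )
    prey["finer_taxon"] = pd.NA
    prey["length_mm"] = pd.to_numeric(prey["length_mm"])
    prey["width_mm"] = pd.to_numeric(prey["width_mm"])
    prey["identifiable"] = prey["identifiable"].astype(bool)
    prey["fragmented"] = prey["fragmented"].astype(bool)
    specimens["gut_status"] = derive_gut_status(specimens, prey)
    kwargs = {"vocabulary": vocabulary} if vocabulary else {}
    return DietDataset(specimens, prey, provenance="test fixture", **kwargs)


@pytest.fixture
def small_dataset() -> DietDataset:
    """Three analyzable guts, one empty, one unidentifiable-only."""
    nan = np.nan
    return build_dataset(
        [
            ("s1", "O_quelchii", "male"),
            ("s2", "O_quelchii", "female"),
            ("s3", "O_quelchii", "male"),
            ("s4", "O_quelchii", "female"),   # empty
            ("s5", "O_quelchii", "unknown"),  # unidentifiable only
        ],
        [
            ("s1", "Acari", 0.6, 0.4, True, False),
            ("s1", "Acari", 0.5, 0.3, True, False),
            ("s1", "Coleoptera", 2.0, 1.0, True, False),
            ("s2", "Coleoptera", 1.8, 0.9, True, False),
            ("s2", "Araneae", 1.5, 0.8, True, False),
            ("s3", "Acari", 0.7, 0.5, True, False),
            ("s3", "Annelida", 3.0, 0.6, True, False),
            ("s5", None, nan, nan, False, True),
            ("s5", None, nan, nan, False, True),
        ],
    )
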