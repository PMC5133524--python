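import numpy as np
import pandas as pd
import pytest

import sbptraj as st
from sbptraj.simulate import LongitudinalPhenotypes


@pytest.fixture(scope="session")
def small_ped():
    """3 extended families, ~40 individuals."""
    return st.simulate_pedigree(3, 3, 2.5, seed=11)


@pytest.fixture(scope="session")
def mid_ped():
    """10 families, ~300 individuals — big enough for mixture fitting."""
    return st.simulate_pedigree(10, 4, 3.0, seed=7)


@pytest.fixture(scope="session")
def mimic_cohort(mid_ped):
    """Study-like cohort on the mid-size pedigree, preprocessed."""
    ph, truth = st.simulate_phenotypes(
        mid_ped, None, st.reference_scenario(), seed=21
    )
    ph_f, report = st.filter_individuals(st.adjust_medication(ph))
    return {"ped": mid_ped, "ph_raw": ph, "ph": ph_f, "truth": truth,
            "report": report}


def make_phenotypes(rows):
    """Build a LongitudinalPhenotypes from (iid, visit, age, sbp, med) rows."""
    tab = pd.DataFrame(
        rows, columns=["individual_id", "visit", "age", "sbp", "med_use"]
    )
    tab["family_id"] = "F1"
    tab["sex"] = "female"
    tab["smoking"] = False
    return LongitudinalPhenotypes(tab)


@pytest.fixture(scope="session")
def tiny_cohort(small_ped):
    ph, _ = st.simulate_phenotypes(
        small_ped, None, st.reference_scenario(), seed=77
    )
    return ph


@pytest.fixture
def hand_cohort():
    """Hand-built 4-individual cohort with exactly known filter outcomes."""
    rows = [
        ("a", 1, 40.0, 120.0, False), ("a", 2, 45.0, 125.0, False),
        ("b", 1, 50.0, 150.0, True),
        ("c", 1, 40.0, 130.0, False), ("c", 2, 44.0, 132.0, False),
        ("c", 3, 49.0, 128.0, False),
        ("d", 1, 42.0, 118.0, False), ("d", 2, 47.0, 122.0, False),
    ]
    return make_phenotypes(rows)
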