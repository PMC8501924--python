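"""Shared fixtures: tiny hand-built trials and a published-table replica."""

import numpy as np
import pandas as pd
import pytest

from jointsafety import TrialData
from jointsafety.simulate import SimulationParams, simulate_trial


def make_subjects(rows):
    """rows: list of (subject_id, arm, age, primigravid, trimester, T)."""
    return pd.DataFrame(rows, columns=["subject_id", "arm", "maternal_age",
                                       "primigravid", "trimester",
                                       "followup_days"])


def make_trial(subjects=None, labs=None, aes=None, conmeds=None) -> TrialData:
    if subjects is None:
        subjects = make_subjects([("A", "AL", 20.0, True, "third", 63.0),
                                  ("B", "ASAQ", 25.0, False, "second", 63.0)])
    empty_labs = pd.DataFrame(columns=["subject_id", "analyte", "day",
                                       "concentration", "log_value"])
    empty_aes = pd.DataFrame(columns=["subject_id", "day", "relatedness"])
    empty_cms = pd.DataFrame(columns=["subject_id", "day", "medication"])
    return TrialData(subjects=subjects,
                     labs=labs if labs is not None else empty_labs,
                     aes=aes if aes is not None else empty_aes,
                     conmeds=conmeds if conmeds is not None else empty_cms)


@pytest.fixture
def two_subject_trial() -> TrialData:
    labs = pd.DataFrame({
        "subject_id": ["A", "B"],
        "analyte": ["alt", "bilirubin"],
        "day": [0.0, 7.0],
        "concentration": [16.5, 10.0],
    })
    aes = pd.DataFrame({"subject_id": ["A", "A", "A"],
                        "day": [1, 5, 9],
                        "relatedness": ["possibly", "unlikely", "probably"]})
    conmeds = pd.DataFrame({"subject_id": ["A", "A", "A"],
                            "day": [1, 2, 3],
                            "medication": ["paracetamol", "paracetamol",
                                           "iron"]})
    return make_trial(labs=labs, aes=aes, conmeds=conmeds)


@pytest.fixture(scope="session")
def small_sim_trial():
    """A 40-subject synthetic trial under the default generative settings."""
    sp = SimulationParams(n_subjects=40, seed=101)
    return simulate_trial(sp)


# ---------------------------------------------------------------------------
# a synthetic replica of the published summary-table margins (three arms of
# 290 women; AE totals 475/569/468 with 36/34/38 judged definitely-not;
# 187/205/172 women with at least one AE; conmed totals 1229/1033/1042 with
# 287 users per arm; 3304 conmed reports over 863 distinct patients)

_ARM_SPECS = {
    "AL": dict(n=290, aes=475, defnot=36, unlikely=413, with_ae=187,
               conmeds=1229, with_cm=287),
    "ASAQ": dict(n=290, aes=569, defnot=34, unlikely=443, with_ae=205,
                 conmeds=1033, with_cm=287),
    "DHAPQ": dict(n=290, aes=468, defnot=38, unlikely=404, with_ae=172,
                  conmeds=1042, with_cm=287),
}


def _table_margin_frames():
    sub_rows, ae_rows, cm_rows = [], [], []
    for arm, spec in _ARM_SPECS.items():
        ids = [f"{arm}{i:03d}" for i in range(spec["n"])]
        for sid in ids:
            sub_rows.append((sid, arm, 20.0, False, "second", 63.0))
        # one AE per "affected" woman, remainder piled on the first subject
        carriers = ids[:spec["with_ae"]] + \
            [ids[0]] * (spec["aes"] - spec["with_ae"])
        relatedness = (["definitely_not"] * spec["defnot"]
                       + ["unlikely"] * spec["unlikely"])
        relatedness += ["possibly"] * (spec["aes"] - len(relatedness))
        for sid, rel in zip(carriers, relatedness):
            ae_rows.append((sid, 1, rel))
        users = ids[:spec["with_cm"]] + \
            [ids[0]] * (spec["conmeds"] - spec["with_cm"])
        for sid in users:
            cm_rows.append((sid, 1, "other"))
    subjects = make_subjects(sub_rows)
    aes = pd.DataFrame(ae_rows, columns=["subject_id", "day", "relatedness"])
    conmeds = pd.DataFrame(cm_rows,
                           columns=["subject_id", "day", "medication"])
    return subjects, aes, conmeds


@pytest.fixture(scope="session")
def table_margin_trial() -> TrialData:
    subjects, aes, conmeds = _table_margin_frames()
    return make_trial(subjects=subjects, aes=aes, conmeds=conmeds)


@pytest.fixture(scope="session")
def conmed_listing_replica() -> pd.DataFrame:
    """3304 conmed reports over 863 patients with the published name margins:
    iron 869 reports / 856 patients, albendazole 353/353, amoxicillin
    220/192, the rest lumped as 'other'."""
    pats = [f"P{i:03d}" for i in range(863)]
    rows = []
    iron = pats[:856] + [pats[0]] * (869 - 856)
    rows += [(p, "iron supplement") for p in iron]
    rows += [(p, "albendazole") for p in pats[:353]]
    amox = pats[:192] + [pats[0]] * (220 - 192)
    rows += [(p, "amoxicillin") for p in amox]
    n_other = 3304 - len(rows)
    rows += [(pats[i % 863], "other") for i in range(n_other)]
    out = pd.DataFrame(rows, columns=["subject_id", "medication"])
    out["day"] = 1
    return out
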