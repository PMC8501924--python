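"""Trial safety data: containers, readers, filtering and descriptive summaries.

The data model mirrors the long-format listings a safety statistician receives
from data management: a subject table (arm, baseline covariates, follow-up
time), a laboratory table (analyte, visit day, concentration), an adverse-event
(AE) listing with a drug-relatedness judgement, and a concomitant-medication
(conmed) listing.  Laboratory concentrations are analysed on the natural-log
scale and are log-transformed on load.  AEs judged *definitely not related* to
the study drug are excluded before any modelling; per-subject cumulative AE and
conmed counts over each subject's own follow-up are the count outcomes.
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

ARMS = ("AL", "ASAQ", "DHAPQ")
TRIMESTERS = ("second", "third")
ANALYTES = ("alt", "bilirubin")
RELATEDNESS_LEVELS = ("definitely_not", "unlikely", "possibly", "probably")

SUBJECT_COLUMNS = ["subject_id", "arm", "maternal_age", "primigravid",
                   "trimester", "followup_days"]
LAB_COLUMNS = ["subject_id", "analyte", "day", "concentration"]
AE_COLUMNS = ["subject_id", "day", "relatedness"]
CONMED_COLUMNS = ["subject_id", "day", "medication"]


class TrialDataError(ValueError):
    """Raised for schema, label or cross-reference violations in input tables."""


def _require_columns(df: pd.DataFrame, cols: Iterable[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TrialDataError(f"{table} table is missing columns {missing}")


def _check_labels(series: pd.Series, allowed: tuple, table: str, col: str) -> None:
    bad = ~series.isin(allowed)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise TrialDataError(
            f"{table} row {row}: unknown {col} label {series.iloc[row]!r}; "
            f"allowed: {allowed}")


@dataclass
class TrialData:
    """Cross-referenced container for the four safety listings.

    ``subjects``, ``labs``, ``aes`` and ``conmeds`` are pandas DataFrames with
    the canonical column sets; ``labs`` carries a derived ``log_value`` column.
    """

    subjects: pd.DataFrame
    labs: pd.DataFrame
    aes: pd.DataFrame
    conmeds: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def validate(self) -> None:
        _require_columns(self.subjects, SUBJECT_COLUMNS, "subject")
        _require_columns(self.labs, LAB_COLUMNS, "lab")
        _require_columns(self.aes, AE_COLUMNS, "AE")
        _require_columns(self.conmeds, CONMED_COLUMNS, "conmed")

        subs = self.subjects
        if subs["subject_id"].duplicated().any():
            dup = subs.loc[subs["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise TrialDataError(f"duplicate subject_id {dup!r}")
        _check_labels(subs["arm"], ARMS, "subject", "arm")
        _check_labels(subs["trimester"], TRIMESTERS, "subject", "trimester")
        bad = subs["followup_days"] <= 0
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TrialDataError(
                f"subject row {row} (id {subs['subject_id'].iloc[row]!r}): "
                "followup_days must be strictly positive (Poisson exposure)")

        _check_labels(self.aes["relatedness"], RELATEDNESS_LEVELS, "AE",
                      "relatedness")
        _check_labels(self.labs["analyte"], ANALYTES, "lab", "analyte")
        bad = self.labs["concentration"] <= 0
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TrialDataError(
                f"lab row {row} (subject {self.labs['subject_id'].iloc[row]!r}): "
                "non-positive concentration; log transform undefined")
        if "log_value" not in self.labs.columns:
            self.labs = self.labs.assign(
                log_value=np.log(self.labs["concentration"].astype(float)))
        dup = self.labs.duplicated(subset=["subject_id", "analyte", "day"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            raise TrialDataError(
                f"lab row {row}: duplicate (subject_id, analyte, day) key")

        ids = set(subs["subject_id"])
        for name, df in (("lab", self.labs), ("AE", self.aes),
                         ("conmed", self.conmeds)):
            orphan = ~df["subject_id"].isin(ids)
            if orphan.any():
                row = int(np.flatnonzero(orphan.to_numpy())[0])
                raise TrialDataError(
                    f"{name} row {row}: subject_id "
                    f"{df['subject_id'].iloc[row]!r} absent from subject table")

    def subject_order(self) -> pd.Index:
        """Canonical (sorted) subject order used to key integration draws."""
        return pd.Index(sorted(self.subjects["subject_id"]))


def load_trial_data(subject_path, lab_path, ae_path, conmed_path) -> TrialData:
    """Read the four comma-separated listings and return a validated TrialData.

    Concentrations are log-transformed on load; medication names are
    lower-cased and whitespace-trimmed.
    """
    subjects = pd.read_csv(subject_path)
    labs = pd.read_csv(lab_path)
    aes = pd.read_csv(ae_path)
    conmeds = pd.read_csv(conmed_path)
    if "primigravid" in subjects.columns:
        subjects["primigravid"] = subjects["primigravid"].astype(bool)
    if len(conmeds):
        conmeds["medication"] = (conmeds["medication"].astype(str)
                                 .str.strip().str.lower())
    return TrialData(subjects=subjects, labs=labs, aes=aes, conmeds=conmeds)


def exclude_unrelated_aes(ae_records: pd.DataFrame) -> pd.DataFrame:
    """Drop AEs judged definitely not related to the study drug.

    Unlikely/possibly/probably related events are all retained.  Returns a new
    frame; the input is untouched.  Idempotent.
    """
    keep = ae_records["relatedness"] != "definitely_not"
    return ae_records.loc[keep].reset_index(drop=True)


def aggregate_counts(trial_data: TrialData,
                     medication_filter: Optional[str] = None,
                     filter_aes: bool = True) -> pd.DataFrame:
    """Per-subject cumulative AE and conmed counts with exposure.

    Every subject gets one ``ae`` and one ``conmed`` row (zeros included); the
    exposure is the subject's own follow-up in days.  ``medication_filter``
    restricts the conmed count to one (case-normalized) medication name, as in
    the paracetamol-only sensitivity analysis.
    """
    aes = exclude_unrelated_aes(trial_data.aes) if filter_aes else trial_data.aes
    conmeds = trial_data.conmeds
    if medication_filter is not None:
        name = medication_filter.strip().lower()
        conmeds = conmeds[conmeds["medication"] == name]
        if len(conmeds) == 0:
            warnings.warn(
                f"medication filter {medication_filter!r} matched no record; "
                "all conmed counts are zero", UserWarning, stacklevel=2)

    ids = trial_data.subjects["subject_id"]
    ae_counts = aes.groupby("subject_id").size().reindex(ids, fill_value=0)
    cm_counts = conmeds.groupby("subject_id").size().reindex(ids, fill_value=0)
    exposure = trial_data.subjects.set_index("subject_id")["followup_days"]

    rows = []
    for outcome, counts in (("ae", ae_counts), ("conmed", cm_counts)):
        rows.append(pd.DataFrame({
            "subject_id": ids.to_numpy(),
            "outcome": outcome,
            "count": counts.to_numpy().astype(int),
            "exposure_days": exposure.reindex(ids).to_numpy(),
        }))
    return pd.concat(rows, ignore_index=True)


def round_half_up_pct(numerator: float, denominator: float) -> float:
    """Percentage rounded half-up to 1 decimal (870/870 -> 100.0)."""
    if denominator == 0:
        return 0.0
    pct = decimal.Decimal(numerator) / decimal.Decimal(denominator) * 100
    return float(pct.quantize(decimal.Decimal("0.1"),
                              rounding=decimal.ROUND_HALF_UP))


def _median_iqr(values: np.ndarray) -> tuple:
    if len(values) == 0:
        return (np.nan, np.nan, np.nan)
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return (float(med), float(q1), float(q3))


def safety_summary(trial_data: TrialData) -> pd.DataFrame:
    """Per-arm and overall AE occurrence and conmed use summary.

    One row per arm plus an ``overall`` row whose totals are exact sums of the
    arm rows.  AE totals and the relatedness breakdown are computed on the
    unfiltered listing (the relatedness cells are the point of the table);
    the ≥1-AE indicator also uses the unfiltered listing.
    """
    subs = trial_data.subjects
    aes = trial_data.aes
    conmeds = trial_data.conmeds
    arm_of = subs.set_index("subject_id")["arm"]

    rows = {}
    for arm in list(ARMS) + ["overall"]:
        if arm == "overall":
            sub_ids = subs["subject_id"]
        else:
            sub_ids = subs.loc[subs["arm"] == arm, "subject_id"]
        n = len(sub_ids)
        arm_aes = aes[aes["subject_id"].isin(set(sub_ids))]
        arm_cms = conmeds[conmeds["subject_id"].isin(set(sub_ids))]
        ae_per_subj = arm_aes.groupby("subject_id").size()
        cm_per_subj = arm_cms.groupby("subject_id").size().reindex(
            sub_ids, fill_value=0)
        n_with_ae = int((ae_per_subj > 0).sum())
        n_with_cm = int((cm_per_subj > 0).sum())
        med, q1, q3 = _median_iqr(cm_per_subj.to_numpy())
        row = {
            "n_subjects": n,
            "total_aes": len(arm_aes),
            "n_with_ae": n_with_ae,
            "pct_with_ae": round_half_up_pct(n_with_ae, n),
            "total_conmeds": len(arm_cms),
            "median_conmeds": med,
            "conmeds_q1": q1,
            "conmeds_q3": q3,
            "n_with_conmed": n_with_cm,
            "pct_with_conmed": round_half_up_pct(n_with_cm, n),
        }
        for level in RELATEDNESS_LEVELS:
            row[f"aes_{level}"] = int((arm_aes["relatedness"] == level).sum())
        rows[arm] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "arm"
    return out


def baseline_summary(trial_data: TrialData) -> pd.DataFrame:
    """Baseline characteristics by arm and overall.

    Median (IQR) for maternal age, n (%) for primigravidae and trimester at
    enrolment.  With a single subject the IQR degenerates to the point value
    and the row is flagged ``degenerate``.
    """
    subs = trial_data.subjects
    rows = {}
    for arm in list(ARMS) + ["overall"]:
        block = subs if arm == "overall" else subs[subs["arm"] == arm]
        n = len(block)
        med, q1, q3 = _median_iqr(block["maternal_age"].to_numpy())
        n_primi = int(block["primigravid"].sum())
        n_second = int((block["trimester"] == "second").sum())
        rows[arm] = {
            "n_subjects": n,
            "age_median": med, "age_q1": q1, "age_q3": q3,
            "primigravid_n": n_primi,
            "primigravid_pct": round_half_up_pct(n_primi, n),
            "second_trimester_n": n_second,
            "second_trimester_pct": round_half_up_pct(n_second, n),
            "third_trimester_n": n - n_second,
            "third_trimester_pct": round_half_up_pct(n - n_second, n),
            "degenerate": n < 2,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "arm"
    return out


def conmed_frequency_table(conmed_records: pd.DataFrame) -> pd.DataFrame:
    """Per-medication report and patient frequencies.

    ``pct_reports`` is out of all reports; ``pct_patients`` is out of patients
    reporting any conmed.  A medication is flagged ``frequent`` when it makes
    up at least 10% of all reports.  Sorted by report count, descending.
    """
    total_reports = len(conmed_records)
    total_patients = conmed_records["subject_id"].nunique()
    grouped = conmed_records.groupby("medication")
    out = pd.DataFrame({
        "n_reports": grouped.size(),
        "n_patients": grouped["subject_id"].nunique(),
    })
    out["pct_reports"] = [round_half_up_pct(c, total_reports)
                          for c in out["n_reports"]]
    out["pct_patients"] = [round_half_up_pct(c, total_patients)
                           for c in out["n_patients"]]
    out["frequent"] = out["n_reports"] >= 0.10 * total_reports
    out = out.sort_values("n_reports", ascending=False)
    out.index.name = "medication"
    return out.reset_index()[["medication", "n_reports", "pct_reports",
                              "n_patients", "pct_patients", "frequent"]]


def lab_profile_export(trial_data: TrialData) -> pd.DataFrame:
    """Tidy per-(analyte, arm, day) box-plot data on the log scale.

    Five-number summary (quartiles plus Tukey whisker bounds clipped to the
    observed range) for external plotting; cells with no measurements are
    omitted.
    """
    labs = trial_data.labs.merge(
        trial_data.subjects[["subject_id", "arm"]], on="subject_id")
    records = []
    for (analyte, arm, day), grp in labs.groupby(["analyte", "arm", "day"]):
        v = grp["log_value"].to_numpy()
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo = float(v[v >= q1 - 1.5 * iqr].min())
        hi = float(v[v <= q3 + 1.5 * iqr].max())
        records.append({"analyte": analyte, "arm": arm, "day": day,
                        "whisker_low": lo, "q1": float(q1),
                        "median": float(med), "q3": float(q3),
                        "whisker_high": hi, "n": len(v)})
    return pd.DataFrame.from_records(
        records, columns=["analyte", "arm", "day", "whisker_low", "q1",
                          "median", "q3", "whisker_high", "n"])
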