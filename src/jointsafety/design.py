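"""Restricted cubic spline basis and fixed-effect design construction.

The longitudinal sub-models use a restricted (natural) cubic spline in visit
day so the lab trajectories can bend while remaining linear beyond the
boundary knots.  With K knots the basis has K-1 columns (here 4 knots -> 3
degrees of freedom): the day itself plus K-2 restricted cubic terms in the
truncated-power form of Harrell, normalized by the squared boundary-knot span
so all columns are on comparable scales.

Column orders are frozen; every coefficient vector in the package aligns with
these names.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: default knots on the lab visit grid {0, 7, 14, 28, 63}
DEFAULT_KNOTS = (0.0, 7.0, 28.0, 63.0)


@dataclass(frozen=True)
class SplineSpec:
    """Knot set for the restricted cubic spline time trend."""

    knots: tuple = DEFAULT_KNOTS

    def __post_init__(self):
        k = np.asarray(self.knots, dtype=float)
        if len(k) < 3:
            raise ValueError(
                f"restricted cubic spline needs >= 3 knots, got {len(k)}; "
                "a 2-knot request is degenerate (pure linear), refused")
        if not np.all(np.diff(k) > 0):
            raise ValueError("knots must be strictly increasing")

    @property
    def df(self) -> int:
        return len(self.knots) - 1


def rcs_basis(day, spec: SplineSpec = SplineSpec()) -> np.ndarray:
    """Evaluate the restricted cubic spline basis at ``day``.

    Returns an array of shape ``(df,)`` for scalar input or ``(n, df)`` for a
    vector of days.  The first column is the day itself; the remaining
    columns are cubic in the interior and exactly linear outside the boundary
    knots, with continuous second derivatives at every knot.
    """
    x = np.asarray(day, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite day passed to rcs_basis")
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    k = np.asarray(spec.knots, dtype=float)
    K = len(k)
    norm = (k[-1] - k[0]) ** 2

    def cube(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(K - 2):
        term = (cube(x - k[j])
                - cube(x - k[-2]) * (k[-1] - k[j]) / (k[-1] - k[-2])
                + cube(x - k[-1]) * (k[-2] - k[j]) / (k[-1] - k[-2]))
        cols.append(term / norm)
    out = np.column_stack(cols)
    return out[0] if scalar else out


def longitudinal_columns(spec: SplineSpec = SplineSpec()) -> list:
    """Frozen column order of the longitudinal design."""
    return (["const"] + [f"rcs{i + 1}" for i in range(spec.df)]
            + ["asaq", "dhapq", "maternal_age", "second_trimester"])


#: frozen column order of the joint-model count sub-model design
COUNT_COLUMNS = ["const", "asaq", "dhapq", "maternal_age", "second_trimester"]
#: frozen column order of the conventional offset-Poisson comparator design
COUNT_COLUMNS_M1 = ["const", "asaq", "dhapq", "maternal_age", "primigravid",
                    "second_trimester"]


def _covariate_tail(subject) -> list:
    return [1.0 if subject.arm == "ASAQ" else 0.0,
            1.0 if subject.arm == "DHAPQ" else 0.0,
            float(subject.maternal_age),
            1.0 if subject.trimester == "second" else 0.0]


def build_longitudinal_design(subject, day,
                              spec: SplineSpec = SplineSpec()) -> np.ndarray:
    """Fixed-effect design row for a lab measurement at ``day``.

    Order: intercept, spline terms, ASAQ and DHAPQ indicators, maternal age
    (years, untransformed), second-trimester indicator.  AL and third
    trimester are the reference levels.
    """
    if day > subject.followup_days:
        raise ValueError(
            f"day {day} exceeds follow-up {subject.followup_days} for "
            f"subject {subject.subject_id!r}")
    return np.concatenate(([1.0], rcs_basis(float(day), spec),
                           _covariate_tail(subject)))


def build_count_design(subject, include_gravidity: bool = False) -> np.ndarray:
    """Fixed-effect design row for the count sub-models.

    The conventional comparator (``include_gravidity=True``) additionally
    carries the primigravid indicator; the joint-model count sub-models do
    not.
    """
    tail = _covariate_tail(subject)
    if include_gravidity:
        return np.array([1.0, tail[0], tail[1], tail[2],
                         1.0 if subject.primigravid else 0.0, tail[3]])
    return np.array([1.0] + tail)


def longitudinal_design_matrix(subjects_indexed, subject_ids, days,
                               spec: SplineSpec = SplineSpec()) -> np.ndarray:
    """Vectorized longitudinal design for aligned id/day arrays."""
    days = np.asarray(days, dtype=float)
    spl = rcs_basis(days, spec) if len(days) else np.zeros((0, spec.df))
    sub = subjects_indexed.loc[list(subject_ids)]
    tail = np.column_stack([
        (sub["arm"] == "ASAQ").to_numpy(float),
        (sub["arm"] == "DHAPQ").to_numpy(float),
        sub["maternal_age"].to_numpy(float),
        (sub["trimester"] == "second").to_numpy(float),
    ])
    return np.column_stack([np.ones(len(days)), spl, tail])


def count_design_matrix(subjects: "pd.DataFrame",
                        include_gravidity: bool = False) -> np.ndarray:
    """Vectorized count design (one row per subject, given row order)."""
    cols = [np.ones(len(subjects)),
            (subjects["arm"] == "ASAQ").to_numpy(float),
            (subjects["arm"] == "DHAPQ").to_numpy(float),
            subjects["maternal_age"].to_numpy(float)]
    if include_gravidity:
        cols.append(subjects["primigravid"].to_numpy(float))
    cols.append((subjects["trimester"] == "second").to_numpy(float))
    return np.column_stack(cols)
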