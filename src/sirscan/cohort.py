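"""Eligibility, BMI cleaning and person-period expansion.

The discrete survival model consumes one *pseudo-observation* per subject per
attended follow-up round (rounds 2 and 3): the diagnosis indicator y_jt, the
elapsed time d_jt since the most recent prior examination, and the covariates
evaluated at that round. A subject stops contributing after a first
diagnosis. BMI values outside [5, 50] kg/m^2 are treated as database
recording errors and replaced from another attended round where possible.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import InvalidRecordError

__all__ = [
    "BMI_VALID_RANGE",
    "CleaningReport",
    "clean_bmi",
    "build_pseudo_observations",
    "subgroup_sizes",
]

BMI_VALID_RANGE = (5.0, 50.0)


@dataclass
class CleaningReport:
    """Counts from the BMI-cleaning pass."""

    n_subjects_in: int
    n_records_replaced: int
    n_subjects_replaced: int
    n_subjects_excluded: int
    n_subjects_out: int

    def to_dict(self) -> dict:
        return asdict(self)


def clean_bmi(cohort: pd.DataFrame) -> tuple[pd.DataFrame, CleaningReport]:
    """Replace out-of-range BMI values from another attended round.

    A BMI < 5 or > 50 kg/m^2 is a recording error: it is replaced by the
    subject's nearest-in-round in-range BMI from a different attended round
    (ties broken toward the earlier round). Subjects with no in-range BMI in
    any attended round are excluded entirely.
    """
    lo, hi = BMI_VALID_RANGE
    out = cohort.sort_values(["subject_id", "round"], ignore_index=True).copy()
    bmi = out["bmi"].to_numpy(dtype=float)
    ok = np.isfinite(bmi) & (bmi >= lo) & (bmi <= hi)
    n_subjects_in = out["subject_id"].nunique()

    bad_idx = np.flatnonzero(~ok)
    n_replaced = 0
    subjects_replaced: set[int] = set()
    excluded: set[int] = set()
    if bad_idx.size:
        rounds = out["round"].to_numpy()
        subj = out["subject_id"].to_numpy()
        # index of in-range records per subject
        good_by_subject: dict[int, list[int]] = {}
        for i in np.flatnonzero(ok):
            good_by_subject.setdefault(subj[i], []).append(i)
        for i in bad_idx:
            sources = good_by_subject.get(subj[i], [])
            if not sources:
                excluded.add(int(subj[i]))
                continue
            nearest = min(sources, key=lambda g: (abs(rounds[g] - rounds[i]),
                                                  rounds[g]))
            bmi[i] = bmi[nearest]
            n_replaced += 1
            subjects_replaced.add(int(subj[i]))
    out["bmi"] = bmi
    if excluded:
        out = out[~out["subject_id"].isin(excluded)].reset_index(drop=True)
    report = CleaningReport(
        n_subjects_in=n_subjects_in,
        n_records_replaced=n_replaced,
        n_subjects_replaced=len(subjects_replaced),
        n_subjects_excluded=len(excluded),
        n_subjects_out=out["subject_id"].nunique(),
    )
    return out, report


def build_pseudo_observations(cohort: pd.DataFrame) -> pd.DataFrame:
    """Expand an eligible cohort into the person-period table.

    Eligibility (attended round 1, undiagnosed there) is assumed already
    applied; every subject's round-1 row anchors the first interval. Returns
    one record per subject per attended follow-up round, stopping after the
    first diagnosis, with columns ``subject_id, region_id, round, y, d,
    sex, log_age, log_bmi, round3`` — d computed from ``exam_date`` columns
    when present (day counts / 365.25), else taken from ``interval_years``.
    """
    df = cohort.sort_values(["subject_id", "round"], ignore_index=True).copy()

    if "exam_date" in df.columns and df["exam_date"].notna().all():
        dates = pd.to_datetime(df["exam_date"])
        df["interval_years"] = (
            dates.groupby(df["subject_id"]).diff().dt.days / 365.25
        )

    fu = df[df["round"] >= 2].copy()
    d = fu["interval_years"].to_numpy(dtype=float)
    bad = ~np.isfinite(d) | (d <= 0)
    if bad.any():
        subjects = sorted(set(fu.loc[bad, "subject_id"].astype(int)))
        raise InvalidRecordError(
            f"nonpositive or missing interval for subject(s) {subjects[:10]}"
        )

    # censor after first diagnosis: keep a follow-up record only if no
    # earlier follow-up round of the same subject was already a case
    fu = fu.sort_values(["subject_id", "round"])
    prior_cases = fu.groupby("subject_id")["diagnosed"].cumsum() - fu["diagnosed"]
    fu = fu[prior_cases == 0]

    dup = fu.duplicated(subset=["subject_id", "round"])
    if dup.any():
        raise InvalidRecordError(
            "duplicate subject-round records: "
            f"{fu.loc[dup, 'subject_id'].tolist()[:10]}"
        )

    return pd.DataFrame(
        {
            "subject_id": fu["subject_id"].to_numpy(),
            "region_id": fu["region_id"].to_numpy(),
            "round": fu["round"].to_numpy(),
            "y": fu["diagnosed"].to_numpy(dtype=int),
            "d": fu["interval_years"].to_numpy(dtype=float),
            "sex": fu["sex"].to_numpy(dtype=float),
            "log_age": np.log(fu["age_years"].to_numpy(dtype=float)),
            "log_bmi": np.log(fu["bmi"].to_numpy(dtype=float)),
            "round3": (fu["round"] == 3).to_numpy(dtype=float),
        }
    ).reset_index(drop=True)


def subgroup_sizes(cohort: pd.DataFrame) -> dict[str, int]:
    """Subject counts of the follow-up patterns D12, D23, D13.

    D12 = attended rounds 1 and 2; D23 = attended rounds 2 and 3 (a subset
    of the D12 attendees); D13 = attended rounds 1 and 3 but not round 2.
    The analysed cohort is |D12| + |D13|.
    """
    attended = cohort.groupby("subject_id")["round"].agg(frozenset)
    has2 = attended.apply(lambda s: 2 in s)
    has3 = attended.apply(lambda s: 3 in s)
    return {
        "D12": int(has2.sum()),
        "D23": int((has2 & has3).sum()),
        "D13": int((~has2 & has3).sum()),
        "analysed": int((has2 | has3).sum()),
    }
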