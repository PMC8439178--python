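"""Three-level occupation classification from daily care reports.

A day is *clinical* when the participant reported exposure to patient areas
(with or without confirmed or suspected COVID-19 patients); days at work
without patient care, remote-work days, and non-working days are
*nonclinical*.  A period is clinical when it holds at least one clinical
day.  Over the whole study, a participant with at least one clinical period
is a clinical trainee if their enrollment role is resident or fellow and a
clinical nontrainee otherwise; participants who never reported patient care
are staff regardless of role.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "CARE_TYPES",
    "CLINICAL_CARE_TYPES",
    "ROLES",
    "TRAINEE_ROLES",
    "classify_daily",
    "classify_period",
    "classify_participant",
    "classify_periods_table",
    "classify_participants_table",
]

#: daily care-type categories collected by the daily survey
CARE_TYPES = frozenset(
    {"covid_facing", "noncovid_facing", "no_patient_care", "remote", "not_working"}
)

#: care types that make a day clinical (patient-area exposure)
CLINICAL_CARE_TYPES = frozenset({"covid_facing", "noncovid_facing"})

ROLES = frozenset({"resident", "fellow", "attending", "nurse", "staff_other"})
TRAINEE_ROLES = frozenset({"resident", "fellow"})


def classify_daily(care_type):
    """Classify one daily care report as ``"clinical"`` or ``"nonclinical"``."""
    if care_type not in CARE_TYPES:
        raise ValueError(f"unknown daily care type: {care_type!r}")
    return "clinical" if care_type in CLINICAL_CARE_TYPES else "nonclinical"


def classify_period(daily_classes):
    """Period class from its daily classes: clinical iff >= 1 clinical day.

    An empty period (no daily responses) is nonclinical, since the rule
    counts reported clinical days only.
    """
    clinical = False
    for c in daily_classes:
        if c not in ("clinical", "nonclinical"):
            raise ValueError(f"unknown daily class: {c!r}")
        clinical = clinical or c == "clinical"
    return "clinical" if clinical else "nonclinical"


def classify_participant(period_classes, role):
    """Study-level class: staff, clinical_nontrainee, or clinical_trainee.

    Participants with no clinical period are staff regardless of role; with
    at least one, role resident/fellow makes them a clinical trainee and any
    other role a clinical nontrainee.
    """
    if role not in ROLES:
        raise ValueError(f"unknown enrollment role: {role!r}")
    has_clinical = any(c == "clinical" for c in period_classes)
    if not has_clinical:
        return "staff"
    return "clinical_trainee" if role in TRAINEE_ROLES else "clinical_nontrainee"


def classify_periods_table(daily, periods_df, participant_col="participant_id",
                           care_col="care_type", date_col="date"):
    """Annotate a period table with each period's occupation class."""
    from .periods import summarize_daily_by_period

    work = daily[[participant_col, date_col]].copy()
    work["is_clinical"] = [
        classify_daily(ct) == "clinical" for ct in daily[care_col]
    ]
    summ = summarize_daily_by_period(work, periods_df,
                                     participant_col=participant_col,
                                     date_col=date_col)
    out = periods_df[[participant_col, "period"]].merge(
        summ[[participant_col, "period", "mean_is_clinical", "n_days_observed"]],
        on=[participant_col, "period"],
        how="left",
    )
    out["occupation_period"] = [
        "clinical" if (pd.notna(m) and m > 0) else "nonclinical"
        for m in out["mean_is_clinical"]
    ]
    return out.drop(columns=["mean_is_clinical", "n_days_observed"])


def classify_participants_table(period_classes_df, baseline,
                                participant_col="participant_id",
                                role_col="role"):
    """Participant-level occupation class from period classes and roles."""
    roles = dict(zip(baseline[participant_col], baseline[role_col]))
    rows = []
    for pid, grp in period_classes_df.groupby(participant_col, sort=True):
        rows.append(
            {
                participant_col: pid,
                "occupation": classify_participant(
                    grp["occupation_period"], roles[pid]
                ),
            }
        )
    # participants with no periods at all are staff by the same rule
    for pid in baseline[participant_col]:
        if pid not in set(period_classes_df[participant_col]):
            rows.append({participant_col: pid, "occupation": "staff"})
    return pd.DataFrame(rows)
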