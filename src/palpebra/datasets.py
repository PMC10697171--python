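"""Bundled tabulations from the angular-translation crossover study.

Three small printed tables from the study report are shipped as plain
records so the tabulation and agreement arithmetic can be recomputed:

* the participant enrollment table (19 rows; one individual enrolled twice,
  two enrollments removed for facial-nerve weakness and one participant for
  communication difficulties, leaving 16 contributing);
* clinician-rated best-fit counts over 17 fitted participant-eyes
  (angular position, lid-magnet polarisation, frame type);
* observed vs expected eyelid-magnet rolling-direction counts per magnet
  type and angle.
"""

from __future__ import annotations

from .stats import ParticipantRecord, RollingCounts

__all__ = [
    "participant_records",
    "best_fit_counts",
    "rolling_direction_counts",
]


def participant_records() -> list:
    """The 19-row participant enrollment table."""
    rows = [
        # id, age, gender, side, severities (mm), cause, duplicate_of, excluded
        ("S01", 28, "M", "right", (3.1,), "CN III palsy, TBI", None, False),
        ("S02", 18, "F", "left", (4.8,), "CN III palsy, brain abscess", None, False),
        ("S03", 78, "F", "right", (0.0,), "stroke, nuclear CN III", None, False),
        ("S04", 23, "M", "right", (), "trauma", None, True),
        ("S05", 41, "F", "left", (6.0,), "CN III palsy, tumor", None, False),
        ("S06", 60, "M", "both", (3.4, 3.8), "OPMD", None, False),
        ("S07", 56, "M", "both", (5.3, 4.5), "OPMD", None, False),
        ("S08", 28, "F", "both", (7.2, 8.5), "CPEO", None, False),
        ("S09", 43, "M", "left", (4.6,), "congenital", None, False),
        ("S10", 71, "F", "left", (0.5,), "sphenoid wing meningioma", None, False),
        ("S11", 58, "M", "both", (6.2, 2.0), "top of basilar stroke, nuclear CN III",
         None, False),
        ("S12", 55, "M", "right", (5.3,), "craniofacial trauma", None, False),
        ("S13", 85, "F", "left", (1.8,), "CN III palsy, presumed CVA", None, False),
        ("S14", 23, "M", "right", (), "trauma", "S04", True),
        ("S15", 6, "F", "both", (), "CN III palsy, TBI", None, True),
        ("S16", 47, "F", "both", (7.6, 6.8), "CPEO", None, False),
        ("S17", 68, "M", "right", (0.0,), "CN III palsy, stroke", None, False),
        ("S18", 55, "F", "both", (5.9,), "CPEO", None, False),
        ("S19", 17, "M", "left", (2.4,), "CN III palsy, midbrain pilocytic astrocytoma",
         None, False),
    ]
    return [
        ParticipantRecord(id=i, age_yr=a, gender=g, side=s, severity_mm=sev,
                          cause=c, duplicate_of=d, excluded=e)
        for i, a, g, s, sev, c, d, e in rows
    ]


def best_fit_counts() -> dict:
    """Clinician-rated best-fit configuration counts (17 participant-eyes)."""
    return {
        "angle": {"0": 4, "30": 3, "60": 1, "90": 4, "180": 5},
        "lid_magnet": {"type1": 5, "type2": 12},
        "frame": {"standard": 7, "custom": 10},
    }


def rolling_direction_counts() -> list:
    """Observed vs expected rolling-direction counts by magnet type and angle."""
    rows = [
        # magnet, angle, observed, expected, direction
        ("type1", 0, 9, 10, "min"),
        ("type1", 30, 4, 7, "min"),
        ("type1", 60, 3, 8, "out"),
        ("type1", 90, 5, 8, "out"),
        ("type1", 180, 6, 8, "out"),
        ("type2", 0, 11, 12, "out"),
        ("type2", 30, 7, 12, "out"),
        ("type2", 60, 3, 11, "min"),
        ("type2", 90, 7, 11, "in"),
        ("type2", 180, 11, 12, "in"),
    ]
    return [
        RollingCounts(magnet_type=m, angle_deg=a, observed=o, expected=e,
                      observed_direction=d, expected_direction=d)
        for m, a, o, e, d in rows
    ]
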