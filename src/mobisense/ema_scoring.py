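"""ICD-10 depression scoring from repeated symptom surveys.

The ICD-10 distinguishes three core symptoms (depressed mood, loss of
interest and enjoyment, increased fatigue) from seven additional symptoms
(reduced concentration, reduced self-esteem, guilt, pessimism about the
future, ideas or acts of self-harm, disturbed sleep, diminished appetite).
A participant is labelled depressed (>= mild) when at least two core and at
least two additional symptoms are present over the assessment window; the
severity grade above that cutoff follows the standard ICD-10 convention
(mild: 2 core + 2-3 additional; moderate: >= 2 core + >= 4 additional;
severe: 3 core + >= 4 additional).

A symptom counts as *present* when it was endorsed in at least 50% of the
survey prompts in which it was administered within the window; symptoms
never administered are *unassessed*.  Burden ratings (1-4) are carried
through but do not enter the classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Mapping

import pandas as pd

CORE_SYMPTOMS = ("depressed_mood", "loss_of_interest", "fatigue")
ADDITIONAL_SYMPTOMS = ("concentration", "self_esteem", "guilt", "pessimism",
                       "self_harm", "sleep", "appetite")
ALL_SYMPTOMS = CORE_SYMPTOMS + ADDITIONAL_SYMPTOMS

PRESENT = "present"
ABSENT = "absent"
UNASSESSED = "unassessed"

#: fraction of administrations in which a symptom must be endorsed to count
#: as present over the window.
PRESENCE_THRESHOLD = 0.5


class Severity(IntEnum):
    subclinical = 0
    mild = 1
    moderate = 2
    severe = 3


@dataclass
class DepressionAssessment:
    participant_id: str
    core_present: frozenset
    additional_present: frozenset
    severity: Severity
    scoreable: bool = True

    @property
    def core_count(self) -> int:
        return len(self.core_present)

    @property
    def additional_count(self) -> int:
        return len(self.additional_present)

    @property
    def label_depressed(self) -> bool:
        return self.severity >= Severity.mild


def aggregate_symptoms(responses: pd.DataFrame) -> dict[str, str]:
    """Window-level symptom presence from repeated prompts.

    ``responses`` needs columns symptom_key and endorsed (one row per item
    administration).  A symptom is present iff endorsed in >= 50% of its
    administrations; never-administered symptoms are unassessed.  Response
    order is irrelevant by construction.
    """
    out = {s: UNASSESSED for s in ALL_SYMPTOMS}
    if responses is None or len(responses) == 0:
        return out
    grp = responses.groupby("symptom_key")["endorsed"]
    frac = grp.mean()
    for s, f in frac.items():
        if s in out:
            out[s] = PRESENT if f >= PRESENCE_THRESHOLD else ABSENT
    return out


def score_icd10(presence_map: Mapping[str, str],
                participant_id: str = "") -> DepressionAssessment:
    """Grade a presence map into the four ICD-10 severity levels.

    Unscoreable input (no assessed core symptom or no assessed additional
    symptom) yields an explicit unscoreable assessment, never a silent
    negative.
    """
    core_assessed = [s for s in CORE_SYMPTOMS
                     if presence_map.get(s, UNASSESSED) != UNASSESSED]
    add_assessed = [s for s in ADDITIONAL_SYMPTOMS
                    if presence_map.get(s, UNASSESSED) != UNASSESSED]
    if not core_assessed or not add_assessed:
        return DepressionAssessment(participant_id, frozenset(), frozenset(),
                                    Severity.subclinical, scoreable=False)
    core = frozenset(s for s in CORE_SYMPTOMS if presence_map.get(s) == PRESENT)
    add = frozenset(s for s in ADDITIONAL_SYMPTOMS if presence_map.get(s) == PRESENT)
    nc, na = len(core), len(add)
    if nc == 3 and na >= 4:
        sev = Severity.severe
    elif nc >= 2 and na >= 4:
        sev = Severity.moderate
    elif nc >= 2 and na >= 2:
        sev = Severity.mild
    else:
        sev = Severity.subclinical
    return DepressionAssessment(participant_id, core, add, sev)


def score_participants(ema: pd.DataFrame) -> pd.DataFrame:
    """Score every participant in an EMA table.

    Returns a frame with participant_id, core_count, additional_count,
    severity (name), label (bool) and scoreable (bool); participants with
    unscoreable windows carry label False and scoreable False, and are
    expected to be filtered out upstream of modelling.
    """
    rows = []
    if len(ema):
        for pid, grp in ema.groupby("participant_id", sort=True):
            a = score_icd10(aggregate_symptoms(grp), participant_id=str(pid))
            rows.append({
                "participant_id": str(pid),
                "core_count": a.core_count,
                "additional_count": a.additional_count,
                "severity": a.severity.name,
                "label": bool(a.label_depressed),
                "scoreable": bool(a.scoreable),
            })
    return pd.DataFrame(rows, columns=["participant_id", "core_count",
                                       "additional_count", "severity",
                                       "label", "scoreable"])
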