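"""Cohort containers shared by the simulator, the statistics layer and I/O.

A :class:`ParticipantRecord` carries one participant's grouping labels,
questionnaire score, worst nausea rating during motion provocation, and the
VOR gains measured before (pre) and after (post) the provocative ride.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import pandas as pd

from .errors import ValidationError

#: Column order of the on-disk cohort table.
COHORT_COLUMNS = [
    "participant_id",
    "susceptible",
    "symptomatic",
    "age",
    "mssq_short",
    "nausea_max",
    "gain_pre",
    "gain_post",
]


@dataclass
class ParticipantRecord:
    """One participant of a pre/post vHIT study.

    Parameters
    ----------
    participant_id:
        Unique identifier.
    susceptible:
        Self-reported motion-sickness susceptibility (answered anything other
        than "never" when asked how often they experience car sickness).
    symptomatic:
        Developed nausea during the provocative ride; must equal
        ``nausea_max > 0``.
    age:
        Age in years.
    mssq_short:
        Motion Sickness Susceptibility Questionnaire (short form) score.
    nausea_max:
        Worst nausea rating on the 11-point (0-10) scale.
    gain_pre, gain_post:
        Pooled VOR gains of the two sessions (dimensionless, ~1 in healthy
        participants).
    """

    participant_id: str
    susceptible: bool
    symptomatic: bool
    age: float
    mssq_short: float
    nausea_max: int
    gain_pre: float
    gain_post: float

    def __post_init__(self) -> None:
        if not (0 <= int(self.nausea_max) <= 10):
            raise ValidationError(
                f"participant {self.participant_id!r}: nausea_max "
                f"{self.nausea_max} outside the 0-10 scale"
            )
        self.nausea_max = int(self.nausea_max)
        if self.symptomatic != (self.nausea_max > 0):
            raise ValidationError(
                f"participant {self.participant_id!r}: symptomatic flag "
                f"{self.symptomatic} inconsistent with nausea_max "
                f"{self.nausea_max} (symptomatic must mean nausea_max > 0)"
            )


@dataclass
class Cohort:
    """An ordered collection of participant records with unique ids."""

    records: list[ParticipantRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.participant_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate participant ids: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ParticipantRecord]:
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with the canonical column order."""
        return pd.DataFrame(
            [
                {c: getattr(r, c) for c in COHORT_COLUMNS}
                for r in self.records
            ],
            columns=COHORT_COLUMNS,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Cohort":
        missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"cohort table missing columns: {missing}")
        records = [
            ParticipantRecord(
                participant_id=str(row.participant_id),
                susceptible=bool(row.susceptible),
                symptomatic=bool(row.symptomatic),
                age=float(row.age),
                mssq_short=float(row.mssq_short),
                nausea_max=int(row.nausea_max),
                gain_pre=float(row.gain_pre),
                gain_post=float(row.gain_post),
            )
            for row in frame.itertuples(index=False)
        ]
        return cls(records)

    def subgroup_counts(self) -> pd.DataFrame:
        """2x2 count table: susceptibility x symptom status."""
        df = self.to_frame()
        return (
            df.groupby(["susceptible", "symptomatic"])
            .size()
            .unstack(fill_value=0)
        )
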