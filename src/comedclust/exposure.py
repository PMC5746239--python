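"""Gestational exposure windows, records, and per-pregnancy profiles.

Medication use in pregnancy is reported on three questionnaires, each
covering a fixed set of gestational-week windows:

* Q1 (answered around gestational week 17): weeks 0-4, 5-8, 9-12, and
  "13 or later";
* Q3 (around week 30): weeks 13-16, 17-20, 21-24, 25-28, and
  "29 or later";
* Q4 (6 months post partum, covering late pregnancy): week 30 until
  birth.

Together these give a canonical axis of exactly ten windows, indexed
0-9 in the order above.  A pregnancy's exposure profile maps each window
to the *set* of ATC codes reported in it; repeated reports of the same
substance in the same window collapse, and a report in Q1's open-ended
"13 or later" window yields to any Q3 report of the same substance
(the Q3 windows resolve the same calendar period at finer grain, so
keeping both would double count).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .atc import ATCCode, parse_atc
from .errors import ATCFormatError, DataError

__all__ = [
    "TimeWindow",
    "ExposureRecord",
    "ExposureProfile",
    "CANONICAL_WINDOWS",
    "N_WINDOWS",
    "PARACETAMOL",
    "QUESTIONNAIRE_WINDOWS",
    "DEFAULT_WINDOW_VOCAB",
    "build_profiles",
    "mean_exposure",
    "window_trajectory",
    "read_exposure_records",
    "write_exposure_records",
    "write_profiles",
    "read_profiles",
]

#: ATC code of the index medication every study-emulating cohort member uses.
PARACETAMOL = "N02BE01"

N_WINDOWS = 10


@dataclass(frozen=True)
class TimeWindow:
    """One canonical reporting window.

    ``gw_range`` holds inclusive gestational-week bounds; an open upper
    bound (``"13 or later"``, ``"week 30 until birth"``) is ``None``.
    """

    index: int
    label: str
    gw_range: tuple[int, Optional[int]]
    source_questionnaire: str


CANONICAL_WINDOWS: tuple[TimeWindow, ...] = (
    TimeWindow(0, "0-4", (0, 4), "Q1"),
    TimeWindow(1, "5-8", (5, 8), "Q1"),
    TimeWindow(2, "9-12", (9, 12), "Q1"),
    TimeWindow(3, "13+", (13, None), "Q1"),
    TimeWindow(4, "13-16", (13, 16), "Q3"),
    TimeWindow(5, "17-20", (17, 20), "Q3"),
    TimeWindow(6, "21-24", (21, 24), "Q3"),
    TimeWindow(7, "25-28", (25, 28), "Q3"),
    TimeWindow(8, "29+", (29, None), "Q3"),
    TimeWindow(9, "30-birth", (30, None), "Q4"),
)

#: Index of Q1's open-ended "13 or later" window, the one that yields to Q3.
Q1_LATE_WINDOW = 3
_Q3_WINDOWS = frozenset(range(4, 9))

QUESTIONNAIRE_WINDOWS: Mapping[str, frozenset[int]] = {
    "Q1": frozenset({0, 1, 2, 3}),
    "Q3": frozenset(range(4, 9)),
    "Q4": frozenset({9}),
}

#: (questionnaire, window label) -> canonical window index, including the
#: long-form labels used on the questionnaires themselves.
DEFAULT_WINDOW_VOCAB: dict[tuple[str, str], int] = {
    (w.source_questionnaire, w.label): w.index for w in CANONICAL_WINDOWS
}
DEFAULT_WINDOW_VOCAB.update(
    {
        ("Q1", "13 or later"): 3,
        ("Q3", "29 or later"): 8,
        ("Q4", "week 30 until birth"): 9,
        ("Q4", "30+"): 9,
    }
)


@dataclass(frozen=True)
class ExposureRecord:
    """One reported medication use: pregnancy x ATC code x window."""

    pregnancy_id: str
    atc: ATCCode
    window_index: int
    questionnaire: str

    def is_consistent(self) -> bool:
        allowed = QUESTIONNAIRE_WINDOWS.get(self.questionnaire)
        return allowed is not None and self.window_index in allowed


@dataclass(frozen=True)
class ExposureProfile:
    """A pregnancy's exposure: one set of ATC code strings per window."""

    pregnancy_id: str
    windows: tuple[frozenset[str], ...] = field(
        default_factory=lambda: tuple(frozenset() for _ in range(N_WINDOWS))
    )

    def __post_init__(self) -> None:
        if len(self.windows) != N_WINDOWS:
            raise DataError(
                f"profile {self.pregnancy_id}: expected {N_WINDOWS} windows, "
                f"got {len(self.windows)}"
            )

    def window_counts(self) -> np.ndarray:
        """Number of distinct medications per window (length-10 vector)."""
        return np.array([len(s) for s in self.windows], dtype=float)

    def mean_exposure(self) -> float:
        """Average number of concomitant medications per window."""
        return float(sum(len(s) for s in self.windows) / N_WINDOWS)

    def all_codes(self) -> frozenset[str]:
        """Union of medications reported in any window."""
        return frozenset().union(*self.windows)

    def uses_paracetamol(self) -> bool:
        return any(PARACETAMOL in s for s in self.windows)


def build_profiles(records: Iterable[ExposureRecord]) -> list[ExposureProfile]:
    """Collapse raw records into one deduplicated profile per pregnancy.

    Within a window, repeated reports of a substance keep a single set
    element.  Across questionnaires, a substance reported both in Q1's
    "13 or later" window and in any Q3 window keeps only the Q3
    report(s).  Output is sorted by ``pregnancy_id``.

    Raises :class:`~comedclust.errors.DataError` listing the offending
    record positions if any record pairs a window with the wrong
    questionnaire.
    """
    records = list(records)
    bad = [
        f"record {i} ({r.pregnancy_id}): window {r.window_index} is not a "
        f"{r.questionnaire} window"
        for i, r in enumerate(records)
        if not r.is_consistent()
    ]
    if bad:
        raise DataError(
            "inconsistent window/questionnaire pairing:\n" + "\n".join(bad)
        )

    per_pregnancy: dict[str, list[set[str]]] = defaultdict(
        lambda: [set() for _ in range(N_WINDOWS)]
    )
    for r in records:
        per_pregnancy[r.pregnancy_id][r.window_index].add(r.atc.code)

    profiles = []
    for pid in sorted(per_pregnancy):
        windows = per_pregnancy[pid]
        q3_codes = set().union(*(windows[w] for w in _Q3_WINDOWS))
        windows[Q1_LATE_WINDOW] -= q3_codes
        profiles.append(
            ExposureProfile(pid, tuple(frozenset(s) for s in windows))
        )
    return profiles


def mean_exposure(profile: ExposureProfile) -> float:
    """Average number of medications per window; see the profile method."""
    return profile.mean_exposure()


def window_trajectory(
    profiles: Sequence[ExposureProfile],
    subset: Optional[Iterable[str]] = None,
) -> np.ndarray:
    """Per-window mean medication count over a set of pregnancies.

    ``subset`` restricts to the given pregnancy ids (default: all).
    """
    if subset is not None:
        wanted = set(subset)
        profiles = [p for p in profiles if p.pregnancy_id in wanted]
        unknown = wanted - {p.pregnancy_id for p in profiles}
        if unknown:
            raise DataError(f"unknown pregnancy ids in subset: {sorted(unknown)}")
    if not profiles:
        raise DataError("window_trajectory requires a nonempty subset")
    return np.mean([p.window_counts() for p in profiles], axis=0)


# ---------------------------------------------------------------------------
# Delimited-text IO
# ---------------------------------------------------------------------------

_RECORD_COLUMNS = ["pregnancy_id", "atc", "questionnaire", "window_label"]


def read_exposure_records(
    path,
    delimiter: str = ",",
    window_vocab: Optional[Mapping[tuple[str, str], int]] = None,
) -> list[ExposureRecord]:
    """Read long-format exposure records.

    Expects a header with columns ``pregnancy_id, atc, questionnaire,
    window_label``; the (questionnaire, label) pair is resolved through
    ``window_vocab`` (default :data:`DEFAULT_WINDOW_VOCAB`).
    """
    vocab = dict(window_vocab) if window_vocab is not None else DEFAULT_WINDOW_VOCAB
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    missing_cols = [c for c in _RECORD_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DataError(f"{path}: missing columns {missing_cols}")
    records, problems = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        q = str(row.questionnaire).strip()
        label = str(row.window_label).strip()
        idx = vocab.get((q, label))
        if idx is None:
            problems.append(f"row {i}: unknown window ({q!r}, {label!r})")
            continue
        try:
            code = parse_atc(row.atc)
        except ATCFormatError as exc:
            problems.append(f"row {i}: {exc}")
            continue
        records.append(ExposureRecord(str(row.pregnancy_id).strip(), code, idx, q))
    if problems:
        raise DataError(f"{path}: invalid records:\n" + "\n".join(problems))
    return records


def write_exposure_records(
    records: Iterable[ExposureRecord], path, delimiter: str = ","
) -> None:
    rows = [
        (
            r.pregnancy_id,
            r.atc.code,
            r.questionnaire,
            CANONICAL_WINDOWS[r.window_index].label,
        )
        for r in records
    ]
    pd.DataFrame(rows, columns=_RECORD_COLUMNS).to_csv(
        path, sep=delimiter, index=False
    )


def write_profiles(
    profiles: Iterable[ExposureProfile], path, delimiter: str = ","
) -> None:
    """Canonical profile table: one row per pregnancy x window with
    semicolon-joined codes (empty field for an empty window)."""
    rows = []
    for p in profiles:
        for w in CANONICAL_WINDOWS:
            rows.append(
                (p.pregnancy_id, w.index, w.label, ";".join(sorted(p.windows[w.index])))
            )
    pd.DataFrame(
        rows, columns=["pregnancy_id", "window_index", "window_label", "codes"]
    ).to_csv(path, sep=delimiter, index=False)


def read_profiles(path, delimiter: str = ",") -> list[ExposureProfile]:
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    per: dict[str, list[frozenset[str]]] = defaultdict(
        lambda: [frozenset() for _ in range(N_WINDOWS)]
    )
    for row in df.itertuples(index=False):
        w = int(row.window_index)
        if not 0 <= w < N_WINDOWS:
            raise DataError(f"{path}: window index {w} out of range 0..9")
        codes = frozenset(
            parse_atc(c).code for c in str(row.codes).split(";") if c.strip()
        )
        per[str(row.pregnancy_id)][w] = codes
    return [ExposureProfile(pid, tuple(per[pid])) for pid in sorted(per)]
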