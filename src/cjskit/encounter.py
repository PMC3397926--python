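"""Encounter histories: representation, I/O, and transformations.

An encounter history is one individual's binary detection vector over
the study's sampling occasions, together with its sex and monitoring
panel.  This module reads and writes MARK-style ``.inp`` files and a
flat CSV dialect, recodes histories for transience removal, annotates
trap-dependence states, and builds the m-array sufficient statistic of
the Cormack-Jolly-Seber likelihood.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
import re

import numpy as np
import pandas as pd

from .design import StudyDesign

__all__ = [
    "EncounterHistory",
    "MArray",
    "TRAP_NONE",
    "TRAP_M1",
    "TRAP_M2",
    "read_inp",
    "write_inp",
    "read_histories_csv",
    "write_histories_csv",
    "read_histories",
    "suppress_first_encounter",
    "build_m_array",
    "split_by_trap_state",
    "detection_matrix",
]

SEXES = ("male", "female", "unknown")

# trap-state codes produced by split_by_trap_state
TRAP_NONE = 0  # before/at first capture, or a gap occasion
TRAP_M1 = 1    # detected at the previous non-gap occasion
TRAP_M2 = 2    # not detected at the previous non-gap occasion


@dataclass
class EncounterHistory:
    """One individual's detections across the study occasions.

    ``detections`` is an int8 0/1 vector aligned to
    ``StudyDesign.occasions``.
    """

    id: str
    sex: str
    panel: str
    detections: np.ndarray

    def __post_init__(self) -> None:
        self.detections = np.asarray(self.detections, dtype=np.int8)
        if self.sex not in SEXES:
            raise ValueError(f"{self.id}: sex must be one of {SEXES}, got {self.sex!r}")

    @property
    def first(self) -> int:
        """0-based index of the first detection."""
        nz = np.flatnonzero(self.detections)
        if nz.size == 0:
            raise ValueError(f"{self.id}: history has no detections")
        return int(nz[0])

    @property
    def last(self) -> int:
        """0-based index of the last detection."""
        return int(np.flatnonzero(self.detections)[-1])

    @property
    def n_detections(self) -> int:
        return int(self.detections.sum())

    def validate(self, design: StudyDesign) -> None:
        if len(self.detections) != design.n_occasions:
            raise ValueError(
                f"{self.id}: history length {len(self.detections)} != "
                f"{design.n_occasions} occasions"
            )
        if not np.isin(self.detections, (0, 1)).all():
            raise ValueError(f"{self.id}: detections must be 0/1")
        if self.detections.sum() == 0:
            raise ValueError(f"{self.id}: history has no detections")
        panel = design.panel(self.panel)
        for j in np.flatnonzero(self.detections):
            year = design.occasions[j]
            if year in design.gap_years:
                raise ValueError(f"{self.id}: detection in gap year {year}")
            if not panel.contains(year):
                raise ValueError(
                    f"{self.id}: detection in {year} outside panel "
                    f"{self.panel!r} range {panel.start}-{panel.end}"
                )

    def copy(self) -> "EncounterHistory":
        return EncounterHistory(self.id, self.sex, self.panel, self.detections.copy())


@dataclass
class MArray:
    """Reduced m-array: the CJS sufficient statistic.

    ``releases[i]`` counts animals released (captured or recaptured) at
    occasion i < K-1; ``m[i, j]`` counts those released at i and next
    re-encountered at j > i; ``never_seen[i]`` is the remainder.
    """

    occasions: tuple[int, ...]
    releases: np.ndarray        # shape (K-1,)
    m: np.ndarray               # shape (K-1, K); only j > i populated

    def __post_init__(self) -> None:
        self.releases = np.asarray(self.releases, dtype=np.int64)
        self.m = np.asarray(self.m, dtype=np.int64)
        k = len(self.occasions)
        if self.releases.shape != (k - 1,) or self.m.shape != (k - 1, k):
            raise ValueError("m-array shape inconsistent with occasions")
        if (self.releases < 0).any() or (self.m < 0).any():
            raise ValueError("negative counts in m-array")
        if (self.never_seen < 0).any():
            raise ValueError("row recaptures exceed releases")

    @property
    def never_seen(self) -> np.ndarray:
        return self.releases - self.m.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.m, index=list(self.occasions[:-1]),
                          columns=list(self.occasions))
        df.insert(0, "released", self.releases)
        df["never_seen"] = self.never_seen
        return df


# ---------------------------------------------------------------------------
# helpers

def detection_matrix(histories: list[EncounterHistory]) -> np.ndarray:
    """Stack detection vectors into an (n, K) int8 matrix."""
    return np.array([h.detections for h in histories], dtype=np.int8)


def _filter(histories, sex=None, panel=None):
    out = histories
    if sex is not None:
        out = [h for h in out if h.sex == sex]
    if panel is not None:
        out = [h for h in out if h.panel == panel]
    return out


# ---------------------------------------------------------------------------
# I/O

_COMMENT_RE = re.compile(r"/\*.*?\*/", re.DOTALL)


def read_inp(path, design: StudyDesign, groups: tuple[str, ...] = ("male", "female"),
             id_prefix: str = "ind") -> list[EncounterHistory]:
    """Read MARK-style ``.inp`` encounter histories.

    Each record is a history string over the study occasions followed by
    one whitespace-separated count column per group, terminated by ';'.
    ``/* ... */`` comments are ignored.  Counts are expanded into
    individual histories; panels are assigned from the first-capture
    year.
    """
    with open(path) as fh:
        text = fh.read()
    text = _COMMENT_RE.sub(" ", text)
    histories: list[EncounterHistory] = []
    counter = 0
    for lineno, record in enumerate(filter(None, (r.strip() for r in text.split(";")))):
        parts = record.split()
        if len(parts) != 1 + len(groups):
            raise ValueError(
                f"record {lineno + 1}: expected history + {len(groups)} "
                f"count column(s), got {len(parts)} fields"
            )
        hist_str = parts[0]
        if len(hist_str) != design.n_occasions:
            raise ValueError(
                f"record {lineno + 1}: history length {len(hist_str)} != "
                f"{design.n_occasions} occasions"
            )
        if set(hist_str) - {"0", "1"}:
            bad = sorted(set(hist_str) - {"0", "1"})
            raise ValueError(f"record {lineno + 1}: illegal characters {bad} in history")
        det = np.array([int(c) for c in hist_str], dtype=np.int8)
        if det.sum() == 0:
            raise ValueError(f"record {lineno + 1}: all-zero history")
        first_year = design.occasions[int(np.flatnonzero(det)[0])]
        panel = design.panel_for_year(first_year).name
        for sex, cnt_s in zip(groups, parts[1:]):
            cnt = int(cnt_s)
            if cnt < 0:
                raise ValueError(f"record {lineno + 1}: negative count")
            for _ in range(cnt):
                counter += 1
                h = EncounterHistory(f"{id_prefix}{counter:06d}", sex, panel, det.copy())
                h.validate(design)
                histories.append(h)
    return histories


def write_inp(path, histories: list[EncounterHistory], design: StudyDesign,
              groups: tuple[str, ...] = ("male", "female")) -> None:
    """Write histories as a MARK-style ``.inp`` with one count column per
    group, aggregating identical (history, sex) records.  Output order is
    deterministic (lexicographic by history string)."""
    counts: Counter = Counter()
    for h in histories:
        if h.sex not in groups:
            raise ValueError(f"{h.id}: sex {h.sex!r} not among groups {groups}")
        counts[("".join(map(str, h.detections)), h.sex)] += 1
    keys = sorted({k[0] for k in counts})
    with open(path, "w") as fh:
        fh.write(f"/* {len(histories)} histories, occasions "
                 f"{design.occasions[0]}-{design.occasions[-1]} */\n")
        for hist_str in keys:
            row = " ".join(str(counts.get((hist_str, g), 0)) for g in groups)
            fh.write(f"{hist_str} {row};\n")


def read_histories_csv(path, design: StudyDesign) -> list[EncounterHistory]:
    """Read the CSV dialect: columns id, sex, panel, then one 0/1 column
    per occasion year."""
    df = pd.read_csv(path, dtype={"id": str, "sex": str, "panel": str})
    year_cols = [str(y) for y in design.occasions]
    missing = [c for c in ("id", "sex", "panel", *year_cols) if c not in df.columns]
    if missing:
        raise ValueError(f"CSV is missing columns: {missing}")
    histories = []
    for _, row in df.iterrows():
        det = row[year_cols].to_numpy(dtype=np.int8)
        h = EncounterHistory(row["id"], row["sex"], row["panel"], det)
        h.validate(design)
        histories.append(h)
    return histories


def write_histories_csv(path, histories: list[EncounterHistory],
                        design: StudyDesign) -> None:
    rows = []
    for h in histories:
        rec = {"id": h.id, "sex": h.sex, "panel": h.panel}
        rec.update({str(y): int(d) for y, d in zip(design.occasions, h.detections)})
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_histories(path, design: StudyDesign, **kwargs) -> list[EncounterHistory]:
    """Dispatch on extension: ``.inp`` → MARK dialect, else CSV."""
    if str(path).endswith(".inp"):
        return read_inp(path, design, **kwargs)
    return read_histories_csv(path, design)


# ---------------------------------------------------------------------------
# transformations

def suppress_first_encounter(
    histories: list[EncounterHistory],
) -> tuple[list[EncounterHistory], int]:
    """Recode each history's first detection to 0, so the record starts
    at its second detection; single-detection records are dropped.

    This is the standard removal of transients: animals passing through
    are only ever seen once, so conditioning every history on its second
    capture deletes them from the likelihood.  Returns the reduced
    histories and the number dropped.
    """
    reduced: list[EncounterHistory] = []
    n_dropped = 0
    for h in histories:
        if h.n_detections <= 1:
            n_dropped += 1
            continue
        det = h.detections.copy()
        det[h.first] = 0
        reduced.append(EncounterHistory(h.id, h.sex, h.panel, det))
    return reduced, n_dropped


def build_m_array(histories: list[EncounterHistory], design: StudyDesign,
                  sex: str | None = None, panel: str | None = None) -> MArray:
    """Build the reduced m-array over an optional sex/panel filter.

    A release at occasion i is any capture or recapture there, except at
    the terminal occasion (no later occasion to re-encounter at)."""
    subset = _filter(histories, sex=sex, panel=panel)
    if not subset:
        raise ValueError("no histories left after filtering")
    k = design.n_occasions
    releases = np.zeros(k - 1, dtype=np.int64)
    m = np.zeros((k - 1, k), dtype=np.int64)
    for h in subset:
        idx = np.flatnonzero(h.detections)
        for a, b in zip(idx, idx[1:]):
            releases[a] += 1
            m[a, b] += 1
        if idx[-1] < k - 1:  # terminal release, never re-encountered
            releases[idx[-1]] += 1
    return MArray(design.occasions, releases, m)


def split_by_trap_state(histories: list[EncounterHistory],
                        design: StudyDesign) -> list[np.ndarray]:
    """Annotate each history with a per-occasion trap state.

    For every occasion after an individual's first capture: state m1 if
    the animal was detected at the immediately preceding non-gap
    occasion, else m2.  Gap occasions, and occasions at or before first
    capture, carry no state.  Returns one int8 code vector
    (TRAP_NONE/TRAP_M1/TRAP_M2) per history, aligned to occasions.
    """
    k = design.n_occasions
    gap = np.array([y in design.gap_years for y in design.occasions])
    # previous non-gap occasion index for every occasion (-1 if none)
    prev_nongap = np.full(k, -1, dtype=int)
    last = -1
    for j in range(k):
        prev_nongap[j] = last
        if not gap[j]:
            last = j
    states = []
    for h in histories:
        s = np.full(k, TRAP_NONE, dtype=np.int8)
        f = h.first
        for j in range(f + 1, k):
            if gap[j]:
                continue
            pj = prev_nongap[j]
            if pj < f:
                continue
            s[j] = TRAP_M1 if h.detections[pj] else TRAP_M2
        states.append(s)
    return states
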