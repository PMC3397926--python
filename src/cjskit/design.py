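"""Study design: sampling occasions, monitoring gaps, and monitoring panels.

A capture-recapture study is described by an ordered list of annual
sampling occasions, an optional set of gap years in which no fieldwork
took place, and one or more monitoring *panels* — disjoint samples of
marked animals, each followed only over its own range of years.  Capture
probability is structurally zero for a panel outside its active range
and for every animal during a gap year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Panel", "StudyDesign", "simple_design"]


@dataclass(frozen=True)
class Panel:
    """A monitoring panel: a named sample active over [start, end] years."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"panel {self.name!r}: end {self.end} < start {self.start}")

    def contains(self, year: int) -> bool:
        return self.start <= year <= self.end


@dataclass(frozen=True)
class StudyDesign:
    """Occasions, gap years and panels of a capture-recapture study.

    Occasion indexing is 0-based internally; occasions are calendar
    years and must be strictly increasing.  Gap years remain occasions
    (survival intervals stay annual); capture is simply impossible
    there.
    """

    occasions: tuple[int, ...]
    gap_years: frozenset[int] = field(default_factory=frozenset)
    panels: tuple[Panel, ...] = ()

    def __post_init__(self) -> None:
        occ = tuple(int(y) for y in self.occasions)
        object.__setattr__(self, "occasions", occ)
        object.__setattr__(self, "gap_years", frozenset(int(y) for y in self.gap_years))
        if len(occ) < 2:
            raise ValueError("need at least two occasions")
        if any(b <= a for a, b in zip(occ, occ[1:])):
            raise ValueError("occasions must be strictly increasing")
        if not self.gap_years <= set(occ):
            raise ValueError("gap_years must be a subset of occasions")
        if not self.panels:
            object.__setattr__(
                self, "panels", (Panel("panel-1", occ[0], occ[-1]),)
            )
        for p in self.panels:
            if p.start not in occ or p.end not in occ:
                raise ValueError(f"panel {p.name!r} range not within occasions")

    # -- basic lookups -------------------------------------------------

    @property
    def n_occasions(self) -> int:
        return len(self.occasions)

    @property
    def n_intervals(self) -> int:
        return len(self.occasions) - 1

    def index(self, year: int) -> int:
        """0-based occasion index of a calendar year."""
        try:
            return self.occasions.index(year)
        except ValueError:
            raise KeyError(f"{year} is not a sampling occasion") from None

    def panel(self, name: str) -> Panel:
        for p in self.panels:
            if p.name == name:
                return p
        raise KeyError(f"unknown panel {name!r}")

    @property
    def panel_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.panels)

    def panel_for_year(self, year: int) -> Panel:
        """Panel whose active range contains ``year`` (used to assign
        an individual to a panel from its first-capture year)."""
        for p in self.panels:
            if p.contains(year):
                return p
        raise KeyError(f"{year} falls in no panel's active range")

    # -- masks ---------------------------------------------------------

    def capture_possible(self, panel: str, year: int) -> bool:
        p = self.panel(panel)
        return p.contains(year) and year not in self.gap_years

    def active_mask(self) -> np.ndarray:
        """Boolean (n_panels, n_occasions) array: capture physically
        possible for animals of each panel at each occasion."""
        mask = np.zeros((len(self.panels), self.n_occasions), dtype=bool)
        for i, p in enumerate(self.panels):
            for j, y in enumerate(self.occasions):
                mask[i, j] = p.contains(y) and y not in self.gap_years
        return mask

    def panel_occasions(self, panel: str) -> np.ndarray:
        """Indices of occasions at which capture is possible for a panel."""
        p = self.panel(panel)
        return np.array(
            [j for j, y in enumerate(self.occasions)
             if p.contains(y) and y not in self.gap_years],
            dtype=int,
        )

    @classmethod
    def default(cls) -> "StudyDesign":
        """The two-panel annual design: occasions 1978-2011, a 2000-2003
        monitoring gap, panel-1 active 1978-1999 and panel-2 2004-2011."""
        return cls(
            occasions=tuple(range(1978, 2012)),
            gap_years=frozenset(range(2000, 2004)),
            panels=(Panel("panel-1", 1978, 1999), Panel("panel-2", 2004, 2011)),
        )


def simple_design(n_occasions: int, start_year: int = 2000) -> StudyDesign:
    """A gap-free single-panel design of consecutive annual occasions."""
    years = tuple(range(start_year, start_year + n_occasions))
    return StudyDesign(occasions=years)
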