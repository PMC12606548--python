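"""Dose-combination matrix with partial toxicity order.

A two-drug combination trial arranges doses in a J x K matrix (drug A rows,
drug B columns).  Toxicity is monotone along rows and columns but
combinations off a shared row/column are incomparable — the *partial
toxicity order*.  Stage-1 escalation handles this by dividing the matrix
into totally ordered *sub-paths* and, whenever a combination proves overly
toxic, excluding its entire upward cone; the resulting frontier of walls is
the "Great Wall" and everything below it is toxicity-admissible.
"""

from __future__ import annotations

import enum
import json
from typing import Iterable, NamedTuple


class DoseCombo(NamedTuple):
    """One combination AjBk, 1-based in both coordinates."""

    j: int  # drug A level, 1..J
    k: int  # drug B level, 1..K

    @property
    def label(self) -> str:
        return f"A{self.j}B{self.k}"

    def dominates(self, other: "DoseCombo") -> bool:
        """True iff self is at least as toxic as ``other`` under the partial order."""
        return self.j >= other.j and self.k >= other.k


class DoseStatus(enum.Enum):
    UNTRIED = "untried"
    SAFE = "tried-safe"
    WALL = "wall"          # tried, flagged overly toxic
    EXCLUDED = "excluded"  # overly toxic by partial-order implication


class DoseGrid:
    """Mutable status map of a J x K combination matrix."""

    def __init__(self, J: int, K: int):
        if J < 1 or K < 1:
            raise ValueError("grid dimensions must be positive")
        self.J = J
        self.K = K
        self._status: dict[DoseCombo, DoseStatus] = {
            DoseCombo(j, k): DoseStatus.UNTRIED
            for j in range(1, J + 1)
            for k in range(1, K + 1)
        }

    # -- queries ---------------------------------------------------------

    def status(self, d: DoseCombo) -> DoseStatus:
        return self._status[d]

    def combos(self) -> list[DoseCombo]:
        return list(self._status)

    def untried(self) -> set[DoseCombo]:
        return {d for d, s in self._status.items() if s is DoseStatus.UNTRIED}

    def tried(self) -> set[DoseCombo]:
        return {
            d for d, s in self._status.items()
            if s in (DoseStatus.SAFE, DoseStatus.WALL)
        }

    def safe_set(self) -> set[DoseCombo]:
        return {d for d, s in self._status.items() if s is DoseStatus.SAFE}

    def walls(self) -> set[DoseCombo]:
        return {d for d, s in self._status.items() if s is DoseStatus.WALL}

    def overly_toxic(self) -> set[DoseCombo]:
        """Walls plus everything excluded through the partial order."""
        return {
            d for d, s in self._status.items()
            if s in (DoseStatus.WALL, DoseStatus.EXCLUDED)
        }

    # -- stage-1 mutations ----------------------------------------------

    def mark_safe(self, d: DoseCombo) -> None:
        if self._status[d] is not DoseStatus.UNTRIED:
            raise ValueError(f"{d.label} already has status {self._status[d].value}")
        self._status[d] = DoseStatus.SAFE

    def mark_wall(self, d: DoseCombo) -> set[DoseCombo]:
        """Flag ``d`` overly toxic and exclude its upward cone.

        Every combination dominating ``d`` is deemed overly toxic: untried
        ones are excluded outright, and any dominating combination that
        passed an earlier sub-path is demoted from tried-safe to excluded
        (the partial order overrides its small-sample pass).  Returns the
        set of combinations newly excluded (cone minus ``d``).
        """
        cone = exclusion_cone(d, self.untried() | {d})
        for c in cone:
            self._status[c] = DoseStatus.EXCLUDED
        for c in list(self.safe_set()):
            if c.dominates(d):
                self._status[c] = DoseStatus.EXCLUDED
                cone.add(c)
        self._status[d] = DoseStatus.WALL
        return cone - {d}

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "J": self.J,
            "K": self.K,
            "status": {d.label: s.value for d, s in self._status.items()},
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, payload: dict) -> "DoseGrid":
        grid = cls(payload["J"], payload["K"])
        for label, value in payload["status"].items():
            a, b = label[1:].split("B")
            grid._status[DoseCombo(int(a), int(b))] = DoseStatus(value)
        return grid

    def __str__(self) -> str:
        # drug A rows printed top-down from the highest level, drug B columns
        symbol = {
            DoseStatus.UNTRIED: ".",
            DoseStatus.SAFE: "S",
            DoseStatus.WALL: "W",
            DoseStatus.EXCLUDED: "x",
        }
        lines = []
        for j in range(self.J, 0, -1):
            row = " ".join(symbol[self._status[DoseCombo(j, k)]] for k in range(1, self.K + 1))
            lines.append(f"A{j} | {row}")
        lines.append("     " + " ".join(f"B{k}" for k in range(1, self.K + 1)))
        return "\n".join(lines)


def build_subpath(remaining: Iterable[DoseCombo]) -> list[DoseCombo]:
    """Next totally ordered sub-path through the remaining search space.

    The path runs up the leftmost remaining column (increasing drug-A level
    at the minimum remaining drug-B level) and then along the top remaining
    row (increasing drug-B level at that maximal drug-A level).  Toxicity is
    non-decreasing along the returned sequence for any row/column-monotone
    truth, so single-agent escalation logic applies within it.
    """
    remaining = set(remaining)
    if not remaining:
        raise ValueError("no remaining doses")
    k_min = min(d.k for d in remaining)
    column = sorted(d for d in remaining if d.k == k_min)
    j_top = column[-1].j
    row = sorted(d for d in remaining if d.j == j_top and d.k > k_min)
    # the top row must be contiguous with the column head for total ordering
    path = column + row
    return path


def exclusion_cone(d: DoseCombo, remaining: Iterable[DoseCombo]) -> set[DoseCombo]:
    """Upward cone of ``d`` within ``remaining`` (both coordinates >=, incl. ``d``).

    If ``d`` is overly toxic, every combination dominating it under the
    partial order is overly toxic as well and can be excluded untried.
    """
    remaining = set(remaining)
    if d not in remaining:
        raise ValueError(f"{d.label} is not in the remaining set")
    return {c for c in remaining if c.dominates(d)}


def wall_admissible_set(grid: DoseGrid) -> set[DoseCombo]:
    """All combinations below the Great Wall: tried and found safe (AT,1)."""
    return grid.safe_set()
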