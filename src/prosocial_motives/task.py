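"""Factorial trial grids of the action and judgment tasks.

One *situation* is a payoff configuration faced by Player A: the points
``p_a`` and ``p_b`` the two players earned (2–10, even), the ``bonus``
(2, 4 or 6) Player A can take by acting selfishly, and the framing
``context`` — Destroying (actively wiping out B's points) or Helping
(forgoing the bonus so B recovers points a lottery erased).  The selfish
action always leaves Player B with 0; the prosocial action preserves
``p_b`` at the cost of the bonus.

The full factorial 5 x 5 x 3 design gives 75 situations per context.  The
judgment task crosses each situation with the two possible decisions of a
fictive Player A, yielding 150 stimuli per context.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "Context",
    "Decision",
    "TrialSituation",
    "PAYOFF_LEVELS",
    "BONUS_LEVELS",
    "build_action_grid",
    "build_judgment_grid",
    "derived_features",
    "add_derived_features",
    "read_grid_csv",
    "write_grid_csv",
]

#: Payoff levels for each player (even integers spanning the 2–10 range;
#: 5 x 5 x 3 = 75 matches the number of distinct trials per context).
PAYOFF_LEVELS = (2, 4, 6, 8, 10)
#: Bonus offered for the selfish action.
BONUS_LEVELS = (2, 4, 6)


class Context(str, enum.Enum):
    """Framing of the choice: active destruction vs. passive non-help."""

    DESTROY = "destroy"
    HELP = "help"


class Decision(str, enum.Enum):
    """The two actions available to Player A."""

    PROSOCIAL = "prosocial"
    SELFISH = "selfish"


@dataclass(frozen=True)
class TrialSituation:
    """One payoff configuration of the action task."""

    p_a: int
    p_b: int
    bonus: int
    context: Context

    def __post_init__(self) -> None:
        if self.p_a not in PAYOFF_LEVELS or self.p_b not in PAYOFF_LEVELS:
            raise ValueError(
                f"payoffs must be in {PAYOFF_LEVELS}, got p_a={self.p_a}, p_b={self.p_b}"
            )
        if self.bonus not in BONUS_LEVELS:
            raise ValueError(f"bonus must be in {BONUS_LEVELS}, got {self.bonus}")

    @property
    def efficiency(self) -> int:
        """Total-wealth consequence of the prosocial choice, ``p_b - bonus``."""
        return self.p_b - self.bonus

    @property
    def worst_off(self) -> int:
        """Score of the worst-off player, ``min(p_a, p_b)``."""
        return min(self.p_a, self.p_b)


def _check_contexts(contexts: Iterable[Context | str]) -> list[Context]:
    ctxs = [Context(c) for c in contexts]
    if not ctxs:
        raise ValueError("need at least one context")
    # canonical order, no duplicates
    seen: list[Context] = []
    for c in sorted(ctxs, key=lambda c: c.value):
        if c not in seen:
            seen.append(c)
    return seen


def build_action_grid(contexts: Iterable[Context | str]) -> pd.DataFrame:
    """Full factorial grid of action-task situations.

    Parameters
    ----------
    contexts
        Non-empty subset of :class:`Context` (enum members or their
        string values).

    Returns
    -------
    DataFrame with columns ``context, p_a, p_b, bonus, efficiency,
    worst_off``, one row per situation, in canonical (context, p_a, p_b,
    bonus) ascending order.  75 rows per context.
    """
    rows = [
        {"context": c.value, "p_a": pa, "p_b": pb, "bonus": b}
        for c in _check_contexts(contexts)
        for pa in PAYOFF_LEVELS
        for pb in PAYOFF_LEVELS
        for b in BONUS_LEVELS
    ]
    return add_derived_features(pd.DataFrame(rows))


def build_judgment_grid(contexts: Iterable[Context | str]) -> pd.DataFrame:
    """Judgment-task stimuli: each situation crossed with both decisions.

    Returns a DataFrame like :func:`build_action_grid` with an extra
    ``judged_decision`` column; 150 rows per context.
    """
    grid = build_action_grid(contexts)
    out = []
    for decision in (Decision.PROSOCIAL, Decision.SELFISH):
        g = grid.copy()
        g["judged_decision"] = decision.value
        out.append(g)
    stim = pd.concat(out, ignore_index=True)
    stim = stim.sort_values(
        ["context", "p_a", "p_b", "bonus", "judged_decision"], kind="stable"
    ).reset_index(drop=True)
    return stim


def derived_features(situation: TrialSituation) -> tuple[int, int]:
    """Model-free features of a situation: ``(efficiency, worst_off)``."""
    return situation.efficiency, situation.worst_off


def add_derived_features(grid: pd.DataFrame) -> pd.DataFrame:
    """Attach ``efficiency = p_b - bonus`` and ``worst_off = min(p_a, p_b)``."""
    grid = grid.copy()
    grid["efficiency"] = grid["p_b"] - grid["bonus"]
    grid["worst_off"] = grid[["p_a", "p_b"]].min(axis=1)
    return grid


_GRID_COLS = ["context", "p_a", "p_b", "bonus"]


def write_grid_csv(grid: pd.DataFrame, path) -> None:
    cols = [c for c in _GRID_COLS + ["judged_decision"] if c in grid.columns]
    grid[cols].to_csv(path, index=False)


def read_grid_csv(path) -> pd.DataFrame:
    grid = pd.read_csv(path)
    missing = [c for c in _GRID_COLS if c not in grid.columns]
    if missing:
        raise ValueError(f"grid CSV missing columns: {missing}")
    return add_derived_features(grid)
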