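"""Reading and writing behavior tables as headered CSV.

Schema (one row per trial): ``participant_id, phase, context, p_a, p_b,
bonus, kind, judged_decision, response``.  Actions encode the choice as
``response`` 1 (prosocial) / 0 (selfish) with an empty
``judged_decision``; judgments carry the judged decision and a 1–6
rating.  Malformed rows are reported with their line numbers.
"""

from __future__ import annotations

import pandas as pd

from .task import BONUS_LEVELS, PAYOFF_LEVELS, Context, Decision

__all__ = ["read_behavior_csv", "write_behavior_csv", "validate_behavior"]

COLUMNS = [
    "participant_id", "phase", "context", "p_a", "p_b", "bonus",
    "kind", "judged_decision", "response",
]

PHASES = {"pre", "post", "na"}


def validate_behavior(df: pd.DataFrame) -> None:
    """Raise ValueError listing offending rows if the table is malformed.

    Row numbers refer to data rows counted from 1 (header excluded).
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"behavior table missing columns: {missing}")
    errors: list[str] = []

    def check(mask, msg):
        bad = df.index[mask] + 1
        for row in bad[:20]:
            errors.append(f"row {row}: {msg}")

    check(~df["context"].isin([c.value for c in Context]), "invalid context")
    check(~df["phase"].isin(PHASES), "invalid phase")
    check(~df["p_a"].isin(PAYOFF_LEVELS), "p_a outside payoff levels")
    check(~df["p_b"].isin(PAYOFF_LEVELS), "p_b outside payoff levels")
    check(~df["bonus"].isin(BONUS_LEVELS), "bonus outside bonus levels")
    check(~df["kind"].isin(["action", "judgment"]), "kind must be action|judgment")

    is_action = df["kind"] == "action"
    is_judgment = df["kind"] == "judgment"
    check(is_action & ~df["response"].isin([0, 1]),
          "action response must be 0 (selfish) or 1 (prosocial)")
    check(is_judgment & ~df["response"].isin(range(1, 7)),
          "judgment rating must be in 1..6")
    check(
        is_judgment & ~df["judged_decision"].isin([d.value for d in Decision]),
        "judgment rows need judged_decision prosocial|selfish",
    )
    if errors:
        raise ValueError("malformed behavior table:\n" + "\n".join(errors))


def read_behavior_csv(path) -> pd.DataFrame:
    """Load and validate a behavior table; empty files yield empty tables."""
    df = pd.read_csv(path, dtype={"participant_id": str}, keep_default_na=False)
    if df.empty:
        return pd.DataFrame(columns=COLUMNS)
    df["response"] = pd.to_numeric(df["response"], errors="coerce")
    if df["response"].isna().any():
        bad = (df.index[df["response"].isna()] + 1).tolist()[:20]
        raise ValueError(f"non-numeric response at rows {bad}")
    df["response"] = df["response"].astype(int)
    validate_behavior(df)
    return df[COLUMNS]


def write_behavior_csv(records: pd.DataFrame, path) -> None:
    validate_behavior(records)
    records[COLUMNS].to_csv(path, index=False)
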