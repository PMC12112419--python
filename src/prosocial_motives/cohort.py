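"""Synthetic cohorts of the four motivational profiles and norm environments.

The generator draws participants from four profiles whose qualitative
signatures match the motivational typology the framework is built to
detect:

* unconditionally selfish — strongly negative baseline bias, low outcome
  weight: virtually never prosocial;
* cost-sensitive — prosocial baseline but low outcome weight: prosocial
  only when the bonus (the cost of prosociality) is small;
* efficiency-sensitive — high outcome weight, low mu: prosocial when it
  preserves total wealth (p_b > bonus);
* harm-sensitive — high outcome weight, high mu: prosocial unless the
  harm to Player B is small.

Parameter locations/spreads are population constants of this package (the
source data are not deposited), chosen so that the per-type action maps
over the payoff grid reproduce the published qualitative patterns.  Draws
are normal on the unconstrained scale (bias raw; gamma/mu/delta1 logit;
inverse temperature and probit scale log), so every sample respects the
parameter domains by construction.

Judgment-model parameters are near-consensual across profiles, mirroring
the empirical finding that people largely agree on what is appropriate
even when their actions diverge.

The module also builds the four norm-exposure environments: feedback from
the 11 most/least prosocial donors (descriptive, A+/A-) or the
strictest/most lenient judges (prescriptive, J+/J-).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import models
from .models import CRParams, default_thresholds
from .task import Decision

__all__ = [
    "Profile",
    "ProfileSpec",
    "EnvironmentKind",
    "ExposureEnvironment",
    "DEFAULT_PROFILE_COUNTS",
    "default_profiles",
    "sample_cohort",
    "cohort_params",
    "simulate_dataset",
    "build_environment",
    "apply_exposure_shift",
]


class Profile(str, enum.Enum):
    UNCONDITIONALLY_SELFISH = "unconditionally_selfish"
    COST_SENSITIVE = "cost_sensitive"
    EFFICIENCY_SENSITIVE = "efficiency_sensitive"
    HARM_SENSITIVE = "harm_sensitive"


class EnvironmentKind(str, enum.Enum):
    A_PLUS = "a_plus"    # frequent prosocial actions
    A_MINUS = "a_minus"  # frequent selfish actions
    J_PLUS = "j_plus"    # strict judgments
    J_MINUS = "j_minus"  # lenient judgments


#: Default profile mix (shares of the four types in the reference sample).
DEFAULT_PROFILE_COUNTS: dict[Profile, int] = {
    Profile.UNCONDITIONALLY_SELFISH: 20,
    Profile.COST_SENSITIVE: 25,
    Profile.EFFICIENCY_SENSITIVE: 39,
    Profile.HARM_SENSITIVE: 16,
}

# Unconstrained-scale keys of the action and judgment models.
ACTION_KEYS = ("bias", "logit_gamma", "logit_mu", "logit_delta1", "log_inv_temp")
JUDGMENT_KEYS = ("j_bias", "j_logit_gamma", "j_logit_mu", "j_logit_delta1", "j_log_scale")


@dataclass(frozen=True)
class ProfileSpec:
    """Population location and spread of one motivational profile.

    Means and SDs live on the unconstrained scale (see module docstring);
    ``thresholds`` are the shared judgment cut-points.
    """

    name: Profile
    mean: Mapping[str, float]
    sd: Mapping[str, float]
    thresholds: tuple[float, ...] = tuple(default_thresholds())


# Shared judgment-model population: near-consensus, harm-leaning (mu high),
# with a moderate Destroy-context discount.
_JUDGMENT_MEAN = {
    "j_bias": -1.0,
    "j_logit_gamma": 1.1,   # gamma ~ 0.75
    "j_logit_mu": 1.1,      # mu ~ 0.75
    "j_logit_delta1": 0.4,  # delta1 ~ 0.6: Destroying judged more harshly
    "j_log_scale": np.log(0.35),
}
_JUDGMENT_SD = {
    "j_bias": 0.5,
    "j_logit_gamma": 0.4,
    "j_logit_mu": 0.4,
    "j_logit_delta1": 0.4,
    "j_log_scale": 0.25,
}

_ACTION_SD = {
    "bias": 0.8,
    "logit_gamma": 0.6,
    "logit_mu": 0.6,
    "logit_delta1": 0.5,
    "log_inv_temp": 0.5,
}

_ACTION_MEANS: dict[Profile, dict[str, float]] = {
    Profile.UNCONDITIONALLY_SELFISH: {
        "bias": -6.0,
        "logit_gamma": -1.8,   # gamma ~ 0.14
        "logit_mu": 0.0,       # mu irrelevant at low gamma
        "logit_delta1": 1.5,
        "log_inv_temp": np.log(0.8),
    },
    Profile.COST_SENSITIVE: {
        "bias": 2.5,
        "logit_gamma": -1.6,   # gamma ~ 0.17: own bonus dominates outcomes
        "logit_mu": 0.0,
        "logit_delta1": 1.5,
        "log_inv_temp": np.log(1.3),
    },
    Profile.EFFICIENCY_SENSITIVE: {
        "bias": 0.0,
        "logit_gamma": 2.2,    # gamma ~ 0.90
        "logit_mu": -2.2,      # mu ~ 0.10: efficiency goal
        "logit_delta1": 1.5,
        "log_inv_temp": np.log(2.2),
    },
    Profile.HARM_SENSITIVE: {
        "bias": 0.0,
        "logit_gamma": 2.2,    # gamma ~ 0.90
        "logit_mu": 1.8,       # mu ~ 0.86: harm-aversion goal
        "logit_delta1": 1.5,
        "log_inv_temp": np.log(1.3),
    },
}


def default_profiles() -> dict[Profile, ProfileSpec]:
    """The four default motivational profiles."""
    out = {}
    for prof, amean in _ACTION_MEANS.items():
        mean = {**amean, **_JUDGMENT_MEAN}
        sd = {**_ACTION_SD, **_JUDGMENT_SD}
        out[prof] = ProfileSpec(name=prof, mean=mean, sd=sd)
    return out


def _natural_row(u: Mapping[str, float]) -> dict[str, float]:
    """Unconstrained draw -> natural-scale parameter columns."""
    return {
        "bias": u["bias"],
        "gamma": float(expit(u["logit_gamma"])),
        "mu": float(expit(u["logit_mu"])),
        "delta1": float(expit(u["logit_delta1"])),
        "inv_temp": float(np.exp(u["log_inv_temp"])),
        "j_bias": u["j_bias"],
        "j_gamma": float(expit(u["j_logit_gamma"])),
        "j_mu": float(expit(u["j_logit_mu"])),
        "j_delta1": float(expit(u["j_logit_delta1"])),
        "j_scale": float(np.exp(u["j_log_scale"])),
    }


def sample_cohort(
    profiles: Mapping[Profile, ProfileSpec] | None = None,
    counts: Mapping[Profile, int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a cohort of synthetic participants with stored true labels.

    Returns a truth table with one row per participant: ``participant_id``
    (p000, p001, ...), ``profile``, natural-scale action parameters
    (``bias, gamma, mu, delta1, inv_temp``), judgment parameters
    (``j_bias, j_gamma, j_mu, j_delta1, j_scale``) and the five shared
    judgment thresholds ``thr_1..thr_5``.  Reproducible from ``seed``.
    """
    profiles = profiles if profiles is not None else default_profiles()
    counts = counts if counts is not None else DEFAULT_PROFILE_COUNTS
    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for prof in Profile:
        n = int(counts.get(prof, 0))
        if n < 0:
            raise ValueError("counts must be >= 0")
        if n == 0 or prof not in profiles:
            continue
        spec = profiles[prof]
        for _ in range(n):
            u = {
                k: rng.normal(spec.mean[k], spec.sd[k])
                for k in ACTION_KEYS + JUDGMENT_KEYS
            }
            row = {"participant_id": f"p{idx:03d}", "profile": prof.value}
            row.update(_natural_row(u))
            for j, t in enumerate(spec.thresholds, start=1):
                row[f"thr_{j}"] = t
            rows.append(row)
            idx += 1
    cols = (
        ["participant_id", "profile", "bias", "gamma", "mu", "delta1", "inv_temp",
         "j_bias", "j_gamma", "j_mu", "j_delta1", "j_scale"]
        + [f"thr_{j}" for j in range(1, 6)]
    )
    return pd.DataFrame(rows, columns=cols)


def cohort_params(row: pd.Series, kind: str = "action") -> CRParams:
    """Typed parameters of one truth-table row for the given task."""
    if kind == "action":
        return CRParams(
            bias=row["bias"], gamma=row["gamma"], mu=row["mu"],
            delta1=row["delta1"], inv_temp=row["inv_temp"],
        )
    return CRParams(
        bias=row["j_bias"], gamma=row["j_gamma"], mu=row["j_mu"],
        delta1=row["j_delta1"], inv_temp=1.0, scale=row["j_scale"],
        thresholds=tuple(row[f"thr_{j}"] for j in range(1, 6)),
    )


def simulate_dataset(
    cohort: pd.DataFrame,
    grid: pd.DataFrame,
    kind: str = "action",
    seed: int = 0,
    phase: str = "na",
) -> pd.DataFrame:
    """Simulate one response per participant per grid row.

    ``kind="action"`` draws Bernoulli prosocial choices via the softmax;
    ``kind="judgment"`` draws 1–6 ratings via the ordered probit (the grid
    must then carry ``judged_decision``).  Output is a behavior table with
    columns ``participant_id, phase, context, p_a, p_b, bonus, kind,
    judged_decision, response``.
    """
    if kind not in ("action", "judgment"):
        raise ValueError("kind must be 'action' or 'judgment'")
    if kind == "judgment" and "judged_decision" not in grid.columns:
        raise ValueError("judgment simulation needs a judgment grid")
    rng = np.random.default_rng(seed)
    frames = []
    for _, row in cohort.iterrows():
        params = cohort_params(row, kind)
        du = models.delta_u(params, grid)
        rec = grid[["context", "p_a", "p_b", "bonus"]].copy()
        rec.insert(0, "participant_id", row["participant_id"])
        rec.insert(1, "phase", phase)
        rec["kind"] = kind
        if kind == "action":
            p = models.prob_prosocial(du, params.inv_temp)
            rec["judged_decision"] = ""
            rec["response"] = (rng.random(len(grid)) < p).astype(int)
        else:
            rec["judged_decision"] = grid["judged_decision"].to_numpy()
            resp = np.empty(len(grid), dtype=int)
            for dec in (Decision.PROSOCIAL.value, Decision.SELFISH.value):
                m = rec["judged_decision"].to_numpy() == dec
                if not m.any():
                    continue
                probs = models.rating_probs(
                    du[m], dec, params.thresholds, params.scale
                )
                cum = probs.cumsum(axis=1)
                resp[m] = 1 + (rng.random((m.sum(), 1)) > cum[:, :5]).sum(axis=1)
            rec["response"] = resp
        frames.append(rec)
    cols = ["participant_id", "phase", "context", "p_a", "p_b", "bonus",
            "kind", "judged_decision", "response"]
    if not frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)[cols]


# ---------------------------------------------------------------------------
# Exposure environments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExposureEnvironment:
    """Feedback block built from 11 selected donor participants.

    ``feedback`` maps every grid situation to an integer 1–6: for A±, the
    number of donors choosing the selfish action rescaled from 0–11 to
    1–6 (round half-up); for J±, the modal 1–6 rating of the selfish
    action among donors (ties -> lower rating).
    """

    kind: EnvironmentKind
    donor_ids: tuple[str, ...]
    feedback: pd.DataFrame = field(compare=False)

    def __post_init__(self) -> None:
        fb = self.feedback["feedback"]
        if fb.min() < 1 or fb.max() > 6:
            raise ValueError("feedback must be on the 1–6 scale")


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(int)


def build_environment(
    pool: pd.DataFrame,
    kind: EnvironmentKind | str,
    n_donors: int = 11,
) -> ExposureEnvironment:
    """Select donors from a behavior pool and compute per-situation feedback.

    ``pool`` is a behavior table (action rows for A±, judgment rows for
    J±) covering the grid for each participant.  Donors are the
    ``n_donors`` participants with the most extreme behavior: A- = highest
    selfish-action frequency, A+ = lowest; J+ = strictest mean rating of
    selfish actions, J- = most lenient.  Ranking ties break by
    participant id.
    """
    kind = EnvironmentKind(kind)
    descriptive = kind in (EnvironmentKind.A_PLUS, EnvironmentKind.A_MINUS)
    rows = pool[pool["kind"] == ("action" if descriptive else "judgment")]
    if not descriptive:
        rows = rows[rows["judged_decision"] == Decision.SELFISH.value]
    if rows.empty:
        raise ValueError(f"pool has no usable rows for environment {kind.value}")

    if descriptive:
        score = 1.0 - rows.groupby("participant_id")["response"].mean()  # selfish freq
    else:
        score = rows.groupby("participant_id")["response"].mean()  # mean rating of selfish
    if len(score) < n_donors:
        raise ValueError(f"pool has {len(score)} participants, need {n_donors}")
    ascending = kind in (EnvironmentKind.A_PLUS, EnvironmentKind.J_PLUS)
    ranked = score.reset_index().sort_values(
        ["response", "participant_id"], ascending=[ascending, True], kind="stable"
    )
    donors = tuple(ranked["participant_id"].head(n_donors))

    dsub = rows[rows["participant_id"].isin(donors)]
    key = ["context", "p_a", "p_b", "bonus"]
    if descriptive:
        counts = dsub.groupby(key)["response"].agg(
            n_selfish=lambda r: int((1 - r).sum()), n="size"
        ).reset_index()
        if (counts["n"] < n_donors).any():
            raise ValueError("donor behavior does not cover the grid")
        fb = _round_half_up(1.0 + 5.0 * counts["n_selfish"].to_numpy() / n_donors)
        feedback = counts[key].copy()
        feedback["feedback"] = fb
    else:
        def lower_mode(r: pd.Series) -> int:
            vals, cnts = np.unique(r.to_numpy(), return_counts=True)
            return int(vals[np.argmax(cnts)])  # first max -> lowest rating

        agg = dsub.groupby(key)["response"].agg(feedback=lower_mode, n="size").reset_index()
        if (agg["n"] < n_donors).any():
            raise ValueError("donor behavior does not cover the grid")
        feedback = agg[key + ["feedback"]]
    return ExposureEnvironment(kind=kind, donor_ids=donors, feedback=feedback)


# ---------------------------------------------------------------------------
# Ground-truth parameter shifts (for testing the change model)
# ---------------------------------------------------------------------------

_SHIFTABLE = {
    "bias": "bias",
    "logit_gamma": "gamma",
    "logit_mu": "mu",
    "logit_delta1": "delta1",
    "log_inv_temp": "inv_temp",
    "j_bias": "j_bias",
    "j_logit_gamma": "j_gamma",
    "j_logit_mu": "j_mu",
}


def apply_exposure_shift(
    cohort: pd.DataFrame,
    shift: Mapping[str, Mapping[str, float]] | Mapping[str, float],
    seed: int = 0,
) -> pd.DataFrame:
    """Additive parameter shifts on the unconstrained scale.

    ``shift`` maps unconstrained parameter keys (``bias``, ``logit_gamma``,
    ``logit_mu``, ...) to offsets, either globally (flat mapping) or per
    profile (``{profile: {key: offset}}``).  Offsets may also be
    ``(mean, sd)`` pairs, in which case per-participant shifts are drawn
    with the given seed.  Returns a new truth table; domains hold by
    construction of the transforms.
    """
    rng = np.random.default_rng(seed)
    per_profile = shift and all(isinstance(v, Mapping) for v in shift.values())
    out = cohort.copy()
    for i, row in cohort.iterrows():
        if per_profile:
            prof = row["profile"]
            spec = shift.get(prof) or shift.get(Profile(prof)) or {}
        else:
            spec = shift
        for key, off in spec.items():
            if key not in _SHIFTABLE:
                raise ValueError(f"cannot shift unknown parameter {key!r}")
            if isinstance(off, (tuple, list)):
                off = rng.normal(off[0], off[1])
            col = _SHIFTABLE[key]
            val = row[col]
            if key.startswith("logit") or key.startswith("j_logit"):
                u = logit(np.clip(val, 1e-9, 1 - 1e-9)) + off
                out.at[i, col] = float(expit(u))
            elif key.startswith("log"):
                out.at[i, col] = float(np.exp(np.log(max(val, 1e-12)) + off))
            else:
                out.at[i, col] = float(val + off)
    return out
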