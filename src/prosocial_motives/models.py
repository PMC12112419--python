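"""Utility-model family and response likelihoods for actions and judgments.

The shared core is the utility difference dU between the prosocial and the
selfish action of Player A in one situation.  The main (extended
Charness–Rabin) family is

    dU = bias + gamma * mu * min(p_a, p_b)
              + gamma * (1 - mu) * (p_b - delta_i * b)
              - (1 - gamma) * delta_i * b

with ``bias`` a stake-independent baseline preference for prosocial
responding, ``gamma`` in [0, 1] the weight on prosocial outcomes versus
the own bonus, ``mu`` in [0, 1] the position between pure efficiency
(mu = 0, total wealth p_b - b) and pure harm-aversion (mu = 1, worst-off
score min(p_a, p_b)), and ``delta_i`` a bonus discount that equals
``delta1`` in the Destroying context and is fixed at 1 in the Helping
context.

Alternative families used for model comparison: Fehr–Schmidt inequity
aversion, a harm-aversion trade-off model (bonus vs. Player B's payoff),
and Krupka–Weber norm-following, which scores actions by empirical
appropriateness ratings (a :class:`NormTable`).

dU is mapped to behavior by one of two transfer functions sharing the
same parameters: a softmax (logistic in ``inv_temp * dU``) for the binary
action, and an ordered probit over the six appropriateness ratings for
the judgment task, with the signed utility +dU when the judged decision
is prosocial and -dU when it is selfish.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit
from scipy.stats import norm

from .task import Context, Decision, build_judgment_grid

__all__ = [
    "CRParams",
    "AltParams",
    "NormTable",
    "ModelSpec",
    "MODEL_REGISTRY",
    "LOG_FLOOR",
    "delta_u",
    "prob_prosocial",
    "rating_probs",
    "loglik",
    "pointwise_loglik",
    "rescale_rating_unit",
    "build_norm_table",
    "default_thresholds",
]

#: Floor applied to per-trial log-probabilities so likelihoods stay finite
#: under extreme parameters.
LOG_FLOOR = float(np.log(1e-12))

#: Sum-to-zero default rating thresholds (identification: the judgment
#: intercept is carried by ``bias``, not by the threshold location).
DEFAULT_THRESHOLDS = (-2.5, -1.25, 0.0, 1.25, 2.5)


def default_thresholds() -> np.ndarray:
    return np.asarray(DEFAULT_THRESHOLDS, dtype=float)


@dataclass(frozen=True)
class CRParams:
    """Parameters of the extended Charness–Rabin model for one participant.

    ``inv_temp`` is used by the action (softmax) likelihood; ``scale`` and
    ``thresholds`` by the judgment (ordered-probit) likelihood.
    """

    bias: float = 0.0
    gamma: float = 0.5
    mu: float = 0.5
    delta1: float = 1.0
    inv_temp: float = 1.0
    scale: float | None = None
    thresholds: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("gamma", "mu", "delta1"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.inv_temp < 0:
            raise ValueError(f"inv_temp must be >= 0, got {self.inv_temp}")
        if self.scale is not None and self.scale < 0:
            raise ValueError(f"scale must be >= 0, got {self.scale}")
        if self.thresholds is not None:
            t = np.asarray(self.thresholds, dtype=float)
            if t.size != 5 or np.any(np.diff(t) <= 0):
                raise ValueError("thresholds must be 5 strictly increasing values")


@dataclass(frozen=True)
class AltParams:
    """Parameters of an alternative utility family (one family active)."""

    family: Literal["fs", "harm", "kw"]
    bias: float = 0.0
    fs_alpha: float = 0.0
    fs_beta: float = 0.0
    harm_weight: float = 0.0
    kw_phi: float = 0.0
    delta1: float = 1.0
    inv_temp: float = 1.0
    scale: float | None = None
    thresholds: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("fs_alpha", "fs_beta", "harm_weight", "kw_phi", "inv_temp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class NormTable:
    """Empirical appropriateness of each (situation, decision) stimulus.

    Values live in [-1, 1]: -1 = very socially inappropriate, +1 = very
    socially appropriate, obtained by linearly rescaling mean 1–6 ratings.
    ``level`` records whether ratings were averaged across the whole
    judgment sample ("group") or come from a single participant
    ("individual").
    """

    KEY = ["context", "p_a", "p_b", "bonus", "judged_decision"]

    def __init__(self, table: pd.DataFrame, level: str = "group"):
        missing = [c for c in self.KEY + ["norm"] if c not in table.columns]
        if missing:
            raise ValueError(f"norm table missing columns: {missing}")
        if table["norm"].abs().max() > 1 + 1e-9:
            raise ValueError("norm values must lie in [-1, 1]")
        self.level = level
        self._table = table[self.KEY + ["norm"]].copy()
        self._lookup = {
            (r.context, r.p_a, r.p_b, r.bonus, r.judged_decision): r.norm
            for r in self._table.itertuples()
        }

    @property
    def table(self) -> pd.DataFrame:
        return self._table.copy()

    def value(self, situations: pd.DataFrame, decision: str) -> np.ndarray:
        """N(a) for the given decision in each situation (vectorized)."""
        out = np.empty(len(situations))
        for i, r in enumerate(situations.itertuples()):
            key = (r.context, r.p_a, r.p_b, r.bonus, decision)
            try:
                out[i] = self._lookup[key]
            except KeyError:
                raise KeyError(f"norm table has no entry for stimulus {key}") from None
        return out

    def norm_diff(self, situations: pd.DataFrame) -> np.ndarray:
        """N(prosocial) - N(selfish) for each situation."""
        return self.value(situations, Decision.PROSOCIAL.value) - self.value(
            situations, Decision.SELFISH.value
        )

    def to_csv(self, path) -> None:
        self._table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, level: str = "group") -> "NormTable":
        return cls(pd.read_csv(path), level=level)


def rescale_rating_unit(rating: int | np.ndarray) -> float | np.ndarray:
    """Map a 1–6 rating linearly onto [0, 1] for reporting."""
    r = np.asarray(rating)
    if np.any(r < 1) or np.any(r > 6):
        raise ValueError("ratings must be in 1..6")
    out = (r - 1) / 5.0
    return float(out) if out.ndim == 0 else out


def _rescale_rating_signed(mean_rating: np.ndarray) -> np.ndarray:
    """Map mean 1–6 ratings linearly onto [-1, 1] (Krupka–Weber convention)."""
    return (np.asarray(mean_rating, dtype=float) - 3.5) / 2.5


def build_norm_table(
    judgments: pd.DataFrame,
    level: str = "group",
    participant_id: str | None = None,
) -> NormTable:
    """Average judgment ratings into a norm table.

    Parameters
    ----------
    judgments
        Behavior table with judgment rows (columns ``context, p_a, p_b,
        bonus, judged_decision, response`` with 1–6 ratings).
    level
        "group": average across all participants.  "individual": use only
        ``participant_id``'s ratings.

    Raises a coverage error listing gaps if any stimulus of the judgment
    grid spanned by the data's contexts lacks an entry.
    """
    j = judgments[judgments["kind"] == "judgment"] if "kind" in judgments.columns else judgments
    if level == "individual":
        if participant_id is None:
            raise ValueError("individual-level norm table needs participant_id")
        j = j[j["participant_id"] == participant_id]
    key = NormTable.KEY
    mean = j.groupby(key, as_index=False)["response"].mean()
    contexts = sorted(j["context"].unique())
    grid = build_judgment_grid(contexts)[key]
    merged = grid.merge(mean, on=key, how="left")
    gaps = merged[merged["response"].isna()]
    if len(gaps):
        listing = gaps[key].head(10).to_dict("records")
        raise ValueError(
            f"judgments do not cover {len(gaps)} grid stimuli, e.g. {listing}"
        )
    merged["norm"] = _rescale_rating_signed(merged["response"].to_numpy())
    return NormTable(merged[key + ["norm"]], level=level)


# ---------------------------------------------------------------------------
# Utility difference
# ---------------------------------------------------------------------------

def _delta_i(params, situations: pd.DataFrame) -> np.ndarray:
    delta1 = getattr(params, "delta1", 1.0)
    is_destroy = (situations["context"].to_numpy() == Context.DESTROY.value)
    return np.where(is_destroy, delta1, 1.0)


def delta_u(
    params: CRParams | AltParams,
    situations: pd.DataFrame,
    norms: NormTable | None = None,
) -> np.ndarray:
    """Utility of the prosocial minus the selfish action, per situation.

    ``situations`` is a grid-like DataFrame (columns ``context, p_a, p_b,
    bonus``).  Returns one value per row.  The Krupka–Weber family
    requires ``norms``.
    """
    pa = situations["p_a"].to_numpy(dtype=float)
    pb = situations["p_b"].to_numpy(dtype=float)
    b = situations["bonus"].to_numpy(dtype=float)

    if isinstance(params, CRParams):
        di = _delta_i(params, situations)
        g, m = params.gamma, params.mu
        return (
            params.bias
            + g * m * np.minimum(pa, pb)
            + g * (1 - m) * (pb - di * b)
            - (1 - g) * di * b
        )

    if params.family == "fs":
        # Inequity-averse utility evaluated at the two outcomes:
        # prosocial -> (p_a, p_b); selfish -> (p_a + b, 0).
        a, bt = params.fs_alpha, params.fs_beta
        u_pro = pa - a * np.maximum(pb - pa, 0.0) - bt * np.maximum(pa - pb, 0.0)
        u_self = (pa + b) - bt * (pa + b)
        return params.bias + u_pro - u_self
    if params.family == "harm":
        # Trade-off between the bonus and the harm done to Player B.
        di = _delta_i(params, situations)
        return params.bias + params.harm_weight * pb - di * b
    if params.family == "kw":
        if norms is None:
            raise ValueError("Krupka–Weber utility requires a NormTable")
        return params.bias - b + params.kw_phi * norms.norm_diff(situations)
    raise ValueError(f"unknown family {params.family!r}")


# ---------------------------------------------------------------------------
# Transfer functions
# ---------------------------------------------------------------------------

def prob_prosocial(du: np.ndarray | float, inv_temp: float) -> np.ndarray | float:
    """Softmax (two-option logistic) probability of the prosocial action."""
    if inv_temp < 0:
        raise ValueError("inv_temp must be >= 0")
    out = expit(inv_temp * np.asarray(du, dtype=float))
    return float(out) if out.ndim == 0 else out


def rating_probs(
    du: np.ndarray | float,
    judged_decision: str | Decision,
    thresholds: Sequence[float],
    scale: float,
) -> np.ndarray:
    """Ordered-probit probabilities of the six appropriateness ratings.

    The signed utility is ``s = +du`` when the judged decision is
    prosocial and ``-du`` when it is selfish: deciders with higher utility
    for the prosocial act rate it as more appropriate, and the selfish act
    as less.  ``P(rating <= k) = Phi(t_k - scale * s)``.

    Returns an array of shape ``(..., 6)`` summing to 1 along the last
    axis.
    """
    t = np.asarray(thresholds, dtype=float)
    if t.size != 5 or np.any(np.diff(t) <= 0):
        raise ValueError("thresholds must be 5 strictly increasing values")
    if scale < 0:
        raise ValueError("scale must be >= 0")
    decision = Decision(judged_decision)
    s = np.asarray(du, dtype=float)
    if decision is Decision.SELFISH:
        s = -s
    z = t - scale * s[..., None]
    cdf = norm.cdf(z)
    probs = np.diff(cdf, axis=-1, prepend=0.0, append=1.0)
    return np.clip(probs, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Model specification and dataset likelihood
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Which utility family and response likelihood to fit.

    ``kind`` selects the transfer function ("action" -> softmax,
    "judgment" -> ordered probit).  ``free_delta1`` frees the Destroy
    bonus discount (only meaningful with two contexts; with a single
    context it is uninformative and fixed at 1).  ``norms`` supplies the
    Krupka–Weber norm table.
    """

    family: Literal["cr", "fs", "harm", "kw"] = "cr"
    kind: Literal["action", "judgment"] = "action"
    include_bias: bool = True
    free_delta1: bool = False
    name: str | None = None
    norms: NormTable | None = field(default=None, compare=False)

    @property
    def label(self) -> str:
        if self.name:
            return self.name
        parts = [self.family]
        if self.free_delta1:
            parts.append("d1")
        if self.include_bias:
            parts.append("bias")
        return "_".join(parts)

    def with_norms(self, norms: NormTable) -> "ModelSpec":
        return replace(self, norms=norms)

    # -- parameter vector layout (unconstrained scale) --------------------
    @property
    def param_names(self) -> tuple[str, ...]:
        """Natural-scale parameter names, in vector order."""
        names: list[str] = []
        if self.include_bias:
            names.append("bias")
        if self.family == "cr":
            names += ["gamma", "mu"]
        elif self.family == "fs":
            names += ["fs_alpha", "fs_beta"]
        elif self.family == "harm":
            names += ["harm_weight"]
        elif self.family == "kw":
            names += ["kw_phi"]
        else:
            raise ValueError(f"unknown family {self.family!r}")
        if self.free_delta1 and self.family in ("cr", "harm"):
            names.append("delta1")
        if self.kind == "action":
            names.append("inv_temp")
        else:
            names.append("scale")
            names += [f"t_gap{i}" for i in range(1, 5)]
        return tuple(names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def unpack(self, theta: np.ndarray) -> dict:
        """Unconstrained vector -> natural-scale parameter dict.

        bias is raw; gamma/mu/delta1 go through a logistic; positive
        parameters through an exponential; rating thresholds are built
        from ``scale``'s 4 log-gaps and centered to sum to zero.
        """
        theta = np.asarray(theta, dtype=float)
        out: dict = {}
        i = 0
        for name in self.param_names:
            if name.startswith("t_gap"):
                continue
            if name == "bias":
                out[name] = float(theta[i])
            elif name in ("gamma", "mu", "delta1"):
                out[name] = float(expit(theta[i]))
            else:  # inv_temp, scale, fs_alpha, fs_beta, harm_weight, kw_phi
                out[name] = float(np.exp(np.clip(theta[i], -30, 30)))
            i += 1
        if self.kind == "judgment":
            gaps = np.exp(np.clip(theta[i : i + 4], -30, 30))
            t = np.concatenate([[0.0], np.cumsum(gaps)])
            out["thresholds"] = tuple(t - t.mean())
        if not self.include_bias:
            out["bias"] = 0.0
        if "delta1" not in out:
            out["delta1"] = 1.0
        return out

    def pack(self, params: Mapping[str, float]) -> np.ndarray:
        """Natural-scale parameter mapping -> unconstrained vector."""
        from scipy.special import logit

        theta = []
        for name in self.param_names:
            if name.startswith("t_gap"):
                continue
            v = params[name]
            if name == "bias":
                theta.append(v)
            elif name in ("gamma", "mu", "delta1"):
                theta.append(float(logit(np.clip(v, 1e-9, 1 - 1e-9))))
            else:
                theta.append(float(np.log(max(v, 1e-12))))
        if self.kind == "judgment":
            t = np.asarray(params["thresholds"], dtype=float)
            theta.extend(np.log(np.diff(t)))
        return np.asarray(theta, dtype=float)

    def to_params(self, params: Mapping[str, float]) -> CRParams | AltParams:
        """Natural-scale dict -> typed parameter object."""
        common = dict(
            bias=params.get("bias", 0.0),
            inv_temp=params.get("inv_temp", 1.0),
            scale=params.get("scale"),
            thresholds=params.get("thresholds"),
        )
        if self.family == "cr":
            return CRParams(
                gamma=params["gamma"],
                mu=params["mu"],
                delta1=params.get("delta1", 1.0),
                **common,
            )
        extra = {
            "fs": dict(fs_alpha=params.get("fs_alpha", 0.0), fs_beta=params.get("fs_beta", 0.0)),
            "harm": dict(
                harm_weight=params.get("harm_weight", 0.0),
                delta1=params.get("delta1", 1.0),
            ),
            "kw": dict(kw_phi=params.get("kw_phi", 0.0)),
        }[self.family]
        return AltParams(family=self.family, **common, **extra)


#: Model variants compared in the framework, keyed by short label.
MODEL_REGISTRY: dict[str, dict] = {
    "cr_d1_bias": dict(family="cr", include_bias=True, free_delta1=True),
    "cr_bias": dict(family="cr", include_bias=True, free_delta1=False),
    "cr_d1": dict(family="cr", include_bias=False, free_delta1=True),
    "cr": dict(family="cr", include_bias=False, free_delta1=False),
    "fs": dict(family="fs", include_bias=False),
    "fs_bias": dict(family="fs", include_bias=True),
    "harm": dict(family="harm", include_bias=False),
    "harm_bias": dict(family="harm", include_bias=True),
    "kw": dict(family="kw", include_bias=False),
    "kw_bias": dict(family="kw", include_bias=True),
}


def spec_from_name(name: str, kind: str = "action", norms: NormTable | None = None) -> ModelSpec:
    if name not in MODEL_REGISTRY:
        raise ValueError(f"unknown model {name!r}; known: {sorted(MODEL_REGISTRY)}")
    return ModelSpec(kind=kind, name=name, norms=norms, **MODEL_REGISTRY[name])


# -- fast per-participant design ---------------------------------------------

class TrialDesign:
    """Pre-extracted arrays for fast repeated likelihood evaluation."""

    def __init__(self, records: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        self.n = len(records)
        self.situations = records[["context", "p_a", "p_b", "bonus"]].reset_index(drop=True)
        self.pa = records["p_a"].to_numpy(dtype=float)
        self.pb = records["p_b"].to_numpy(dtype=float)
        self.b = records["bonus"].to_numpy(dtype=float)
        self.mn = np.minimum(self.pa, self.pb)
        self.is_destroy = (records["context"].to_numpy() == Context.DESTROY.value).astype(float)
        if spec.family == "kw":
            if spec.norms is None:
                raise ValueError("Krupka–Weber model requires a NormTable on the spec")
            self.dn = spec.norms.norm_diff(self.situations)
        if spec.kind == "action":
            resp = records["response"].to_numpy()
            self.y = resp.astype(int)
            if not np.isin(self.y, [0, 1]).all():
                raise ValueError("action responses must be 0 (selfish) or 1 (prosocial)")
        else:
            self.rating = records["response"].to_numpy(dtype=int)
            if not np.isin(self.rating, range(1, 7)).all():
                raise ValueError("judgment responses must be ratings in 1..6")
            self.judged_pro = (
                records["judged_decision"].to_numpy() == Decision.PROSOCIAL.value
            )

    def delta_u(self, p: dict) -> np.ndarray:
        bias = p.get("bias", 0.0)
        if self.spec.family == "cr":
            g, m = p["gamma"], p["mu"]
            di = 1.0 + (p.get("delta1", 1.0) - 1.0) * self.is_destroy
            return (
                bias
                + g * m * self.mn
                + g * (1 - m) * (self.pb - di * self.b)
                - (1 - g) * di * self.b
            )
        if self.spec.family == "fs":
            a, bt = p["fs_alpha"], p["fs_beta"]
            u_pro = self.pa - a * np.maximum(self.pb - self.pa, 0.0) - bt * np.maximum(
                self.pa - self.pb, 0.0
            )
            u_self = (self.pa + self.b) * (1 - bt)
            return bias + u_pro - u_self
        if self.spec.family == "harm":
            di = 1.0 + (p.get("delta1", 1.0) - 1.0) * self.is_destroy
            return bias + p["harm_weight"] * self.pb - di * self.b
        # kw
        return bias - self.b + p["kw_phi"] * self.dn

    def pointwise(self, theta: np.ndarray) -> np.ndarray:
        """Per-trial log-probabilities at unconstrained parameters theta."""
        return self.pointwise_params(self.spec.unpack(theta))

    def pointwise_params(self, p: Mapping[str, float]) -> np.ndarray:
        """Per-trial log-probabilities at natural-scale parameters."""
        du = self.delta_u(p)
        if self.spec.kind == "action":
            x = p["inv_temp"] * du
            # log P(y): log_expit(x) for prosocial, log_expit(-x) for selfish
            lp = np.where(self.y == 1, log_expit(x), log_expit(-x))
        else:
            s = np.where(self.judged_pro, du, -du)
            t = np.asarray(p["thresholds"])
            z = t - p["scale"] * s[:, None]
            cdf = norm.cdf(z)
            probs = np.diff(cdf, axis=-1, prepend=0.0, append=1.0)
            lp = np.log(np.clip(probs[np.arange(self.n), self.rating - 1], 1e-300, 1.0))
        return np.maximum(lp, LOG_FLOOR)

    def loglik(self, theta: np.ndarray) -> float:
        return float(self.pointwise(theta).sum())


def pointwise_loglik(
    dataset: pd.DataFrame,
    params_by_participant: Mapping[str, Mapping[str, float]],
    spec: ModelSpec,
) -> pd.DataFrame:
    """Per-trial log-probabilities for every record of a behavior table.

    ``params_by_participant`` maps participant id to a natural-scale
    parameter dict (as returned by :meth:`ModelSpec.unpack`).  Returns the
    dataset's index order with a ``logp`` column.
    """
    rows = dataset[dataset["kind"] == spec.kind] if "kind" in dataset.columns else dataset
    out = np.empty(len(rows))
    pos = 0
    pid_order = []
    for pid, group in rows.groupby("participant_id", sort=True):
        params = params_by_participant[pid]
        design = TrialDesign(group, spec)
        lp = design.pointwise_params(params)
        out[pos : pos + len(group)] = lp
        pid_order.extend([pid] * len(group))
        pos += len(group)
    return pd.DataFrame({"participant_id": pid_order, "logp": out})


def loglik(
    dataset: pd.DataFrame,
    params_by_participant: Mapping[str, Mapping[str, float]],
    spec: ModelSpec,
) -> tuple[float, pd.DataFrame]:
    """Total and pointwise log-likelihood of a behavior table."""
    pw = pointwise_loglik(dataset, params_by_participant, spec)
    return float(pw["logp"].sum()), pw
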