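"""Hierarchical fitting, parameter recovery, and the pre/post change model.

Fitting is empirical-Bayes EM with a Laplace approximation.  Participant
parameters live on an unconstrained scale (bias raw, gamma/mu/delta1
logit, positive parameters log) and are exchangeable draws from diagonal
normal population distributions.  Each EM iteration alternates

* E-step: per-participant penalized MAP (the population normal acts as
  the prior) plus a diagonal Laplace variance around the mode;
* M-step: population mean/SD moment updates regularized by weakly
  informative hyperpriors (mean ~ N(0, 5), SD ~ half-normal(2.5)).

After convergence, participant-level posteriors are approximated as
Gaussians around the MAP (full Hessian), from which posterior draws and
pointwise log-likelihood draws are generated for PSIS-LOO.  Under this
Gaussian approximation the marginal posterior mode equals the MAP, so
per-participant estimates are the (transformed) modes.

Diagnostics report split-R-hat and bulk ESS computed on the draws, plus
optimizer failures and Hessian regularizations; a fit is flagged
non-converged rather than silently accepted when the gate
(R-hat <= 1.05, ESS >= 100, no optimizer failure) fails.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import pearsonr

from . import cohort as cohort_mod
from .models import ModelSpec, TrialDesign
from .task import Context, build_action_grid

__all__ = [
    "PosteriorFit",
    "ChangeFit",
    "RecoveryReport",
    "fit_map_participant",
    "fit_hierarchical",
    "recovery_study",
    "fit_change_model",
]

log = logging.getLogger(__name__)

RHAT_GATE = 1.05
ESS_GATE = 100

# Default (non-hierarchical) prior on the unconstrained scale, used by
# single-participant MAP fits and as the EM starting population.
DEFAULT_PRIOR_SD = 2.5
POP_MEAN_PRIOR_SD = 5.0   # hyperprior on population means
POP_SD_PRIOR = 2.5        # half-normal scale on population SDs
POP_SD_MIN, POP_SD_MAX = 0.05, 5.0


def _neg_log_post(theta, design: TrialDesign, mu, sd):
    z = (theta - mu) / sd
    return -design.loglik(theta) + 0.5 * float(z @ z)


def _diag_hessian(f, theta, h=1e-3):
    """Diagonal of the Hessian by central differences."""
    d = len(theta)
    f0 = f(theta)
    out = np.empty(d)
    for i in range(d):
        e = np.zeros(d)
        e[i] = h
        out[i] = (f(theta + e) - 2 * f0 + f(theta - e)) / h**2
    return out


def _full_hessian(f, theta, h=1e-3):
    d = len(theta)
    H = np.empty((d, d))
    f0 = f(theta)
    fp = np.empty(d)
    fm = np.empty(d)
    for i in range(d):
        e = np.zeros(d)
        e[i] = h
        fp[i] = f(theta + e)
        fm[i] = f(theta - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d); ei[i] = h
            ej = np.zeros(d); ej[j] = h
            fij = f(theta + ei + ej)
            H[i, j] = H[j, i] = (fij - fp[i] - fp[j] + f0) / h**2
    return H


def _cov_from_hessian(H: np.ndarray, floor: float = 1e-3) -> tuple[np.ndarray, bool]:
    """Invert a (possibly indefinite) Hessian into a PD covariance."""
    H = 0.5 * (H + H.T)
    w, V = np.linalg.eigh(H)
    regularized = bool(np.any(w < floor))
    w = np.maximum(w, floor)
    cov = (V / w) @ V.T
    return cov, regularized


def _sir_draws(
    neg_log_post,
    mode: np.ndarray,
    cov: np.ndarray,
    draws: int,
    rng: np.random.Generator,
    proposal_scale: float = 1.4,
    oversample: int = 5,
) -> np.ndarray:
    """Posterior draws by sampling-importance-resampling.

    Proposes from an overdispersed Gaussian around the Laplace mode,
    weights by the exact (unnormalized) participant posterior, and
    resamples.  This corrects the Gaussian approximation in directions
    where the likelihood is flat or skewed, keeping downstream PSIS-LOO
    importance ratios well behaved.
    """
    d = len(mode)
    n0 = max(oversample * draws, 500)
    L = np.linalg.cholesky(cov) * proposal_scale
    z = rng.standard_normal((n0, d))
    proposals = mode + z @ L.T
    log_target = np.array([-neg_log_post(t) for t in proposals])
    # log proposal density (up to a constant): -0.5 * |L^-1 (theta-m)|^2
    log_q = -0.5 * (z**2).sum(axis=1)
    lw = log_target - log_q
    lw -= lw.max()
    w = np.exp(lw)
    w /= w.sum()
    idx = rng.choice(n0, size=draws, replace=True, p=w)
    return proposals[idx]


def fit_map_participant(
    records: pd.DataFrame,
    spec: ModelSpec,
    prior_mean: np.ndarray | None = None,
    prior_sd: np.ndarray | None = None,
    n_starts: int = 3,
    seed: int = 0,
    x0: np.ndarray | None = None,
) -> dict:
    """Penalized ML estimate for one participant under normal priors.

    Returns a dict with the unconstrained mode ``theta``, natural-scale
    ``params``, the objective value and a ``success`` flag.  Optimizer
    failure triggers multi-start retries before raising.
    """
    if len(records) == 0:
        raise ValueError("participant has no trials")
    design = TrialDesign(records, spec)
    return _fit_design(design, spec, prior_mean, prior_sd, n_starts, seed, x0)


def _fit_design(design, spec, prior_mean, prior_sd, n_starts=3, seed=0, x0=None):
    d = spec.n_params
    mu = np.zeros(d) if prior_mean is None else np.asarray(prior_mean, dtype=float)
    sd = np.full(d, DEFAULT_PRIOR_SD) if prior_sd is None else np.asarray(prior_sd, dtype=float)
    f = lambda th: _neg_log_post(th, design, mu, sd)
    rng = np.random.default_rng(seed)
    starts = [mu.copy() if x0 is None else np.asarray(x0, dtype=float)]
    starts += [mu + rng.normal(0, 1.0, d) for _ in range(max(n_starts - 1, 0))]
    best = None
    for s in starts:
        res = minimize(f, s, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("MAP optimization failed for all starts")
    return {
        "theta": best.x,
        "params": spec.unpack(best.x),
        "fun": float(best.fun),
        "success": bool(best.success),
        "design": design,
        "objective": f,
    }


@dataclass
class PosteriorFit:
    """Output of a hierarchical (or MAP-mode) fit."""

    spec: ModelSpec
    estimates: pd.DataFrame            # natural-scale posterior modes, index = pid
    theta: pd.DataFrame                # unconstrained modes
    pop_mean: pd.Series
    pop_sd: pd.Series
    obs: pd.DataFrame                  # participant_id per observation (flat order)
    pointwise: np.ndarray              # (n_obs,) log-lik at the modes
    loglik_draws: np.ndarray | None    # (n_draws, n_obs) or None
    diagnostics: dict
    seed: int
    config: dict

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))

    @property
    def participant_ids(self) -> list:
        return list(self.estimates.index)

    def params_dict(self) -> dict:
        """pid -> natural-scale parameter dict (including thresholds)."""
        out = {}
        for pid in self.estimates.index:
            out[pid] = self.spec.unpack(self.theta.loc[pid].to_numpy())
        return out

    def to_inferencedata(self, n_chains: int = 4):
        """Package log-likelihood draws for arviz (PSIS-LOO)."""
        import arviz as az

        if self.loglik_draws is None:
            raise ValueError("fit has no posterior draws; refit with draws > 0")
        S, N = self.loglik_draws.shape
        if S % n_chains:
            n_chains = 1
        ll = self.loglik_draws.reshape(n_chains, S // n_chains, N)
        return az.from_dict(
            posterior={"dummy": np.zeros((n_chains, S // n_chains))},
            log_likelihood={"obs": ll},
        )

    def save(self, outdir) -> None:
        """Serialize estimates, pointwise matrix, diagnostics and config."""
        import json
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.estimates.to_csv(outdir / "estimates.csv")
        pw = self.obs.copy()
        pw["logp"] = self.pointwise
        pw.to_csv(outdir / "pointwise_loglik.csv", index=False)
        pop = pd.DataFrame({"mean": self.pop_mean, "sd": self.pop_sd})
        pop.to_csv(outdir / "population.csv")
        meta = {
            "model": self.spec.label,
            "kind": self.spec.kind,
            "seed": self.seed,
            "config": self.config,
            "diagnostics": {
                k: (float(v) if np.isscalar(v) and not isinstance(v, bool) else v)
                for k, v in self.diagnostics.items()
            },
        }
        (outdir / "fit.json").write_text(json.dumps(meta, indent=2, default=str))


def fit_hierarchical(
    dataset: pd.DataFrame,
    spec: ModelSpec,
    n_em: int = 8,
    draws: int = 200,
    seed: int = 0,
    tol: float = 1e-3,
    n_starts: int = 3,
) -> PosteriorFit:
    """Empirical-Bayes hierarchical fit of one model family.

    ``dataset`` is a behavior table; rows whose ``kind`` does not match
    the spec are ignored.  ``draws`` Gaussian posterior draws per
    participant feed the pointwise log-likelihood matrix used by PSIS-LOO
    (set 0 to skip).  Degenerate data (e.g. all-identical responses)
    yield boundary-attracted, prior-shrunk estimates with a warning
    rather than failure.
    """
    rows = dataset[dataset["kind"] == spec.kind] if "kind" in dataset.columns else dataset
    pids = sorted(rows["participant_id"].unique())
    if len(pids) < 2:
        raise ValueError("hierarchical fit needs at least 2 participants")
    designs = {pid: TrialDesign(rows[rows["participant_id"] == pid], spec) for pid in pids}
    d = spec.n_params
    n = len(pids)
    pop_mu = np.zeros(d)
    pop_sd = np.full(d, DEFAULT_PRIOR_SD)

    modes = {pid: pop_mu.copy() for pid in pids}
    variances = {pid: np.full(d, 1.0) for pid in pids}
    n_fail = 0
    for it in range(n_em):
        for k, pid in enumerate(pids):
            try:
                fit = _fit_design(
                    designs[pid], spec, pop_mu, pop_sd,
                    n_starts=(n_starts if it == 0 else 1),
                    seed=seed * 1000 + k,
                    x0=None if it == 0 else modes[pid],
                )
            except RuntimeError:
                n_fail += 1
                continue
            modes[pid] = fit["theta"]
            hd = _diag_hessian(fit["objective"], fit["theta"])
            variances[pid] = 1.0 / np.maximum(hd, 1e-2)
        M = np.array([modes[p] for p in pids])
        V = np.array([variances[p] for p in pids])
        prec = n / np.maximum(pop_sd**2, 1e-6) + 1.0 / POP_MEAN_PRIOR_SD**2
        new_mu = (M.sum(axis=0) / np.maximum(pop_sd**2, 1e-6)) / prec
        ss = ((M - new_mu) ** 2 + V).sum(axis=0)
        new_sd = np.sqrt((ss + 0.25) / (n + 1))
        new_sd = np.clip(new_sd, POP_SD_MIN, min(POP_SD_MAX, POP_SD_PRIOR * 2))
        shift = max(np.max(np.abs(new_mu - pop_mu)), np.max(np.abs(new_sd - pop_sd)))
        pop_mu, pop_sd = new_mu, new_sd
        log.debug("EM iter %d: max shift %.4f", it, shift)
        if shift < tol:
            break

    # Final Laplace covariances and (optionally) posterior draws.
    rng = np.random.default_rng(seed + 7)
    n_hess_reg = 0
    obs_pid = []
    pw_mode = []
    ll_draws = [] if draws > 0 else None
    theta_rows, est_rows = [], []
    degenerate = []
    for pid in pids:
        design = designs[pid]
        f = lambda th: _neg_log_post(th, design, pop_mu, pop_sd)
        mode = modes[pid]
        pw_mode.append(design.pointwise(mode))
        obs_pid.extend([pid] * design.n)
        theta_rows.append(mode)
        est_rows.append(spec.unpack(mode))
        if spec.kind == "action" and len(np.unique(design.y)) == 1:
            degenerate.append(pid)
        if draws > 0:
            H = _full_hessian(f, mode)
            cov, reg = _cov_from_hessian(H)
            n_hess_reg += reg
            th_draws = _sir_draws(f, mode, cov, draws, rng)
            ll_draws.append(np.stack([design.pointwise(t) for t in th_draws], axis=0))
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} participant(s) with constant responses; their "
            "estimates are boundary-attracted and shrunk toward the population "
            f"(e.g. {degenerate[:3]})"
        )

    names = [nm for nm in spec.param_names if not nm.startswith("t_gap")]
    theta_df = pd.DataFrame(np.array(theta_rows), index=pids,
                            columns=list(spec.param_names))
    est_df = pd.DataFrame(
        [{k: v for k, v in e.items() if k != "thresholds"} for e in est_rows],
        index=pids,
    )
    if spec.kind == "judgment":
        thr = np.array([e["thresholds"] for e in est_rows])
        for j in range(5):
            est_df[f"thr_{j+1}"] = thr[:, j]
    est_df.index.name = "participant_id"
    theta_df.index.name = "participant_id"

    loglik_draws = np.concatenate(ll_draws, axis=1) if ll_draws else None
    diagnostics = _diagnostics(theta_df, loglik_draws, modes, pids, rng, n_fail,
                               n_hess_reg, draws, spec, designs, pop_mu, pop_sd, seed)
    return PosteriorFit(
        spec=spec,
        estimates=est_df,
        theta=theta_df,
        pop_mean=pd.Series(pop_mu, index=list(spec.param_names)),
        pop_sd=pd.Series(pop_sd, index=list(spec.param_names)),
        obs=pd.DataFrame({"participant_id": obs_pid}),
        pointwise=np.concatenate(pw_mode),
        loglik_draws=loglik_draws,
        diagnostics=diagnostics,
        seed=seed,
        config={"n_em": n_em, "draws": draws, "tol": tol, "n_starts": n_starts},
    )


def _diagnostics(theta_df, loglik_draws, modes, pids, rng, n_fail, n_hess_reg,
                 draws, spec, designs, pop_mu, pop_sd, seed):
    diag = {
        "n_participants": len(pids),
        "n_optim_failures": int(n_fail),
        "n_hessian_regularized": int(n_hess_reg),
        "n_divergences": 0,
    }
    if loglik_draws is not None and draws >= 8:
        import arviz as az

        S, N = loglik_draws.shape
        chains = 4 if S % 4 == 0 else 1
        ll = loglik_draws.reshape(chains, S // chains, N)
        # R-hat/ESS on the total log-likelihood per participant-block is a
        # cheap, representative summary of draw quality.
        tot = ll.sum(axis=2)
        data = az.convert_to_dataset({"total_loglik": tot})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = float(az.rhat(data)["total_loglik"].values)
            ess = float(az.ess(data)["total_loglik"].values)
        diag["rhat_max"] = rhat
        diag["ess_min"] = ess
        diag["converged"] = bool(
            rhat <= RHAT_GATE and ess >= ESS_GATE and n_fail == 0
        )
        if not diag["converged"]:
            warnings.warn(
                f"fit flagged non-converged: rhat={rhat:.3f}, ess={ess:.0f}, "
                f"optimizer failures={n_fail}"
            )
    else:
        diag["converged"] = n_fail == 0
    return diag


def fit_map_cohort(
    dataset: pd.DataFrame,
    spec: ModelSpec,
    seed: int = 0,
    n_starts: int = 2,
) -> PosteriorFit:
    """Fast non-hierarchical mode: independent MAP fits under the default
    prior.  Same return type as :func:`fit_hierarchical` (no draws)."""
    return fit_hierarchical(dataset, spec, n_em=1, draws=0, seed=seed,
                            n_starts=n_starts)


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Generating-vs-recovered correlations of a simulate-then-refit study."""

    correlations: dict[str, float]
    table: pd.DataFrame          # participant_id, profile, <p>_true, <p>_hat
    n_participants: int
    fit: PosteriorFit

    @property
    def min_r(self) -> float:
        vals = [v for v in self.correlations.values() if np.isfinite(v)]
        return float(min(vals)) if vals else float("nan")


def recovery_study(
    profiles: Mapping | None = None,
    counts: Mapping | None = None,
    grid: pd.DataFrame | None = None,
    seed: int = 0,
    fit_mode: Literal["hierarchical", "map"] = "hierarchical",
    n_em: int = 6,
    kind: str = "action",
) -> RecoveryReport:
    """Simulate a cohort, refit the CR model, correlate true vs recovered.

    With a single-context grid the bonus discount multiplies the bonus in
    every trial and is not separately informative, so ``delta1`` is fixed
    at 1 and the correlated parameters are bias, gamma, mu and the
    inverse temperature (action) or probit scale (judgment).
    Correlations are Pearson r on the natural parameter scale; a
    zero-variance generating parameter yields NaN (reported not-applicable).
    """
    counts = counts if counts is not None else cohort_mod.DEFAULT_PROFILE_COUNTS
    total = int(sum(counts.values()))
    if total < 10:
        raise ValueError("recovery study needs at least 10 participants")
    if grid is None:
        grid = build_action_grid([Context.DESTROY])
    two_contexts = grid["context"].nunique() > 1
    cohort = cohort_mod.sample_cohort(profiles, counts, seed=seed)
    data = cohort_mod.simulate_dataset(cohort, grid, kind=kind, seed=seed + 1)
    spec = ModelSpec(family="cr", kind=kind, include_bias=True,
                     free_delta1=two_contexts)
    if fit_mode == "hierarchical":
        fit = fit_hierarchical(data, spec, n_em=n_em, draws=0, seed=seed + 2)
    else:
        fit = fit_map_cohort(data, spec, seed=seed + 2)

    truth_cols = {"bias": "bias", "gamma": "gamma", "mu": "mu"}
    if two_contexts:
        truth_cols["delta1"] = "delta1"
    truth_cols["inv_temp" if kind == "action" else "scale"] = (
        "inv_temp" if kind == "action" else "j_scale"
    )
    table = cohort[["participant_id", "profile"]].copy().set_index("participant_id")
    corr = {}
    for par, tcol in truth_cols.items():
        true = cohort.set_index("participant_id")[tcol]
        hat = fit.estimates[par]
        table[f"{par}_true"] = true
        table[f"{par}_hat"] = hat
        if true.std() == 0 or hat.std() == 0:
            corr[par] = float("nan")
        else:
            corr[par] = float(pearsonr(true, hat.loc[true.index])[0])
    return RecoveryReport(correlations=corr, table=table.reset_index(),
                          n_participants=total, fit=fit)


# ---------------------------------------------------------------------------
# Pre/post change model
# ---------------------------------------------------------------------------

CHANGE_PARAMS = ("bias", "gamma", "mu")  # deltas on bias / logit-gamma / logit-mu


@dataclass
class ChangeFit:
    """Joint pre/post fit with additive unconstrained-scale change terms."""

    spec: ModelSpec
    table: pd.DataFrame   # pre params (natural), d_* deltas, post params
    skipped: list = field(default_factory=list)

    def deltas(self) -> pd.DataFrame:
        return self.table[[f"d_{p}" for p in CHANGE_PARAMS]]


def fit_change_model(
    dataset: pd.DataFrame,
    spec: ModelSpec,
    delta_prior_sd: float = 1.0,
    prior_mean: np.ndarray | None = None,
    prior_sd: np.ndarray | None = None,
    seed: int = 0,
) -> ChangeFit:
    """Fit theta_post = theta_pre + Delta per participant.

    ``dataset`` must carry ``phase`` in {"pre", "post"}.  Delta terms are
    restricted to bias, logit(gamma) and logit(mu) and get zero-centered
    normal priors (SD ``delta_prior_sd``); thresholds, discount and
    temperature/scale are shared across phases.  Participants missing a
    phase are skipped with a warning.
    """
    rows = dataset[dataset["kind"] == spec.kind] if "kind" in dataset.columns else dataset
    d = spec.n_params
    names = list(spec.param_names)
    delta_idx = np.array([names.index(p) for p in CHANGE_PARAMS if p in names])
    nd = len(delta_idx)
    mu0 = np.zeros(d) if prior_mean is None else np.asarray(prior_mean, dtype=float)
    sd0 = np.full(d, DEFAULT_PRIOR_SD) if prior_sd is None else np.asarray(prior_sd, dtype=float)

    out_rows = []
    skipped = []
    rng = np.random.default_rng(seed)
    for pid, grp in rows.groupby("participant_id", sort=True):
        pre = grp[grp["phase"] == "pre"]
        post = grp[grp["phase"] == "post"]
        if pre.empty or post.empty:
            skipped.append(pid)
            continue
        dpre = TrialDesign(pre, spec)
        dpost = TrialDesign(post, spec)

        def f(x):
            th = x[:d]
            dl = x[d:]
            th_post = th.copy()
            th_post[delta_idx] = th_post[delta_idx] + dl
            zp = (th - mu0) / sd0
            return (
                -dpre.loglik(th)
                - dpost.loglik(th_post)
                + 0.5 * float(zp @ zp)
                + 0.5 * float(dl @ dl) / delta_prior_sd**2
            )

        best = None
        for s in range(3):
            x0 = np.concatenate([mu0, np.zeros(nd)])
            if s:
                x0 = x0 + rng.normal(0, 0.5, d + nd)
            res = minimize(f, x0, method="L-BFGS-B")
            if best is None or res.fun < best.fun:
                best = res
        th, dl = best.x[:d], best.x[d:]
        th_post = th.copy()
        th_post[delta_idx] = th_post[delta_idx] + dl
        pre_par = spec.unpack(th)
        post_par = spec.unpack(th_post)
        row = {"participant_id": pid}
        for k, v in pre_par.items():
            if k != "thresholds":
                row[f"pre_{k}"] = v
        for j, p in enumerate([p for p in CHANGE_PARAMS if p in names]):
            row[f"d_{p}"] = float(dl[j])
        for k, v in post_par.items():
            if k != "thresholds":
                row[f"post_{k}"] = v
        out_rows.append(row)
    if skipped:
        warnings.warn(f"skipped {len(skipped)} participant(s) missing a phase")
    table = pd.DataFrame(out_rows).set_index("participant_id") if out_rows else pd.DataFrame()
    return ChangeFit(spec=spec, table=table, skipped=skipped)
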