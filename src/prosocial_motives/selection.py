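"""Model comparison by Pareto-smoothed importance-sampling LOO.

Thin, typed wrapper around :func:`arviz.loo` / :func:`arviz.compare`:
each fitted model contributes posterior draws of the pointwise
log-likelihood; models are ranked by estimated elpd (expected log
pointwise predictive density), with pairwise differences and their
standard errors relative to the best model, and counts of observations
whose Pareto-k diagnostic exceeds 0.7.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import PosteriorFit

__all__ = ["LooResult", "psis_loo", "compare"]

PARETO_K_WARN = 0.7


@dataclass
class LooResult:
    """elpd table of one or more models (best model first)."""

    table: pd.DataFrame  # index model; elpd, se, elpd_diff, se_diff, p_loo, n_high_k

    @property
    def best(self) -> str:
        return str(self.table.index[0])

    @property
    def ranking(self) -> list[str]:
        return list(self.table.index)

    def to_csv(self, path) -> None:
        self.table[["elpd_diff", "se_diff"]].to_csv(path)


def _loo_one(fit: PosteriorFit):
    import arviz as az

    if fit.loglik_draws is None:
        raise ValueError(
            f"fit {fit.spec.label!r} has no log-likelihood draws; "
            "refit with draws > 0"
        )
    if fit.loglik_draws.shape[0] < 8:
        raise ValueError("PSIS-LOO needs at least 8 posterior draws")
    idata = fit.to_inferencedata()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return az.loo(idata, pointwise=True)


def psis_loo(fit: PosteriorFit) -> LooResult:
    """PSIS-LOO elpd (with SE and Pareto-k flags) for a single fit."""
    res = _loo_one(fit)
    k = np.asarray(res.pareto_k)
    table = pd.DataFrame(
        {
            "elpd": [float(res.elpd_loo)],
            "se": [float(res.se)],
            "p_loo": [float(res.p_loo)],
            "elpd_diff": [0.0],
            "se_diff": [0.0],
            "n_high_k": [int((k > PARETO_K_WARN).sum())],
        },
        index=pd.Index([fit.spec.label], name="model"),
    )
    return LooResult(table=table)


def compare(fits: dict[str, PosteriorFit] | list[PosteriorFit]) -> LooResult:
    """Rank fitted models of the *same* dataset by PSIS-LOO elpd.

    Raises if the fits do not cover identical observations (same
    participants, same trial counts).
    """
    if not isinstance(fits, dict):
        fits = {f.spec.label: f for f in fits}
    if not fits:
        raise ValueError("no fits to compare")
    ref = next(iter(fits.values()))
    for name, f in fits.items():
        if len(f.obs) != len(ref.obs) or not (
            f.obs["participant_id"].to_numpy() == ref.obs["participant_id"].to_numpy()
        ).all():
            raise ValueError(
                f"fit {name!r} covers a different dataset than {ref.spec.label!r}"
            )
    loos = {name: _loo_one(f) for name, f in fits.items()}
    rows = []
    for name, res in loos.items():
        k = np.asarray(res.pareto_k)
        rows.append(
            {
                "model": name,
                "elpd": float(res.elpd_loo),
                "se": float(res.se),
                "p_loo": float(res.p_loo),
                "n_high_k": int((k > PARETO_K_WARN).sum()),
            }
        )
    table = pd.DataFrame(rows).set_index("model").sort_values("elpd", ascending=False)
    best = table.index[0]
    # SE of the pairwise elpd difference from the pointwise values.
    best_i = np.asarray(loos[best].loo_i)
    diffs, se_diffs = [], []
    for name in table.index:
        li = np.asarray(loos[name].loo_i)
        diffs.append(float((li - best_i).sum()))
        se_diffs.append(float(np.sqrt(len(li) * np.var(li - best_i))))
    table["elpd_diff"] = diffs
    table["se_diff"] = se_diffs
    return LooResult(table=table)
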