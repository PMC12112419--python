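"""Motivational typology: k-means profiling and exposure-change analysis.

Participants are clustered on their fitted action-model parameters
(bias, gamma, mu, inverse temperature), z-scored with training-set
statistics.  The inverse temperature (and, if used, the probit scale)
enters on its log scale — the model's own unconstrained scale — which
stabilizes the variance of this positive, right-skewed parameter before
z-scoring.  The number of clusters is chosen by mean silhouette over a
k range with multiple k-means restarts.  When k = 4, clusters are named
by centroid signature: most negative bias -> unconditionally selfish; of
the rest, lowest gamma -> cost-sensitive; of the remaining two, higher
mu -> harm-sensitive, lower -> efficiency-sensitive.  New cohorts are
assigned to trained clusters by nearest centroid in the training
normalization space, as when typing a replication sample with clusters
learned on earlier experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .cohort import EnvironmentKind, Profile
from .models import rescale_rating_unit

__all__ = [
    "ClusterModel",
    "fit_clusters",
    "assign",
    "transition_matrix",
    "pre_post_summary",
    "DEFAULT_FEATURES",
]

DEFAULT_FEATURES = ("bias", "gamma", "mu", "inv_temp")

#: Positive, right-skewed features entered on the log scale before z-scoring.
LOG_FEATURES = ("inv_temp", "scale")

#: Cluster names used when k = 4, in signature order.
PROFILE_NAMES = (
    Profile.UNCONDITIONALLY_SELFISH.value,
    Profile.COST_SENSITIVE.value,
    Profile.EFFICIENCY_SENSITIVE.value,
    Profile.HARM_SENSITIVE.value,
)


@dataclass
class ClusterModel:
    """Trained k-means typology with stored normalization."""

    features: tuple[str, ...]
    norm_mean: pd.Series
    norm_sd: pd.Series
    k: int
    centroids: pd.DataFrame          # normalized space, index = cluster name
    labels: pd.Series                # training labels, index = participant_id
    seed: int
    selection: pd.DataFrame = field(default=None, repr=False)  # k, silhouette

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {
            "features": list(self.features),
            "k": int(self.k),
            "seed": int(self.seed),
            "norm_mean": {f: float(self.norm_mean[f]) for f in self.features},
            "norm_sd": {f: float(self.norm_sd[f]) for f in self.features},
        }
        (outdir / "cluster_model.yaml").write_text(yaml.safe_dump(meta))
        self.centroids.to_csv(outdir / "centroids.csv")
        self.labels.rename("cluster").to_csv(outdir / "training_labels.csv")
        if self.selection is not None:
            self.selection.to_csv(outdir / "k_selection.csv", index=False)

    @classmethod
    def load(cls, outdir) -> "ClusterModel":
        outdir = Path(outdir)
        meta = yaml.safe_load((outdir / "cluster_model.yaml").read_text())
        centroids = pd.read_csv(outdir / "centroids.csv", index_col=0)
        labels = pd.read_csv(outdir / "training_labels.csv", index_col=0)["cluster"]
        feats = tuple(meta["features"])
        return cls(
            features=feats,
            norm_mean=pd.Series(meta["norm_mean"])[list(feats)],
            norm_sd=pd.Series(meta["norm_sd"])[list(feats)],
            k=meta["k"],
            centroids=centroids,
            labels=labels,
            seed=meta["seed"],
        )


def _feature_matrix(table: pd.DataFrame, feats) -> np.ndarray:
    X = table[list(feats)].to_numpy(dtype=float).copy()
    for j, f in enumerate(feats):
        if f in LOG_FEATURES:
            X[:, j] = np.log(np.maximum(X[:, j], 1e-12))
    return X


def _zscore(table: pd.DataFrame, mean: pd.Series, sd: pd.Series, feats) -> np.ndarray:
    X = _feature_matrix(table, feats)
    return (X - mean[list(feats)].to_numpy()) / sd[list(feats)].to_numpy()


def _name_clusters(centroids: np.ndarray, feats: tuple[str, ...]) -> list[str]:
    """Map centroid signatures to the four profile names (k = 4 only)."""
    k = centroids.shape[0]
    if k != 4 or not {"bias", "gamma", "mu"} <= set(feats):
        return [f"cluster_{i}" for i in range(k)]
    i_bias, i_gamma, i_mu = (feats.index(f) for f in ("bias", "gamma", "mu"))
    names = [None] * 4
    remaining = list(range(4))
    selfish = min(remaining, key=lambda i: centroids[i, i_bias])
    names[selfish] = Profile.UNCONDITIONALLY_SELFISH.value
    remaining.remove(selfish)
    cost = min(remaining, key=lambda i: centroids[i, i_gamma])
    names[cost] = Profile.COST_SENSITIVE.value
    remaining.remove(cost)
    a, b = remaining
    harm, eff = (a, b) if centroids[a, i_mu] >= centroids[b, i_mu] else (b, a)
    names[harm] = Profile.HARM_SENSITIVE.value
    names[eff] = Profile.EFFICIENCY_SENSITIVE.value
    return names


def fit_clusters(
    params: pd.DataFrame,
    k_range: range | tuple = range(2, 9),
    restarts: int = 50,
    seed: int = 0,
    features: tuple[str, ...] = DEFAULT_FEATURES,
) -> ClusterModel:
    """Silhouette-optimized k-means on z-scored fitted parameters.

    ``params`` must be indexed by participant id (or carry a
    ``participant_id`` column) and contain the feature columns.
    Zero-variance features are dropped with a warning.  The selection
    report (mean silhouette per k) is stored on the model.
    """
    if "participant_id" in params.columns:
        params = params.set_index("participant_id")
    ks = [int(k) for k in k_range]
    if len(params) < 2 * max(ks):
        raise ValueError(
            f"need at least {2 * max(ks)} participants for k up to {max(ks)}"
        )
    feats = []
    for f in features:
        if f not in params.columns:
            raise ValueError(f"missing feature column {f!r}")
        if params[f].std() == 0:
            warnings.warn(f"feature {f!r} has zero variance; dropped")
        else:
            feats.append(f)
    feats = tuple(feats)
    F = pd.DataFrame(_feature_matrix(params, feats), columns=list(feats),
                     index=params.index)
    mean = F.mean()
    sd = F.std(ddof=0)
    X = _zscore(params, mean, sd, feats)

    rows = []
    best = None
    for k in ks:
        if k >= len(params):
            continue
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
        lab = km.fit_predict(X)
        sil = float(silhouette_score(X, lab))
        rows.append({"k": k, "silhouette": sil})
        if best is None or sil > best[0]:
            best = (sil, k, km)
    sil, k, km = best
    selection = pd.DataFrame(rows)
    names = _name_clusters(km.cluster_centers_, feats)
    labels = pd.Series([names[i] for i in km.labels_], index=params.index, name="cluster")
    centroids = pd.DataFrame(km.cluster_centers_, index=names, columns=list(feats))
    if sil < 0.25:
        warnings.warn(f"weak cluster structure: best mean silhouette {sil:.2f}")
    return ClusterModel(
        features=feats, norm_mean=mean, norm_sd=sd, k=k,
        centroids=centroids, labels=labels, seed=seed, selection=selection,
    )


def assign(model: ClusterModel, params: pd.DataFrame) -> pd.Series:
    """Nearest-centroid labels for new participants (training normalization).

    Ties break toward the lowest cluster index (centroid row order).
    """
    if "participant_id" in params.columns:
        params = params.set_index("participant_id")
    missing = [f for f in model.features if f not in params.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {missing}")
    X = _zscore(params, model.norm_mean, model.norm_sd, model.features)
    C = model.centroids.to_numpy(dtype=float)
    d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
    idx = d2.argmin(axis=1)  # argmin takes the first (lowest) index on ties
    return pd.Series(model.centroids.index[idx], index=params.index, name="cluster")


def transition_matrix(
    pre_labels: pd.Series,
    post_labels: pd.Series,
    environment: EnvironmentKind | str | None = None,
) -> pd.DataFrame:
    """Row-normalized percentage matrix of pre -> post cluster assignments.

    Returns a DataFrame whose rows sum to 100 (pre clusters) with an
    ``environment`` attribute in ``.attrs`` and overall stability share in
    ``.attrs["stability"]``.
    """
    pre_labels = pre_labels.sort_index()
    post_labels = post_labels.sort_index()
    if not pre_labels.index.equals(post_labels.index):
        raise ValueError("pre and post labels cover different participants")
    order = [n for n in PROFILE_NAMES if n in set(pre_labels) | set(post_labels)]
    extra = sorted((set(pre_labels) | set(post_labels)) - set(order))
    order += [n for n in extra if n not in order]
    ct = pd.crosstab(pre_labels, post_labels).reindex(
        index=order, columns=order, fill_value=0
    )
    pct = ct.div(ct.sum(axis=1).replace(0, np.nan), axis=0) * 100
    pct.attrs["environment"] = (
        EnvironmentKind(environment).value if environment is not None else None
    )
    pct.attrs["stability"] = float((pre_labels == post_labels).mean() * 100)
    return pct


def pre_post_summary(
    behavior: pd.DataFrame,
    labels: pd.Series,
    environment: EnvironmentKind | str | None = None,
) -> pd.DataFrame:
    """Per-type behavior change after exposure.

    ``behavior`` is a behavior table with phases "pre" and "post"
    containing action and/or judgment rows.  Per participant the change
    in prosocial-action rate and in mean rescaled (0–1) judgment of
    selfish actions is computed, then aggregated by cluster label (mean,
    SD, n).  Participants without both phases or without a label are
    dropped with a warning.
    """
    out = {}
    for kind, col in (("action", "d_prosocial_rate"), ("judgment", "d_judgment")):
        rows = behavior[behavior["kind"] == kind]
        if kind == "judgment":
            rows = rows[rows["judged_decision"] == "selfish"]
        if rows.empty:
            continue
        if kind == "judgment":
            rows = rows.assign(value=rescale_rating_unit(rows["response"].to_numpy()))
        else:
            rows = rows.assign(value=rows["response"])
        means = rows.pivot_table(
            index="participant_id", columns="phase", values="value", aggfunc="mean"
        )
        if not {"pre", "post"} <= set(means.columns):
            continue
        complete = means.dropna(subset=["pre", "post"])
        dropped = len(means) - len(complete)
        if dropped:
            warnings.warn(f"{dropped} participant(s) missing a phase for {kind}; dropped")
        out[col] = complete["post"] - complete["pre"]
    deltas = pd.DataFrame(out)
    deltas = deltas.join(labels.rename("cluster"), how="inner")
    if len(deltas) < len(out.get("d_prosocial_rate", deltas)):
        warnings.warn("some participants had no cluster label; dropped")
    agg = deltas.groupby("cluster").agg(["mean", "std", "count"])
    agg.attrs["environment"] = (
        EnvironmentKind(environment).value if environment is not None else None
    )
    return agg
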