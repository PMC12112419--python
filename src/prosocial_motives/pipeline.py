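"""End-to-end orchestration: simulate -> fit -> compare -> cluster -> expose.

A :class:`RunConfig` (YAML-serializable) fully determines a run; the
config and seeds are echoed into the results directory so every artifact
is regenerable.  Stages are isolated: a failing stage is logged and
downstream stages that depend on it are skipped, while independent
stages continue.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import clustering as clustering_mod
from . import inference, io, selection
from .cohort import EnvironmentKind, Profile
from .models import MODEL_REGISTRY, ModelSpec, build_norm_table, spec_from_name
from .task import Context, build_action_grid, build_judgment_grid

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    seed: int = 0
    outdir: str = "results/run"
    contexts: tuple[str, ...] = (Context.DESTROY.value,)
    profile_counts: dict = field(
        default_factory=lambda: {p.value: n for p, n in cohort_mod.DEFAULT_PROFILE_COUNTS.items()}
    )
    models: tuple[str, ...] = ("cr_bias", "fs", "harm_bias", "kw_bias")
    fit_mode: str = "hierarchical"       # or "map"
    n_em: int = 6
    draws: int = 120
    k_range: tuple[int, int] = (2, 8)
    restarts: int = 50
    environment: str = EnvironmentKind.A_MINUS.value
    shift: dict = field(
        default_factory=lambda: {"bias": -1.0, "logit_gamma": -0.5}
    )
    report: bool = True

    def validate(self) -> None:
        for m in self.models:
            if m not in MODEL_REGISTRY:
                raise ValueError(f"unknown model family {m!r}")
        for c in self.contexts:
            Context(c)
        EnvironmentKind(self.environment)
        for p in self.profile_counts:
            Profile(p)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _counts(cfg: RunConfig) -> dict:
    return {Profile(k): int(v) for k, v in cfg.profile_counts.items()}


STAGE_ORDER = ("simulate", "fit", "compare", "cluster", "expose", "report")


def run_pipeline(config: RunConfig, stop_after: str | None = None) -> dict:
    """Run the pipeline stages; returns a dict of produced artifacts.

    ``stop_after`` truncates the chain after the named stage.  Layout
    under ``config.outdir``: ``config.yaml``, ``data/`` (cohort truth,
    behavior tables, environment feedback), ``fits/<model>/``,
    ``comparison.csv``, ``clusters/``, ``changes/`` and ``report.md``.
    """
    config.validate()
    if stop_after is not None and stop_after not in STAGE_ORDER:
        raise ValueError(f"unknown stage {stop_after!r}")
    enabled = (
        STAGE_ORDER
        if stop_after is None
        else STAGE_ORDER[: STAGE_ORDER.index(stop_after) + 1]
    )
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "data").mkdir(exist_ok=True)
    config.to_yaml(out / "config.yaml")
    artifacts: dict = {}
    failed: set[str] = set()

    def stage(name: str, fn, *deps):
        if name not in enabled:
            return None
        if any(d in failed for d in deps):
            log.warning("skipping stage %s (failed dependency)", name)
            failed.add(name)
            return None
        try:
            artifacts[name] = fn()
            log.info("stage %s done", name)
            return artifacts[name]
        except Exception:
            log.exception("stage %s failed", name)
            failed.add(name)
            return None

    # -- simulate ----------------------------------------------------------
    def simulate():
        cohort = cohort_mod.sample_cohort(counts=_counts(config), seed=config.seed)
        agrid = build_action_grid(config.contexts)
        jgrid = build_judgment_grid(config.contexts)
        actions = cohort_mod.simulate_dataset(cohort, agrid, "action",
                                              seed=config.seed + 1, phase="pre")
        judgments = cohort_mod.simulate_dataset(cohort, jgrid, "judgment",
                                                seed=config.seed + 2, phase="pre")
        cohort.to_csv(out / "data" / "cohort_truth.csv", index=False)
        io.write_behavior_csv(actions, out / "data" / "actions_pre.csv")
        io.write_behavior_csv(judgments, out / "data" / "judgments_pre.csv")
        return {"cohort": cohort, "agrid": agrid, "jgrid": jgrid,
                "actions": actions, "judgments": judgments}

    sim = stage("simulate", simulate)

    # -- fit ----------------------------------------------------------------
    def fit():
        norms = build_norm_table(sim["judgments"], level="group")
        fits = {}
        for name in config.models:
            spec = spec_from_name(name, kind="action",
                                  norms=norms if MODEL_REGISTRY[name]["family"] == "kw" else None)
            if spec.free_delta1 and len(config.contexts) < 2:
                log.info("dropping %s: discount uninformative with one context", name)
                continue
            f = inference.fit_hierarchical(
                sim["actions"], spec, n_em=(config.n_em if config.fit_mode == "hierarchical" else 1),
                draws=config.draws, seed=config.seed + 3,
            )
            f.save(out / "fits" / name)
            fits[name] = f
        return fits

    fits = stage("fit", fit, "simulate")

    # -- compare -------------------------------------------------------------
    def compare_stage():
        res = selection.compare(fits)
        res.table.to_csv(out / "comparison.csv")
        return res

    comparison = stage("compare", compare_stage, "fit")

    # -- cluster -------------------------------------------------------------
    def cluster_stage():
        best = comparison.best if comparison is not None else "cr_bias"
        est = fits[best].estimates
        model = clustering_mod.fit_clusters(
            est, k_range=range(config.k_range[0], config.k_range[1] + 1),
            restarts=config.restarts, seed=config.seed + 4,
        )
        model.save(out / "clusters")
        return model

    cluster_model = stage("cluster", cluster_stage, "compare")

    # -- expose --------------------------------------------------------------
    def expose():
        pool = pd.concat([sim["actions"], sim["judgments"]], ignore_index=True)
        env = cohort_mod.build_environment(pool, config.environment)
        env.feedback.to_csv(out / "data" / "environment_feedback.csv", index=False)
        shifted = cohort_mod.apply_exposure_shift(sim["cohort"], config.shift,
                                                  seed=config.seed + 5)
        post_actions = cohort_mod.simulate_dataset(
            shifted, sim["agrid"], "action", seed=config.seed + 6, phase="post")
        post_judgments = cohort_mod.simulate_dataset(
            shifted, sim["jgrid"], "judgment", seed=config.seed + 7, phase="post")
        io.write_behavior_csv(post_actions, out / "data" / "actions_post.csv")
        io.write_behavior_csv(post_judgments, out / "data" / "judgments_post.csv")

        spec = fits[comparison.best].spec if comparison is not None else ModelSpec(kind="action")
        post_fit = inference.fit_hierarchical(
            post_actions, spec, n_em=config.n_em, draws=0, seed=config.seed + 8)
        pre_labels = clustering_mod.assign(cluster_model, fits[comparison.best].estimates)
        post_labels = clustering_mod.assign(cluster_model, post_fit.estimates)
        trans = clustering_mod.transition_matrix(pre_labels, post_labels,
                                                 config.environment)
        behavior = pd.concat(
            [sim["actions"], sim["judgments"], post_actions, post_judgments],
            ignore_index=True,
        )
        changes = clustering_mod.pre_post_summary(behavior, pre_labels,
                                                  config.environment)
        (out / "changes").mkdir(exist_ok=True)
        trans.to_csv(out / "changes" / "transition_matrix.csv")
        changes.to_csv(out / "changes" / "per_type_changes.csv")
        pre_labels.rename("cluster").to_csv(out / "changes" / "pre_labels.csv")
        post_labels.rename("cluster").to_csv(out / "changes" / "post_labels.csv")
        return {"environment": env, "transition": trans, "changes": changes,
                "pre_labels": pre_labels, "post_labels": post_labels,
                "post_actions": post_actions}

    exposure = stage("expose", expose, "cluster")

    # -- report ---------------------------------------------------------------
    if config.report:
        stage("report", lambda: _write_report(out, config, artifacts), "simulate")

    artifacts["outdir"] = str(out)
    artifacts["failed_stages"] = sorted(failed)
    return artifacts


def _heatmap(ax, table: pd.DataFrame, title: str) -> None:
    im = ax.imshow(table.to_numpy(), origin="lower", cmap="RdYlGn",
                   vmin=0, vmax=1, aspect="auto")
    ax.set_xticks(range(table.shape[1]), table.columns)
    ax.set_yticks(range(table.shape[0]), table.index)
    ax.set_xlabel("bonus")
    ax.set_ylabel("points of B")
    ax.set_title(title, fontsize=9)
    return im


def _write_report(out: Path, config: RunConfig, artifacts: dict) -> str:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lines = ["# Pipeline report", "",
             f"Seed: {config.seed}; contexts: {', '.join(config.contexts)}", ""]
    sim = artifacts.get("simulate")
    if sim:
        actions = sim["actions"]
        rate = actions.pivot_table(index="p_b", columns="bonus", values="response")
        fig, ax = plt.subplots(figsize=(4, 3))
        im = _heatmap(ax, rate, "prosocial action rate")
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(out / "action_heatmap.png", dpi=120)
        plt.close(fig)
        lines += [f"Simulated {actions['participant_id'].nunique()} participants; "
                  f"mean prosocial rate {actions['response'].mean():.3f}",
                  "", "![action rates](action_heatmap.png)", ""]
    comparison = artifacts.get("compare")
    if comparison is not None:
        lines += ["## Model comparison (PSIS-LOO)", "",
                  comparison.table[["elpd", "se", "elpd_diff", "se_diff"]]
                  .round(2).to_markdown(), ""]
    cm = artifacts.get("cluster")
    if cm is not None:
        shares = cm.labels.value_counts(normalize=True).mul(100).round(1)
        lines += ["## Motivational types", "",
                  f"Selected k = {cm.k} by mean silhouette", "",
                  shares.rename("share_%").to_markdown(), ""]
    exp = artifacts.get("expose")
    if exp is not None:
        lines += [f"## Exposure ({config.environment})", "",
                  "Pre -> post cluster transition matrix (%):", "",
                  exp["transition"].round(1).to_markdown(), "",
                  "Per-type behavior change:", "",
                  exp["changes"].round(3).to_markdown(), ""]
        fig, ax = plt.subplots(figsize=(5, 3))
        ch = exp["changes"]
        col = ("d_prosocial_rate", "mean")
        if col in ch.columns:
            ax.bar(ch.index, ch[col].to_numpy())
            ax.axhline(0, color="k", lw=0.8)
            ax.set_ylabel("d prosocial rate (post - pre)")
            ax.tick_params(axis="x", rotation=30)
            fig.tight_layout()
            fig.savefig(out / "change_bars.png", dpi=120)
            lines += ["![per-type change](change_bars.png)", ""]
        plt.close(fig)
    report = "\n".join(lines)
    (out / "report.md").write_text(report)
    return report
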