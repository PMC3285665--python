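"""End-to-end orchestration: generate -> quantify -> features -> cluster -> LDA.

A :class:`RunConfig` fully determines a run (screen layout, effect model,
feature policy, clustering and LDA options, seed); :func:`run_pipeline`
executes the stages in order, persists every intermediate table, and stamps
the report with the seed, a config hash and library versions so any output
can be reproduced byte for byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as _cluster
from . import features as _features
from . import lda as _lda
from . import quantify as _quantify
from . import synth as _synth

logger = logging.getLogger("phenoscreen")


@dataclass
class Finding:
    level: str          # "error" | "warning"
    message: str


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    outdir: str = "phenoscreen_run"
    seed: int = 7
    log_level: str = "INFO"

    # screen layout
    n_probes: int = 100
    n_lines: int = 60
    n_informative: int = 30
    concentrations_nM: tuple[float, ...] = (500.0,)
    channels: tuple[str, ...] = ("TRITC",)
    sites: int = 1
    time_points_h: tuple[float, ...] = (1.0, 48.0)
    replicates: int = 2
    image_shape: tuple[int, int] = (128, 128)

    # effect model
    primary_fold: tuple[float, float] = (2.0, 4.0)
    secondary_fold: tuple[float, float] = (1.5, 2.5)
    line_scatter_sd: float = 0.12
    pixel_noise_sigma: float = 0.15
    batch_sd: float = 0.10
    batch_aligned: bool = True

    # features
    collapse_policy: str = "per_condition"
    baseline_floor: float | None = None     # default: background level + 1
    log2_features: bool = True

    # clustering
    cluster_metric: str = "euclidean"
    cluster_method: str = "average"
    purity_k: int = 9

    # LDA
    alpha_enter: float = 0.150
    alpha_remove: float = 0.150
    max_features: int | None = None
    priors: str = "equal"
    jackknife: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for f in dataclasses.fields(cls):
            v = getattr(cfg, f.name)
            if isinstance(v, list):
                setattr(cfg, f.name, tuple(v))
        return cfg

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def validate_config(cfg: RunConfig) -> list[Finding]:
    """Static checks before running; errors block, warnings inform."""
    out: list[Finding] = []
    err = lambda m: out.append(Finding("error", m))
    warn = lambda m: out.append(Finding("warning", m))

    if not (0 < cfg.alpha_enter < 1 and 0 < cfg.alpha_remove < 1):
        err("alpha-to-enter/remove must lie in (0, 1)")
    if cfg.n_probes < 1 or cfg.n_lines < 2 or cfg.sites < 1 or cfg.replicates < 1:
        err("probe/line/site/replicate counts out of range")
    t = cfg.time_points_h
    if len(t) < 2 or any(b <= a for a, b in zip(t, t[1:])):
        err("time_points_h must be strictly increasing with >= 2 points")
    if cfg.collapse_policy not in _features.COLLAPSE_POLICIES:
        err(f"unknown collapse policy {cfg.collapse_policy!r}")
    if cfg.n_lines > 60:
        err("panel has 60 lines")
    if cfg.priors not in ("equal", "proportional"):
        err("priors must be 'equal' or 'proportional'")

    if not out:
        lines = _synth.nci60_lines(cfg.n_lines)
        counts = pd.Series([c.origin for c in lines]).value_counts()
        if len(counts) < len(_synth.ORIGINS):
            err("not every origin is represented at this n_lines")
        if (counts == 1).any():
            warn(f"single-member origin class present: "
                 f"{sorted(counts[counts == 1].index)} — its line cannot be "
                 f"correctly jackknifed")
        g = len(counts)
        df_cap = cfg.n_lines - g - 1
        if cfg.max_features is not None and cfg.max_features > df_cap:
            warn(f"max_features {cfg.max_features} exceeds the df guard "
                 f"(n - g - 1 = {df_cap}); it will be capped")
    return out


@dataclass
class ReportBundle:
    config: RunConfig
    paths: dict[str, Path] = field(default_factory=dict)
    intensity: pd.DataFrame | None = None
    feature_matrix: _features.FeatureMatrix | None = None
    line_dendrogram: _cluster.Dendrogram | None = None
    probe_dendrogram: _cluster.Dendrogram | None = None
    origin_purity: float | None = None
    stepwise: _lda.StepwiseResult | None = None
    model: _lda.LDAModel | None = None
    classification: _lda.ClassificationMatrix | None = None
    score_points: pd.DataFrame | None = None
    subset_table: pd.DataFrame | None = None
    ground_truth: pd.DataFrame | None = None


def _save_heatmap(matrix: pd.DataFrame, row_order, col_order,
                  path: Path) -> None:
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    fig = Figure(figsize=(8, 6))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    data = matrix.iloc[row_order, col_order]
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="viridis",
                   interpolation="nearest")
    ax.set_xlabel("probes (clustered)")
    ax.set_ylabel("cell lines (clustered)")
    fig.colorbar(im, ax=ax, label="log2 fold change")
    fig.savefig(path, dpi=120)


def _save_score_plot(points: pd.DataFrame, path: Path) -> None:
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    fig = Figure(figsize=(7, 6))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    for origin, sub in points.groupby("true_origin"):
        ax.scatter(sub["score_highest"], sub["score_second"], s=18,
                   label=str(origin))
    ax.set_xlabel("highest LDA score")
    ax.set_ylabel("second-highest LDA score")
    ax.legend(fontsize=7, ncol=2)
    fig.savefig(path, dpi=120)


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """Execute every stage; any stage failure aborts with a tagged error."""
    findings = validate_config(cfg)
    errors = [f.message for f in findings if f.level == "error"]
    for f in findings:
        logger.log(logging.ERROR if f.level == "error" else logging.WARNING,
                   "[config] %s", f.message)
    if errors:
        raise ValueError(f"[config] invalid configuration: {errors}")

    root = Path(cfg.outdir)
    root.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(cfg)
    timings: dict[str, float] = {}

    def stage(name):
        logger.info("stage %s ...", name)
        timings[name] = time.perf_counter()
        return name

    def done(name):
        timings[name] = time.perf_counter() - timings[name]
        logger.info("stage %s done in %.1f s", name, timings[name])

    # ---- generate -------------------------------------------------------
    s = stage("generate")
    design, model = _synth.demo_recipe(
        cfg.seed, n_probes=cfg.n_probes, n_lines=cfg.n_lines,
        n_informative=cfg.n_informative, primary_fold=cfg.primary_fold,
        secondary_fold=cfg.secondary_fold,
        line_scatter_sd=cfg.line_scatter_sd,
        pixel_noise_sigma=cfg.pixel_noise_sigma, batch_sd=cfg.batch_sd,
        batch_aligned=cfg.batch_aligned,
        concentrations=cfg.concentrations_nM, channels=cfg.channels,
        sites=cfg.sites, replicates=cfg.replicates,
        time_points_h=cfg.time_points_h, image_shape=cfg.image_shape)
    try:
        screen = _synth.generate_screen(design, model, cfg.seed,
                                        root / "screen")
    except Exception as exc:
        raise RuntimeError(f"[generate] {exc}") from exc
    bundle.ground_truth = screen.ground_truth
    bundle.paths["manifest"] = screen.root / "manifest.csv"
    done(s)

    # ---- quantify -------------------------------------------------------
    s = stage("quantify")
    try:
        intensity = _quantify.quantify_screen(screen.manifest,
                                              root=screen.root)
    except Exception as exc:
        raise RuntimeError(f"[quantify] {exc}") from exc
    bundle.intensity = intensity
    bundle.paths["intensity"] = root / "intensity.csv"
    intensity.to_csv(bundle.paths["intensity"], index=False)
    done(s)

    # ---- features -------------------------------------------------------
    s = stage("features")
    floor = (cfg.baseline_floor if cfg.baseline_floor is not None
             else model.background_level + 1.0)
    try:
        fm = _features.build_feature_matrix(
            intensity, collapse_policy=cfg.collapse_policy,
            baseline_floor=floor)
    except Exception as exc:
        raise RuntimeError(f"[features] {exc}") from exc
    bundle.feature_matrix = fm
    bundle.paths["features"] = root / "features.csv"
    bundle.paths["origins"] = root / "feature_origins.csv"
    fm.to_csv(bundle.paths["features"], bundle.paths["origins"])
    X = fm.log2() if cfg.log2_features else fm.values
    done(s)

    # ---- cluster --------------------------------------------------------
    s = stage("cluster")
    try:
        dlines = _cluster.hierarchical_cluster(X, "lines",
                                               cfg.cluster_metric,
                                               cfg.cluster_method)
        dprobes = _cluster.hierarchical_cluster(X, "probes",
                                                cfg.cluster_metric,
                                                cfg.cluster_method)
        purity = _cluster.origin_purity(dlines, fm.origins.tolist(),
                                        cfg.purity_k)
    except Exception as exc:
        raise RuntimeError(f"[cluster] {exc}") from exc
    bundle.line_dendrogram, bundle.probe_dendrogram = dlines, dprobes
    bundle.origin_purity = purity
    (root / "lines.nwk").write_text(dlines.to_newick())
    (root / "probes.nwk").write_text(dprobes.to_newick())
    pd.DataFrame({"axis": ["lines"] * dlines.n_leaves
                  + ["probes"] * dprobes.n_leaves,
                  "position": (list(range(dlines.n_leaves))
                               + list(range(dprobes.n_leaves))),
                  "label": dlines.leaf_labels + dprobes.leaf_labels}
                 ).to_csv(root / "leaf_orders.csv", index=False)
    _save_heatmap(X, dlines.leaf_order, dprobes.leaf_order,
                  root / "heatmap.png")
    done(s)

    # ---- lda ------------------------------------------------------------
    s = stage("lda")
    y = fm.origins.to_numpy()
    Xa = X.to_numpy(dtype=float)
    names = list(X.columns)
    try:
        sel = _lda.forward_stepwise_select(Xa, y, cfg.alpha_enter,
                                           cfg.alpha_remove,
                                           cfg.max_features)
        if not sel.selected:
            raise ValueError("stepwise selection is empty")
        model_lda = _lda.fit_lda(Xa, y, sel.selected, cfg.priors,
                                 feature_names=names)
        cm = (_lda.jackknife_classification(Xa, y, sel.selected, cfg.priors,
                                            feature_names=names)
              if cfg.jackknife else
              _lda.resubstitution_classification(Xa, y, sel.selected,
                                                 cfg.priors))
        pts = _lda.score_plot(model_lda, Xa[:, sel.selected], y,
                              ids=list(fm.values.index))
        fam_map = {c: c.split("-")[0] for c in names}
        subsets = _lda.subset_comparison(X, y, fam_map, cfg.alpha_enter,
                                         cfg.alpha_remove, cfg.max_features,
                                         cfg.priors)
    except Exception as exc:
        raise RuntimeError(f"[lda] {exc}") from exc
    bundle.stepwise, bundle.model, bundle.classification = sel, model_lda, cm
    bundle.score_points, bundle.subset_table = pts, subsets
    sel.trace_frame(names).to_csv(root / "stepwise_trace.csv", index=False)
    model_lda.to_json(root / "model.json")
    cm.counts.rename_axis("true_origin").to_csv(root / "classification_matrix.csv")
    pts.to_csv(root / "score_plot.csv", index=False)
    _save_score_plot(pts, root / "score_plot.png")
    subsets.to_csv(root / "subset_comparison.csv", index=False)
    done(s)

    # ---- report metadata ------------------------------------------------
    import phenoscreen
    meta = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": yaml.safe_load(cfg.to_yaml()),
        "versions": {"phenoscreen": phenoscreen.__version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
        "n_images": int(len(screen.manifest)),
        "n_flagged_conditions": int((intensity["flag"] != "ok").sum()),
        "n_features": int(fm.values.shape[1]),
        "n_selected": len(sel.selected),
        "origin_purity_k": cfg.purity_k,
        "origin_purity": purity,
        "jackknife_pct_correct": cm.overall_pct,
        "stage_seconds": {k: round(v, 2) for k, v in timings.items()},
    }
    (root / "run_meta.json").write_text(json.dumps(meta, indent=2))
    cfg.to_yaml(root / "config.yaml")
    logger.info("run complete: jackknifed %% correct = %.1f, purity = %.3f",
                cm.overall_pct, purity)
    return bundle
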