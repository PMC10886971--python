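"""End-to-end orchestration of the ripple-classification analysis.

Stage order: generate -> duration filter -> standardize -> log-transform ->
similarity matrix -> selection -> zero-pad -> train/test split -> CNN
training -> evaluation -> Grad-CAM on correctly classified test events ->
t-SNE embedding of full and partial waveforms -> centroid comparison ->
pairwise-R statistics with ANOVA / Scheffé.

One global seed fans out deterministically to the per-stage seeds, so two
runs with equal configurations produce identical numeric artifacts.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import yaml

from . import io as rio
from .cnn import RippleEpisodeCNN, TrainingConfig, split_dataset
from .embedding import compare_separation, embed, summarize_centroids
from .gradcam import extract_partial, gradcam_heatmap
from .plots import render_heatmap_overlay, render_r_histograms, render_similarity_matrix
from .preprocess import (
    build_similarity_matrix,
    filter_min_duration,
    log_transform,
    select_similar,
    standardize,
    zero_pad,
)
from .stats import pairwise_R, scheffe_posthoc
from .synthetic import GeneratorConfig, generate_dataset
from .waveforms import CATEGORIES, PAD_LENGTH, RippleError, labels_of

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


@dataclass
class PipelineConfig:
    """Serializable configuration for a full pipeline run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_per_category: Dict[str, int] = field(
        default_factory=lambda: {c: 60 for c in CATEGORIES}
    )
    similarity_threshold: float = 0.6
    min_duration_ms: float = 15.0
    pad_length: int = PAD_LENGTH
    training: TrainingConfig = field(default_factory=TrainingConfig)
    test_per_category: int = 10
    gradcam_colormap: str = "viridis"
    tsne_perplexity: float = 30.0
    tsne_max_iter: int = 1000
    stats_alpha: float = 0.05
    out_dir: str = "ripplecam_run"
    seed: int = 0

    # -- seed fan-out -------------------------------------------------------
    @property
    def dataset_seed(self) -> int:
        return self.seed

    @property
    def split_seed(self) -> int:
        return self.seed + 1

    @property
    def init_seed(self) -> int:
        return self.seed + 2

    @property
    def shuffle_seed(self) -> int:
        return self.seed + 3

    @property
    def tsne_seed(self) -> int:
        return self.seed + 4

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"]["duration_range_ms"] = list(self.generator.duration_range_ms)
        d["generator"]["amplitude_scale_range"] = list(
            self.generator.amplitude_scale_range
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        g = dict(d.pop("generator", {}))
        for key in ("duration_range_ms", "amplitude_scale_range"):
            if key in g:
                g[key] = tuple(g[key])
        t = dict(d.pop("training", {}))
        return cls(generator=GeneratorConfig(**g), training=TrainingConfig(**t), **d)

    def save(self, path: PathLike) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: PathLike) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the run report (also written as JSON).

    On a stage failure a :class:`RippleError` naming the stage is raised and
    artifacts written so far are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: List[str] = []
    report: dict = {
        "seeds": {
            "global": config.seed,
            "dataset": config.dataset_seed,
            "split": config.split_seed,
            "init": config.init_seed,
            "shuffle": config.shuffle_seed,
            "tsne": config.tsne_seed,
        },
        "stages": {},
    }

    def emit(name: str, path: Path) -> None:
        artifacts.append(str(path.relative_to(out)))
        logger.info("wrote %s", path)

    try:
        # -- generate -------------------------------------------------------
        events, manifest = generate_dataset(
            config.generator, config.n_per_category, seed=config.dataset_seed
        )
        rio.write_manifest(manifest, out / "manifest.csv")
        emit("manifest", out / "manifest.csv")
        rio.write_waveforms_h5(events, out / "waveforms_raw.h5")
        emit("waveforms", out / "waveforms_raw.h5")
        report["stages"]["generate"] = {"n_events": len(events)}

        # -- preprocess -----------------------------------------------------
        kept = filter_min_duration(events, config.min_duration_ms)
        standardized = []
        for ev in kept:
            try:
                standardized.append(standardize(ev))
            except RippleError as e:
                logger.warning("excluding %s: %s", ev.id, e)
        logged = [log_transform(ev) for ev in standardized]
        matrix = build_similarity_matrix(logged)
        rio.write_similarity_csv(matrix, out / "similarity.csv")
        emit("similarity", out / "similarity.csv")
        render_similarity_matrix(matrix, out / "similarity.png",
                                 config.similarity_threshold)
        emit("similarity_png", out / "similarity.png")
        selection = select_similar(matrix, config.similarity_threshold)
        selection.report.to_csv(out / "selection.csv", index=False)
        emit("selection", out / "selection.csv")
        chosen_ids = set(selection.selected_ids)
        selected = [ev for ev in standardized if ev.id in chosen_ids]
        if len(selected) < 5 * (config.test_per_category + 1):
            raise RippleError(
                f"stage 'select' failed: only {len(selected)} events survived "
                "similarity selection"
            )
        padded = [zero_pad(ev, config.pad_length) for ev in selected]
        report["stages"]["preprocess"] = {
            "n_after_duration_filter": len(kept),
            "n_selected": len(selected),
        }

        # -- split & train --------------------------------------------------
        train_ev, test_ev = split_dataset(
            padded, config.test_per_category, seed=config.split_seed
        )
        tc = dataclasses.replace(config.training, seed=config.shuffle_seed)
        model = RippleEpisodeCNN.from_events(train_ev, init_seed=config.init_seed)
        results = model.fit(tc)
        rio.save_model(results, out / "model.h5")
        emit("model", out / "model.h5")
        results.history.to_csv(out / "history.csv", index=False)
        emit("history", out / "history.csv")
        report["stages"]["train"] = {
            "n_train": len(train_ev),
            "n_test": len(test_ev),
            "final_train_accuracy": float(results.history["accuracy"].iloc[-1]),
            "final_train_loss": float(results.history["loss"].iloc[-1]),
        }

        # -- evaluate -------------------------------------------------------
        from .waveforms import as_matrix

        X_test, y_test = as_matrix(test_ev), labels_of(test_ev)
        ev_report = results.evaluate(X_test, y_test)
        rio.write_json(ev_report.to_dict(), out / "evaluation.json")
        emit("evaluation", out / "evaluation.json")
        report["stages"]["evaluate"] = ev_report.to_dict()

        # -- Grad-CAM on correctly classified test events -------------------
        pred = results.predict(X_test)
        correct_idx = np.flatnonzero(pred == y_test)
        heat_rows = []
        partials = []
        full_correct = []
        for i in correct_idx:
            evi = test_ev[i]
            hm = gradcam_heatmap(results, X_test[i], int(pred[i]), source_id=evi.id)
            heat_rows.append(
                {"id": evi.id, "class": int(pred[i]),
                 **{f"p{j}": v for j, v in enumerate(hm.values)}}
            )
            pw = extract_partial(X_test[i], hm, results.arch.conv_stride,
                                 results.arch.conv_kernel)
            if pw is None:
                continue
            partials.append((evi, pw))
            full_correct.append(evi)
        if not partials:
            raise RippleError("stage 'gradcam' failed: no focus windows extracted")
        import pandas as pd

        pd.DataFrame(heat_rows).to_csv(out / "heatmaps.csv", index=False)
        emit("heatmaps", out / "heatmaps.csv")
        partial_events = [
            evi.with_samples(pw.samples, stage="standardized", n_orig=None,
                             motif_start=None)
            for evi, pw in partials
        ]
        rio.write_waveforms_h5(partial_events, out / "partial_waveforms.h5")
        emit("partials", out / "partial_waveforms.h5")
        ex_ev, _ = partials[0]
        all_heat = [gradcam_heatmap(results, ex_ev.samples, k, source_id=ex_ev.id)
                    for k in range(results.arch.n_classes)]
        render_heatmap_overlay(ex_ev.samples, all_heat, out / "overlay_example.png",
                               results.arch.conv_stride, results.arch.conv_kernel,
                               cmap=config.gradcam_colormap)
        emit("overlay", out / "overlay_example.png")
        report["stages"]["gradcam"] = {"n_correct": int(len(correct_idx)),
                                       "n_partials": len(partials)}

        # -- embeddings & centroid comparison ------------------------------
        n_pts = len(full_correct)
        perp = min(config.tsne_perplexity, max(2.0, (n_pts - 1) / 3.0))
        X_full = np.stack([e.samples for e in full_correct])
        X_part = np.stack([pw.samples for _, pw in partials])
        lbls = [e.category for e in full_correct]
        emb_full = embed(X_full, lbls, perplexity=perp,
                         max_iter=config.tsne_max_iter, seed=config.tsne_seed)
        emb_part = embed(X_part, lbls, perplexity=perp,
                         max_iter=config.tsne_max_iter, seed=config.tsne_seed)
        emb_full.to_frame().to_csv(out / "embedding_full.csv", index=False)
        emit("embedding_full", out / "embedding_full.csv")
        emb_part.to_frame().to_csv(out / "embedding_partial.csv", index=False)
        emit("embedding_partial", out / "embedding_partial.csv")
        sum_full = summarize_centroids(emb_full)
        sum_part = summarize_centroids(emb_part)
        comparison = compare_separation(sum_full, sum_part)
        rio.write_json(
            {"full": sum_full.to_dict(), "partial": sum_part.to_dict(),
             "comparison": comparison.to_dict()},
            out / "separation.json",
        )
        emit("separation", out / "separation.json")
        report["stages"]["embedding"] = {
            "n_points": n_pts,
            "perplexity": perp,
            "n_pairs_increased": comparison.n_increased,
            "n_pairs": comparison.n_pairs,
        }

        # -- pairwise-R statistics ------------------------------------------
        by_cat: Dict[str, list] = {}
        for evs in selected:
            by_cat.setdefault(evs.category, []).append(evs)
        r_values = {}
        summaries = {}
        for cat, evs in by_cat.items():
            if len(evs) < 2:
                continue
            rset = pairwise_R(evs)
            r_values[cat] = rset.values
            summaries[cat] = {
                "mean": float(rset.values.mean()),
                "sem": float(rset.values.std(ddof=1) / np.sqrt(rset.values.size)),
                "n_pairs": int(rset.n_pairs),
            }
        anova = scheffe_posthoc(r_values, alpha=config.stats_alpha)
        rio.write_json(
            {
                "groups": summaries,
                "anova": {"F": anova.F, "df1": anova.df1, "df2": anova.df2,
                          "p_value": anova.p_value},
                "scheffe": anova.scheffe.to_dict(orient="records"),
            },
            out / "pairwise_stats.json",
        )
        emit("stats", out / "pairwise_stats.json")
        render_r_histograms(r_values, out / "r_histograms.png")
        emit("r_histograms", out / "r_histograms.png")
        report["stages"]["stats"] = {"anova_F": anova.F, "anova_p": anova.p_value}

    except RippleError:
        report["artifacts"] = artifacts
        rio.write_json(report, out / "run_report.json")
        raise

    report["artifacts"] = artifacts
    rio.write_json(report, out / "run_report.json")
    return report
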