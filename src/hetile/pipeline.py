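"""End-to-end orchestration of the three experiments.

``run_experiment_direct`` trains tile classifiers straight from pixels for
every configured trait and writes per-set metrics plus heterogeneity maps
for test slides. ``run_experiment_encoded`` sweeps the autoencoder family,
classifies from latent vectors at each dimension (with a no-encoder
baseline), and writes accuracy-vs-dimension summaries with confidence
intervals. ``run_experiment_inertia`` computes the permutation-null
inertia summary per (trait, latent dimension).

All randomness flows from the config's master seed through named stage
seeds; outputs are CSV files with provenance sidecars, written only inside
the given work directory.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .autoencoder import (Autoencoder, AutoencoderSpec, build_autoencoder,
                          encode_tiles, train_autoencoder)
from .classifier import ClassifierConfig, TileClassifier, predict_tiles, train_classifier
from .config import RunConfig, write_sidecar
from .evaluation import assemble_map, compute_metrics, render_map
from .inertia import run_inertia_study, sampling_protocol, shuffle_null
from .labels import (LabelScheme, balance_downsample, binarize_trait, grouped_split,
                     ood_bins, trinary_bins)
from .synthetic import CohortSpec, SlideRecord, TraitSpec, generate_cohort
from .tiling import Tile, tile_slide

__all__ = [
    "build_cohort",
    "tile_cohort",
    "trait_scheme",
    "assemble_sets",
    "run_experiment_direct",
    "run_experiment_encoded",
    "run_experiment_inertia",
]

log = logging.getLogger("hetile")

OOD_LABEL = {"ood0": 0, "ood1": 1}


def build_cohort(config: RunConfig) -> tuple[list[SlideRecord], pd.DataFrame]:
    spec = CohortSpec(
        n_patients=config.n_patients,
        timepoints_per_patient=config.timepoints_per_patient,
        image_height=config.image_height, image_width=config.image_width,
        tile_size=config.tile_size,
        trait_specs=tuple(TraitSpec(**t) for t in config.traits),
        background_fraction=config.background_fraction,
        heterogeneity_patch_fraction=config.heterogeneity_patch_fraction,
        seed=config.stage_seed("cohort"))
    return generate_cohort(spec)


def tile_cohort(records: list[SlideRecord], config: RunConfig) -> dict[str, list[Tile]]:
    return {r.slide_id: tile_slide(r, tile_size=config.tile_size,
                                   max_background=config.max_background,
                                   whiteness_threshold=config.whiteness_threshold)
            for r in records}


def trait_scheme(table: pd.DataFrame, trait: str, kind: str,
                 config: RunConfig) -> LabelScheme:
    values = dict(zip(table.slide_id, table[trait].astype(float)))
    if kind == "binary":
        return binarize_trait(values, trait=trait, kind="binary")
    scheme = binarize_trait(values, trait=trait, low_q=config.low_q,
                            high_q=config.high_q)
    return ood_bins(values, scheme)


def assemble_sets(tiles_by_slide: dict[str, list[Tile]], scheme: LabelScheme,
                  config: RunConfig, stage: str = "split"
                  ) -> dict[str, tuple[list[Tile], np.ndarray]]:
    """Slide-grouped split, tile-label inheritance, per-set balancing.

    Returns {set_name: (tiles, labels)}; every set with both classes is
    downsampled so label groups have equal tile counts.
    """
    split = grouped_split(scheme, fractions=config.split_fractions,
                          seed=config.stage_seed(stage))
    sets: dict[str, tuple[list[Tile], np.ndarray]] = {}
    for set_name in ("train", "val", "test", "ood"):
        groups: dict[str, list[Tile]] = {}
        for slide in split.slides_in(set_name):
            b = scheme.slide_bins[slide]
            label = OOD_LABEL.get(b, None)
            label = int(b) if label is None else label
            groups.setdefault(str(label), []).extend(tiles_by_slide.get(slide, []))
        groups = {k: v for k, v in groups.items() if v}
        if not groups:
            continue
        if len(groups) >= 2:
            groups = balance_downsample(
                groups, seed=config.stage_seed(f"{stage}:{set_name}:balance"))
        tiles = [t for k in sorted(groups) for t in groups[k]]
        labels = np.array([int(k) for k in sorted(groups) for _ in groups[k]])
        sets[set_name] = (tiles, labels)
    return sets


def _metric_row(report, trait: str, extra: dict | None = None) -> dict:
    (tn, fp), (fn, tp) = report.confusion
    row = {"trait": trait, "set": report.set_name, "n_tiles": report.n_tiles,
           "accuracy": report.accuracy, "auc_roc": report.auc_roc, "f1": report.f1,
           "tn": int(tn), "fp": int(fp), "fn": int(fn), "tp": int(tp),
           "accuracy_ci_low": report.accuracy_ci95[0],
           "accuracy_ci_high": report.accuracy_ci95[1]}
    row.update(extra or {})
    return row


def _evaluate_sets(model: TileClassifier, sets, trait: str, extra: dict | None = None,
                   to_inputs=lambda tiles: tiles) -> tuple[list[dict], list[dict]]:
    """Metric rows plus flat per-tile prediction records for all eval sets."""
    rows, pred_rows = [], []
    for set_name in ("val", "test", "ood"):
        if set_name not in sets:
            continue
        tiles, labels = sets[set_name]
        preds = predict_tiles(model, to_inputs(tiles), truths=labels)
        rows.append(_metric_row(compute_metrics(preds, set_name=set_name),
                                trait, extra))
        pred_rows.extend({"slide_id": p.slide_id, "row": p.row, "col": p.col,
                          "score": p.score, "label_hat": p.label_hat,
                          "truth": p.truth, "set": set_name}
                         for p in preds)
    return rows, pred_rows


def run_experiment_direct(config: RunConfig, out_dir: str | Path,
                          cohort=None) -> pd.DataFrame:
    """Raw-tile classification for each trait; metrics CSV + test-slide maps."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, table = cohort if cohort is not None else build_cohort(config)
    tiles_by_slide = tile_cohort(records, config)
    rows = []
    for tdef in config.traits:
        trait, kind = tdef["name"], tdef.get("kind", "continuous")
        log.info("direct classification: trait %s", trait)
        scheme = trait_scheme(table, trait, kind, config)
        sets = assemble_sets(tiles_by_slide, scheme, config, stage=f"direct:{trait}")
        cfg = ClassifierConfig(input_kind="raw_tile", backbone="smallcnn",
                               epochs=config.clf_epochs,
                               seed=config.stage_seed(f"direct:{trait}:clf"))
        res = train_classifier(cfg, sets["train"][0], sets["train"][1],
                               sets["val"][0], sets["val"][1])
        metric_rows, pred_rows = _evaluate_sets(res.model, sets, trait)
        rows.extend(metric_rows)
        pd.DataFrame(pred_rows).to_csv(out / f"predictions_{trait}.csv", index=False)
        # heterogeneity maps over the full (unbalanced) test slides
        map_dir = out / "maps" / trait
        split = grouped_split(scheme, fractions=config.split_fractions,
                              seed=config.stage_seed(f"direct:{trait}"))
        grid_rows = []
        for slide in split.slides_in("test"):
            tiles = tiles_by_slide.get(slide, [])
            if not tiles:
                continue
            bulk = int(scheme.slide_bins[slide])
            preds = predict_tiles(res.model, tiles, truths=[bulk] * len(tiles))
            hmap = assemble_map(preds, bulk_label=bulk)
            render_map(hmap, map_dir / f"{slide}_{trait}.png")
            for (r, c), v in np.ndenumerate(hmap.grid):
                grid_rows.append({"slide_id": slide, "row": r, "col": c,
                                  "label": int(v),
                                  "per_slide_accuracy": hmap.per_slide_accuracy})
        if grid_rows:
            pd.DataFrame(grid_rows).to_csv(map_dir / "grids.csv", index=False)
    df = pd.DataFrame(rows)
    path = out / "direct_metrics.csv"
    df.to_csv(path, index=False)
    write_sidecar(path, config)
    return df


def _train_family(train_tiles, val_tiles, config: RunConfig
                  ) -> dict[int, Autoencoder]:
    models = {}
    for dim in config.latent_dims:
        spec = AutoencoderSpec.from_latent_dim(dim, epochs=config.ae_epochs)
        model = build_autoencoder(spec, seed=config.stage_seed(f"ae:{dim}"))
        log.info("training autoencoder, latent dim %d", dim)
        train_autoencoder(model, train_tiles, val_tiles,
                          seed=config.stage_seed(f"ae:{dim}:train"))
        models[dim] = model
    return models


def run_experiment_encoded(config: RunConfig, out_dir: str | Path,
                           cohort=None, trait: str | None = None) -> pd.DataFrame:
    """Latent-dimension sweep for one trait (default: the first configured)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, table = cohort if cohort is not None else build_cohort(config)
    tiles_by_slide = tile_cohort(records, config)
    tdef = next(t for t in config.traits
                if trait is None or t["name"] == trait)
    trait, kind = tdef["name"], tdef.get("kind", "continuous")
    scheme = trait_scheme(table, trait, kind, config)
    sets = assemble_sets(tiles_by_slide, scheme, config, stage=f"encoded:{trait}")
    rows = []
    # no-encoder baseline: the direct smallcnn on the same sets
    base_cfg = ClassifierConfig(input_kind="raw_tile", backbone="smallcnn",
                                epochs=config.clf_epochs,
                                seed=config.stage_seed(f"encoded:{trait}:base"))
    base = train_classifier(base_cfg, sets["train"][0], sets["train"][1],
                            sets["val"][0], sets["val"][1])
    rows.extend(_evaluate_sets(base.model, sets, trait,
                               extra={"latent_dim": "none"})[0])
    models = _train_family(sets["train"][0], sets["val"][0], config)
    for dim, model in models.items():
        latents = {name: encode_tiles(model, tiles)
                   for name, (tiles, _) in sets.items()}
        cfg = ClassifierConfig(input_kind="latent", latent_dim=dim, backbone="mlp",
                               epochs=config.clf_epochs,
                               seed=config.stage_seed(f"encoded:{trait}:{dim}"))
        res = train_classifier(cfg, latents["train"], sets["train"][1],
                               latents["val"], sets["val"][1])
        for set_name in ("val", "test", "ood"):
            if set_name not in sets:
                continue
            preds = predict_tiles(res.model, latents[set_name],
                                  truths=sets[set_name][1])
            rows.append(_metric_row(compute_metrics(preds, set_name=set_name),
                                    trait, {"latent_dim": dim}))
    df = pd.DataFrame(rows)
    path = out / "encoded_metrics.csv"
    df.to_csv(path, index=False)
    write_sidecar(path, config)
    # accuracy-vs-dimension summary (validation and test), CI bounds included
    summary = df[df["set"].isin(["val", "test"])][
        ["trait", "set", "latent_dim", "n_tiles", "accuracy",
         "accuracy_ci_low", "accuracy_ci_high"]]
    summary.to_csv(out / "accuracy_vs_dim.csv", index=False)
    return df


def run_experiment_inertia(config: RunConfig, out_dir: str | Path,
                           cohort=None) -> pd.DataFrame:
    """Permutation-null inertia summary per (trait, dim), plus histograms."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, table = cohort if cohort is not None else build_cohort(config)
    tiles_by_slide = tile_cohort(records, config)
    all_tiles = [t for tiles in tiles_by_slide.values() for t in tiles]
    rng = np.random.default_rng(config.stage_seed("inertia:ae-sample"))
    order = rng.permutation(len(all_tiles))
    n_val = max(1, len(all_tiles) // 10)
    ae_val = [all_tiles[i] for i in order[:n_val]]
    ae_train = [all_tiles[i] for i in order[n_val:]]
    models = _train_family(ae_train, ae_val, config)
    latents_by_dim = {dim: encode_tiles(model, all_tiles)
                      for dim, model in models.items()}
    schemes = {}
    for tdef in config.traits:
        trait, kind = tdef["name"], tdef.get("kind", "continuous")
        values = dict(zip(table.slide_id, table[trait].astype(float)))
        schemes[trait] = trinary_bins(values, trait=trait, kind=kind)
    df = run_inertia_study(latents_by_dim, schemes,
                           rounds=config.inertia_rounds,
                           n_permutations=config.inertia_permutations,
                           images_per_label=config.images_per_label,
                           tiles_per_image=config.tiles_per_image,
                           seed=config.stage_seed("inertia:study"))
    path = out / "inertia.csv"
    df.to_csv(path, index=False)
    write_sidecar(path, config)
    # one null-distribution histogram per (trait, dim), actual J as a line
    for trait, scheme in schemes.items():
        for dim in config.latent_dims:
            inp = sampling_protocol(
                latents_by_dim[dim], scheme,
                images_per_label=config.images_per_label,
                tiles_per_image=config.tiles_per_image,
                seed=config.stage_seed(f"inertia:plot:{trait}:{dim}"))
            res = shuffle_null(inp, n_permutations=config.inertia_permutations,
                               seed=config.stage_seed(f"inertia:plotnull:{trait}:{dim}"))
            fig, ax = plt.subplots(figsize=(5, 3.2))
            ax.hist(res.null_values, bins=20, color="steelblue", alpha=0.8)
            ax.axvline(res.J_actual, color="red", lw=2)
            ax.set_xlabel("inertia J under shuffled slide labels")
            ax.set_ylabel("count")
            ax.set_title(f"{trait}, latent dim {dim} "
                         f"(percent above = {res.percent_above:.0f}%)")
            fig.tight_layout()
            fig.savefig(out / f"inertia_null_{trait}_dim{dim}.png", dpi=100)
            plt.close(fig)
    summary = (df.groupby(["trait", "dim"])["percent_above"]
               .mean().reset_index(name="mean_percent_above"))
    summary.to_csv(out / "inertia_summary.csv", index=False)
    return df
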