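"""Metrics against brute-force oracles; heterogeneity map assembly/rendering.

The AUC oracle is the tie-corrected Mann-Whitney formulation:
U = sum of positive-class ranks minus n1(n1+1)/2, with midranks for ties;
AUC = U / (n0 * n1).
"""

import numpy as np
import pytest
from PIL import Image
from scipy import stats

from hetile.classifier import TilePrediction
from hetile.evaluation import MISSING, assemble_map, compute_metrics, render_map


def _pred(truth, label_hat, score, slide="S0", row=0, col=0):
    return TilePrediction(slide_id=slide, row=row, col=col, score=score,
                          label_hat=label_hat, truth=truth)


def _random_preds(rng, n):
    truth = rng.integers(0, 2, size=n)
    score = np.round(rng.random(n), 2)         # rounding forces score ties
    return [_pred(int(t), int(s >= 0.5), float(s), row=i)
            for i, (t, s) in enumerate(zip(truth, score))]


def brute_force_metrics(preds):
    tp = sum(1 for p in preds if p.truth == 1 and p.label_hat == 1)
    tn = sum(1 for p in preds if p.truth == 0 and p.label_hat == 0)
    fp = sum(1 for p in preds if p.truth == 0 and p.label_hat == 1)
    fn = sum(1 for p in preds if p.truth == 1 and p.label_hat == 0)
    acc = (tp + tn) / len(preds)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return acc, f1, np.array([[tn, fp], [fn, tp]])


def mann_whitney_auc(preds):
    scores = np.array([p.score for p in preds])
    truth = np.array([p.truth for p in preds])
    ranks = stats.rankdata(scores)             # midranks under ties
    n1 = int(truth.sum())
    n0 = len(truth) - n1
    u = ranks[truth == 1].sum() - n1 * (n1 + 1) / 2
    return u / (n0 * n1)


def test_perfect_predictions():
    preds = [_pred(t, t, float(t), row=i) for i, t in enumerate([0] * 5 + [1] * 5)]
    rep = compute_metrics(preds)
    assert rep.accuracy == 1.0 and rep.f1 == 1.0
    assert rep.confusion[0, 1] == 0 and rep.confusion[1, 0] == 0
    assert rep.confusion.sum() == rep.n_tiles == 10


def test_constant_scores_give_auc_half():
    preds = [_pred(t, 1, 0.7, row=i) for i, t in enumerate([0, 1, 0, 1, 1])]
    assert compute_metrics(preds).auc_roc == pytest.approx(0.5)


def test_printed_toy_confusion():
    # 4 TP, 2 TN, 1 FP, 1 FN -> accuracy 0.75, F1 = 2*4/(2*4+1+1) = 0.8
    preds = ([_pred(1, 1, 0.9, row=i) for i in range(4)] +
             [_pred(0, 0, 0.1, row=4 + i) for i in range(2)] +
             [_pred(0, 1, 0.8, row=6), _pred(1, 0, 0.2, row=7)])
    rep = compute_metrics(preds)
    assert rep.accuracy == pytest.approx(0.75)
    assert rep.f1 == pytest.approx(0.8)
    assert rep.confusion.tolist() == [[2, 1], [1, 4]]


def test_single_class_truth_gives_undefined_auc():
    preds = [_pred(1, 1, 0.9, row=i) for i in range(4)]
    rep = compute_metrics(preds)
    assert np.isnan(rep.auc_roc) and rep.accuracy == 1.0


def test_metrics_match_brute_force_oracle_on_random_instances():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        n = int(rng.integers(4, 40))
        preds = _random_preds(rng, n)
        truth = {p.truth for p in preds}
        if truth != {0, 1}:
            continue
        rep = compute_metrics(preds)
        acc, f1, conf = brute_force_metrics(preds)
        assert rep.accuracy == pytest.approx(acc, abs=1e-12)
        assert rep.f1 == pytest.approx(f1, abs=1e-12)
        assert np.array_equal(rep.confusion, conf)
        assert rep.auc_roc == pytest.approx(mann_whitney_auc(preds), abs=1e-9)


def test_ci_width_shrinks_like_sqrt_n():
    rng = np.random.default_rng(1)
    preds = _random_preds(rng, 1600)
    widths = {}
    for n in (100, 400, 1600):
        rep = compute_metrics(preds[:n])
        widths[n] = rep.accuracy_ci95[1] - rep.accuracy_ci95[0]
    assert widths[400] < widths[100] and widths[1600] < widths[400]
    # nested fourfold subsamples roughly halve the width
    assert widths[100] / widths[400] == pytest.approx(2.0, rel=0.35)


def test_exact_ci_option_contains_point_estimate():
    preds = [_pred(1, 1, 0.9, row=i) for i in range(6)] + [_pred(0, 0, 0.1, row=9)]
    rep = compute_metrics(preds, exact_ci=True)
    lo, hi = rep.accuracy_ci95
    assert 0.0 <= lo <= rep.accuracy <= hi <= 1.0


def test_assemble_map_accuracy_and_errors():
    preds = [_pred(1, 1 if i < 9 else 0, 0.9, slide="S7", row=i // 4, col=i % 4)
             for i in range(10)]
    hmap = assemble_map(preds, bulk_label=1)
    assert hmap.per_slide_accuracy == pytest.approx(0.9)
    assert (hmap.grid != MISSING).sum() == 10
    # per-slide accuracy equals the cellwise indicator mean, by scan
    agree = sum(1 for (r, c), v in np.ndenumerate(hmap.grid)
                if v != MISSING and v == 1)
    assert hmap.per_slide_accuracy == agree / 10

    with pytest.raises(ValueError, match="no tiles"):
        assemble_map([], bulk_label=0)
    with pytest.raises(ValueError, match="duplicate"):
        assemble_map([_pred(1, 1, 0.9, slide="S7"),
                      _pred(1, 0, 0.1, slide="S7")], bulk_label=1)
    with pytest.raises(ValueError, match="multiple slides"):
        assemble_map([_pred(1, 1, 0.9, slide="A"),
                      _pred(1, 1, 0.9, slide="B", row=1)], bulk_label=1)


def test_render_map_geometry_and_palette(tmp_path):
    preds = [_pred(1, 1, 0.9, slide="S1", row=r, col=c)
             for r in range(2) for c in range(2)]
    hmap = assemble_map(preds, bulk_label=1)
    p = render_map(hmap, tmp_path / "m.png", cell_size=8)
    img = np.asarray(Image.open(p))
    assert img.shape == (16, 16, 3)
    assert (img == (247, 214, 26)).all(axis=-1).all()     # uniform yellow
    # palette swap inverts colors only, geometry unchanged
    p2 = render_map(hmap, tmp_path / "m2.png", cell_size=8,
                    palette={1: (38, 70, 183), 0: (247, 214, 26)})
    img2 = np.asarray(Image.open(p2))
    assert img2.shape == img.shape
    assert (img2 == (38, 70, 183)).all(axis=-1).all()


def test_discordant_cells_overlap_planted_patch_beyond_chance():
    """Tile predictions that disagree with the bulk label should sit on the
    heterogeneity patch, not at random positions (Jaccard vs permuted cells)."""
    from hetile.synthetic import CohortSpec, TraitSpec, generate_cohort
    from hetile.tiling import tile_slide
    spec = CohortSpec(n_patients=1, timepoints_per_patient=1,
                      image_height=640, image_width=640,
                      trait_specs=(TraitSpec("K", signal_strength=1.0, noise_sd=0.0),),
                      background_fraction=0.0,
                      heterogeneity_patch_fraction=0.3, seed=13)
    records, _ = generate_cohort(spec)
    r = records[0]
    tiles = tile_slide(r)
    bulk_label = int(float(np.mean(r.truth_map)) > 50.0)
    # a predictor that reads the local truth level with slight label noise;
    # patch cells = tiles whose truth-level label disagrees with the bulk
    rng = np.random.default_rng(3)
    preds, patch_cells = [], set()
    for t in tiles:
        block = r.truth_map[t.row * 128:(t.row + 1) * 128,
                            t.col * 128:(t.col + 1) * 128]
        level = float(np.mean(block))
        label = int(level > 50.0)
        if label != bulk_label:
            patch_cells.add((t.row, t.col))
        if rng.random() < 0.05:
            label = 1 - label
        preds.append(TilePrediction(r.slide_id, t.row, t.col,
                                    score=float(label), label_hat=label, truth=-1))
    assert 0 < len(patch_cells) < len(preds)
    hmap = assemble_map(preds, bulk_label=bulk_label)
    discordant = {(r_, c_) for (r_, c_), v in np.ndenumerate(hmap.grid)
                  if v != MISSING and v != bulk_label}
    cells = [(r_, c_) for (r_, c_), v in np.ndenumerate(hmap.grid) if v != MISSING]

    def jaccard(a, b):
        return len(a & b) / max(len(a | b), 1)

    observed = jaccard(discordant, patch_cells)
    null = []
    for _ in range(200):
        perm = rng.permutation(len(cells))[:len(discordant)]
        null.append(jaccard({cells[i] for i in perm}, patch_cells))
    assert observed > np.quantile(null, 0.95)
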