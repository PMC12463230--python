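"""Inertia of latent representations under a labeling, with a slide-level
permutation null.

The statistic is

    J(C) = (1/m) * sum_i || x_i - mu(C(x_i)) ||_2

the mean *unsquared* Euclidean distance of each tile's latent vector x_i
to the centroid mu of its class under the binning C — deliberately not the
squared-distance inertia k-means minimizes (a flag offers the squared
variant for comparison). Lower J means tighter classes.

The null shuffles labels at the slide (whole-image) level: a random
permutation of the slide labels is applied so all tiles of a slide move
together and label proportions are preserved; centroids are recomputed for
every permutation. The summary is the percentage of null draws whose J is
strictly greater than the actual J.

The sampling protocol draws, per class, a fixed number of slides and a
fixed number of tiles per slide (both without replacement); a study
repeats this over many rounds with sub-seeds derived from a master seed,
redrawing both the sample and the permutations each round.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autoencoder import LatentVector
from .labels import LabelScheme

__all__ = [
    "InertiaInput",
    "InertiaResult",
    "inertia_J",
    "shuffle_null",
    "sampling_protocol",
    "run_inertia_study",
]


@dataclass
class InertiaInput:
    X: np.ndarray                  # (m, d) latent matrix, row i = tile i
    C: np.ndarray                  # (m,) integer class per tile
    tile_slide: np.ndarray         # (m,) slide id per tile

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.C = np.asarray(self.C)
        self.tile_slide = np.asarray(self.tile_slide)
        if self.X.ndim != 2 or self.X.shape[0] < 2 or self.X.shape[1] < 1:
            raise ValueError("X must be (m >= 2, d >= 1)")
        if len(self.C) != len(self.X) or len(self.tile_slide) != len(self.X):
            raise ValueError("C and tile_slide must align with X rows")
        if not np.isfinite(self.X).all():
            raise ValueError("non-finite entries in X")


@dataclass
class InertiaResult:
    J_actual: float
    null_values: np.ndarray
    percent_above: float
    n_permutations: int
    seed: int


def inertia_J(X: np.ndarray, C: np.ndarray, squared: bool = False) -> float:
    """Mean Euclidean distance of each row to its class centroid.

    ``squared=True`` gives the classical k-means within-class inertia
    (mean squared distance) instead.
    """
    X = np.asarray(X, dtype=float)
    C = np.asarray(C)
    if not np.isfinite(X).all():
        raise ValueError("non-finite entries in X")
    classes, inv, counts = np.unique(C, return_inverse=True, return_counts=True)
    if (counts == 0).any():
        raise ValueError("empty class")
    sums = np.zeros((len(classes), X.shape[1]))
    np.add.at(sums, inv, X)
    centroids = sums / counts[:, None]
    sq = ((X - centroids[inv]) ** 2).sum(axis=1)
    return float(np.mean(sq if squared else np.sqrt(sq)))


def _slide_label_table(C: np.ndarray, tile_slide: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique slides, their (consistent) labels, and each tile's slide index."""
    slides, slide_idx = np.unique(tile_slide, return_inverse=True)
    slide_labels = np.empty(len(slides), dtype=C.dtype)
    for k in range(len(slides)):
        labs = np.unique(C[slide_idx == k])
        if len(labs) != 1:
            raise ValueError(f"slide {slides[k]!r} carries inconsistent labels {labs}")
        slide_labels[k] = labs[0]
    return slides, slide_labels, slide_idx


def permuted_tile_labels(slide_labels: np.ndarray, slide_idx: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """One null draw: permute labels among slides, broadcast to tiles."""
    perm = rng.permutation(len(slide_labels))
    return slide_labels[perm][slide_idx]


def shuffle_null(inp: InertiaInput, n_permutations: int = 100, seed: int = 0,
                 squared: bool = False) -> InertiaResult:
    """Slide-level label-shuffling null for J(C).

    Each permutation permutes the slide labels uniformly at random (the
    identity permutation is allowed), assigns every tile its slide's new
    label, recomputes centroids, and records J. ``percent_above`` counts
    null draws strictly greater than the actual J.
    """
    slides, slide_labels, slide_idx = _slide_label_table(inp.C, inp.tile_slide)
    if len(slides) < 2:
        raise ValueError("need at least 2 slides to shuffle")
    rng = np.random.default_rng(seed)
    j_actual = inertia_J(inp.X, inp.C, squared=squared)
    null = np.empty(n_permutations)
    for p in range(n_permutations):
        null[p] = inertia_J(inp.X, permuted_tile_labels(slide_labels, slide_idx, rng),
                            squared=squared)
    percent_above = 100.0 * float(np.sum(null > j_actual)) / n_permutations
    return InertiaResult(J_actual=j_actual, null_values=null,
                         percent_above=percent_above,
                         n_permutations=n_permutations, seed=seed)


def sampling_protocol(latents: list[LatentVector], scheme: LabelScheme,
                      images_per_label: int = 5, tiles_per_image: int = 100,
                      seed: int = 0) -> InertiaInput:
    """Draw the study sample: per class, slides then tiles, without replacement."""
    by_slide: dict[str, list[LatentVector]] = {}
    for lv in latents:
        by_slide.setdefault(lv.slide_id, []).append(lv)
    class_bins = sorted({b for b in scheme.slide_bins.values()
                         if b not in ("ood0", "ood1", "excluded")})
    rng = np.random.default_rng(seed)
    rows, labels, slide_of = [], [], []
    for b in class_bins:
        slides = sorted(s for s in scheme.slides_in(b) if s in by_slide)
        if len(slides) < images_per_label:
            raise ValueError(f"class {b!r} has {len(slides)} slides with encodings, "
                             f"need {images_per_label}")
        chosen = rng.choice(len(slides), size=images_per_label, replace=False)
        for si in sorted(chosen):
            slide = slides[si]
            tiles = by_slide[slide]
            if len(tiles) < tiles_per_image:
                raise ValueError(f"slide {slide!r} has {len(tiles)} encoded tiles, "
                                 f"need {tiles_per_image}")
            pick = rng.choice(len(tiles), size=tiles_per_image, replace=False)
            for ti in sorted(pick):
                rows.append(tiles[ti].values)
                labels.append(b)
                slide_of.append(slide)
    return InertiaInput(X=np.stack(rows), C=np.array(labels),
                        tile_slide=np.array(slide_of))


def run_inertia_study(latents_by_dim: dict[int, list[LatentVector]],
                      schemes: dict[str, LabelScheme],
                      rounds: int = 100, n_permutations: int = 100,
                      images_per_label: int = 5, tiles_per_image: int = 100,
                      seed: int = 0) -> pd.DataFrame:
    """Percent-above summary per (trait, latent dim) over repeated rounds.

    Each round redraws the slide/tile sample and the permutations from
    independent sub-seeds of the master seed. Returns one row per
    (trait, dim, round) with J_actual and percent_above.
    """
    records = []
    for trait, scheme in schemes.items():
        for dim, latents in latents_by_dim.items():
            ss = np.random.SeedSequence([seed, zlib.crc32(trait.encode()), dim])
            round_seeds = ss.generate_state(2 * rounds)
            for r in range(rounds):
                inp = sampling_protocol(
                    latents, scheme, images_per_label=images_per_label,
                    tiles_per_image=tiles_per_image,
                    seed=int(round_seeds[2 * r] % (2 ** 31)))
                res = shuffle_null(inp, n_permutations=n_permutations,
                                   seed=int(round_seeds[2 * r + 1] % (2 ** 31)))
                records.append({"trait": trait, "dim": dim, "round": r,
                                "J_actual": res.J_actual,
                                "percent_above": res.percent_above})
    return pd.DataFrame(records)
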