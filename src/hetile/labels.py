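"""Slide-level label schemes and slide-grouped splits.

Continuous traits are binarized by quantiles: values at or below the 20th
percentile are class 0 and values at or above the 80th are class 1, with
an out-of-distribution (OOD) band — (q20, q30] labeled ``ood0`` and
[q70, q80) labeled ``ood1`` — reserved for generalization checks. A
trinary scheme (cuts at the 33rd/66th percentiles) serves the inertia
analysis. All tiles of a slide inherit the slide's bin, so splits are
drawn at the slide level and stratified by bin; balanced sets are produced
by downsampling every label group to the smallest group's size.

Quantiles use inclusive linear interpolation between order statistics
(numpy's default); a value exactly at a cut goes to the lower bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabelScheme",
    "SplitAssignment",
    "binarize_trait",
    "ood_bins",
    "trinary_bins",
    "grouped_split",
    "balance_downsample",
    "shuffled_scheme",
]

BINARY_BINS = ("0", "1", "ood0", "ood1", "excluded")


@dataclass
class LabelScheme:
    trait: str
    kind: str                                  # "continuous" | "binary"
    quantile_cuts: dict[str, float] = field(default_factory=dict)
    slide_bins: dict[str, str] = field(default_factory=dict)
    n_classes: int = 2

    def slides_in(self, *bins: str) -> list[str]:
        return [s for s, b in self.slide_bins.items() if b in bins]


@dataclass
class SplitAssignment:
    slide_to_set: dict[str, str]               # train | val | test | ood
    fractions: tuple[float, float, float]
    seed: int

    def slides_in(self, set_name: str) -> list[str]:
        return [s for s, v in self.slide_to_set.items() if v == set_name]


def _check_values(values: dict[str, float]) -> np.ndarray:
    v = np.array(list(values.values()), dtype=float)
    if np.unique(v).size < 2:
        raise ValueError("degenerate trait: constant value vector")
    return v


def _snap(p: float) -> float:
    """Round a quantile probability to 12 decimals so band edges like
    0.2 + 0.1 do not drift past the exact order statistic."""
    return float(np.round(p, 12))


def binarize_trait(values: dict[str, float], trait: str = "trait",
                   low_q: float = 0.2, high_q: float = 0.8,
                   kind: str = "continuous") -> LabelScheme:
    """Quantile-binarize slide values; middle slides start as ``excluded``.

    Binary traits pass through unchanged (no quantiles stored).
    """
    if kind == "binary":
        bins = {}
        for s, v in values.items():
            if v not in (0, 1):
                raise ValueError(f"binary trait value for {s} must be 0/1, got {v}")
            bins[s] = str(int(v))
        return LabelScheme(trait=trait, kind="binary", slide_bins=bins)
    v = _check_values(values)
    if v.size < 5:
        raise ValueError("degenerate trait: need >= 5 values for quantiles")
    cuts = {
        "q20": float(np.quantile(v, _snap(low_q))),
        "q30": float(np.quantile(v, _snap(low_q + 0.1))),
        "q70": float(np.quantile(v, _snap(high_q - 0.1))),
        "q80": float(np.quantile(v, _snap(high_q))),
    }
    bins = {}
    for s, val in values.items():
        if val <= cuts["q20"]:
            bins[s] = "0"
        elif val >= cuts["q80"]:
            bins[s] = "1"
        else:
            bins[s] = "excluded"
    return LabelScheme(trait=trait, kind="continuous", quantile_cuts=cuts,
                       slide_bins=bins)


def ood_bins(values: dict[str, float], scheme: LabelScheme) -> LabelScheme:
    """Assign the OOD bands on a scheme produced by :func:`binarize_trait`.

    (q20, q30] -> ood0 and [q70, q80) -> ood1; slides strictly between q30
    and q70 stay excluded. Binary schemes have no OOD band.
    """
    if scheme.kind == "binary":
        return scheme
    c = scheme.quantile_cuts
    for s, val in values.items():
        if scheme.slide_bins[s] != "excluded":
            continue
        if c["q20"] < val <= c["q30"]:
            scheme.slide_bins[s] = "ood0"
        elif c["q70"] <= val < c["q80"]:
            scheme.slide_bins[s] = "ood1"
    return scheme


def trinary_bins(values: dict[str, float], trait: str = "trait",
                 kind: str = "continuous") -> LabelScheme:
    """Three bins cut at the 33rd/66th percentiles; binary traits kept as-is."""
    if kind == "binary":
        scheme = binarize_trait(values, trait=trait, kind="binary")
        return scheme
    v = _check_values(values)
    q33, q66 = float(np.quantile(v, 0.33)), float(np.quantile(v, 0.66))
    bins = {}
    for s, val in values.items():
        bins[s] = "0" if val <= q33 else ("1" if val <= q66 else "2")
    return LabelScheme(trait=trait, kind="continuous",
                       quantile_cuts={"q33": q33, "q66": q66},
                       slide_bins=bins, n_classes=3)


def shuffled_scheme(scheme: LabelScheme, seed: int = 0) -> LabelScheme:
    """Permute the bin assignments uniformly among slides (proportions kept).

    The slide-level null for pipeline calibration: labels become independent
    of image content while the bin composition is unchanged.
    """
    rng = np.random.default_rng(seed)
    slides = sorted(scheme.slide_bins)
    bins = [scheme.slide_bins[s] for s in slides]
    rng.shuffle(bins)
    return LabelScheme(trait=scheme.trait, kind=scheme.kind,
                       quantile_cuts=dict(scheme.quantile_cuts),
                       slide_bins=dict(zip(slides, bins)),
                       n_classes=scheme.n_classes)


def _allocate(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Integer split of n by fractions; remainder goes to train."""
    n_val = int(round(n * fractions[1]))
    n_test = int(round(n * fractions[2]))
    n_train = n - n_val - n_test
    if n_train < 0:
        raise ValueError("fractions allocate more slides than available")
    return n_train, n_val, n_test


def grouped_split(scheme: LabelScheme, fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                  seed: int = 0) -> SplitAssignment:
    """Randomly partition slides into train/val/test, stratified by bin.

    Slides — never tiles — are the unit of assignment, so all tiles of one
    slide land in one set. OOD-binned slides go to the ``ood`` set;
    ``excluded`` slides are left out entirely.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    class_bins = [b for b in set(scheme.slide_bins.values())
                  if b not in ("ood0", "ood1", "excluded")]
    n_sets = sum(1 for f in fractions if f > 0)
    for b in sorted(class_bins):
        slides = sorted(scheme.slides_in(b))
        if len(slides) < n_sets:
            raise ValueError(f"label class {b!r} has {len(slides)} slides, "
                             f"fewer than the {n_sets} requested sets")
        rng.shuffle(slides)
        n_train, n_val, n_test = _allocate(len(slides), fractions)
        for s in slides[:n_train]:
            assignment[s] = "train"
        for s in slides[n_train:n_train + n_val]:
            assignment[s] = "val"
        for s in slides[n_train + n_val:]:
            assignment[s] = "test"
    for s in scheme.slides_in("ood0", "ood1"):
        assignment[s] = "ood"
    return SplitAssignment(slide_to_set=assignment, fractions=tuple(fractions),
                           seed=seed)


def balance_downsample(groups: dict[str, list], seed: int = 0) -> dict[str, list]:
    """Subsample every label group without replacement to the smallest size."""
    if len(groups) < 2:
        raise ValueError("need >= 2 label groups to balance")
    for name, members in groups.items():
        if not members:
            raise ValueError(f"label group {name!r} is empty")
    n_min = min(len(m) for m in groups.values())
    rng = np.random.default_rng(seed)
    out = {}
    for name in sorted(groups):
        members = groups[name]
        idx = rng.choice(len(members), size=n_min, replace=False)
        out[name] = [members[i] for i in sorted(idx)]
    return out
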