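"""Shared study configuration for the numbered analysis scripts.

One cohort drives all analyses: 14 patients x 3 timepoints (42 slides),
512x512 px slides, with three traits chosen to span the interesting cases:

- Ki67: continuous, strongly coupled to nucleus density (the planted
  signal the pipeline should recover),
- PAM50: binary, a noisy threshold of the same density axis (recoverable
  but weaker),
- PR: continuous pure noise (nothing to recover; the negative control).

Every script takes --seed and --out and rebuilds the cohort
deterministically from that seed, so scripts can run in any order.
"""

import argparse
from pathlib import Path

from hetile.config import RunConfig


def analysis_config(seed: int) -> RunConfig:
    return RunConfig(
        n_patients=14,
        traits=[
            {"name": "Ki67", "kind": "continuous",
             "signal_strength": 1.0, "noise_sd": 0.05},
            {"name": "PAM50", "kind": "binary",
             "signal_strength": 2.0, "noise_sd": 0.2},
            {"name": "PR", "kind": "continuous",
             "signal_strength": 0.0, "noise_sd": 1.0},
        ],
        latent_dims=[512, 64, 2],
        ae_epochs=8,
        clf_epochs=10,
        inertia_rounds=10,
        images_per_label=3,
        tiles_per_image=6,
        master_seed=seed,
    )


def parse_args(description: str, default_out: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path(default_out))
    return parser.parse_args()
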