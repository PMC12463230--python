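"""Reconstruction quality across the autoencoder latent-dimension sweep.

Trains one autoencoder per latent dimension on a fixed tile sample (300
train / 60 validation tiles, 20 epochs, best-validation checkpoint) and
summarizes per-tile validation MSE; the median should fall as the
bottleneck widens.
"""

import numpy as np
import pandas as pd

from common import analysis_config, parse_args
from hetile.autoencoder import (AutoencoderSpec, build_autoencoder,
                                reconstruction_report, train_autoencoder)
from hetile.pipeline import build_cohort, tile_cohort


def main() -> None:
    args = parse_args(__doc__, "results/autoencoders")
    config = analysis_config(args.seed)
    records, _ = build_cohort(config)
    tiles = [t for ts in tile_cohort(records, config).values() for t in ts]
    rng = np.random.default_rng(config.stage_seed("sweep-sample"))
    order = rng.permutation(len(tiles))
    val = [tiles[i] for i in order[:60]]
    train = [tiles[i] for i in order[60:360]]

    rows, per_tile = [], {}
    for dim in config.latent_dims:
        spec = AutoencoderSpec.from_latent_dim(dim, epochs=20)
        model = build_autoencoder(spec, seed=config.stage_seed(f"ae:{dim}"))
        result = train_autoencoder(model, train, val,
                                   seed=config.stage_seed(f"ae:{dim}:train"))
        rep = reconstruction_report(model, val)
        per_tile[dim] = rep["per_tile_mse"]
        rows.append({"latent_dim": dim, "best_epoch": result.best_epoch,
                     "median_val_mse": rep["median"], "q1": rep["q1"],
                     "q3": rep["q3"]})
        print(f"latent dim {dim:>4}: median val MSE {rep['median']:.5f} "
              f"(IQR {rep['q1']:.5f}-{rep['q3']:.5f}), best epoch "
              f"{result.best_epoch}")

    args.out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out / "reconstruction_summary.csv", index=False)
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 3.5))
    dims = sorted(per_tile)
    ax.boxplot([per_tile[d] for d in dims], tick_labels=[str(d) for d in dims])
    ax.set_xlabel("latent space dimension")
    ax.set_ylabel("validation reconstruction MSE")
    fig.tight_layout()
    fig.savefig(args.out / "mse_by_latent_dim.png", dpi=120)
    print(f"wrote {args.out}/reconstruction_summary.csv and boxplot")


if __name__ == "__main__":
    main()
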