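"""Classification from encoded tiles across latent dimensions (Ki67).

Trains the autoencoder family on the Ki67 training tiles, encodes every
set, trains a perceptron classifier on the latent vectors at each
dimension, and compares against the no-encoder (raw-tile CNN) baseline.
Accuracy should decay gracefully as the dimension shrinks, with signal
remaining even at dimension 2.
"""

from common import analysis_config, parse_args
from hetile.pipeline import build_cohort, run_experiment_encoded


def main() -> None:
    args = parse_args(__doc__, "results/encoded")
    config = analysis_config(args.seed)
    cohort = build_cohort(config)
    df = run_experiment_encoded(config, args.out, cohort=cohort, trait="Ki67")
    print(f"wrote {args.out}/encoded_metrics.csv and accuracy_vs_dim.csv")
    cols = ["latent_dim", "set", "n_tiles", "accuracy", "auc_roc", "f1"]
    print(df[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}"))


if __name__ == "__main__":
    main()
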