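"""Run configuration: one YAML-serializable object drives every stage.

A single master seed reproduces an entire run; every stage draws its own
seed deterministically from the master seed and the stage name, so stages
can be rerun independently without disturbing each other's randomness.
Artifact files carry a sidecar recording the config hash and package
version.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "derive_seed", "write_sidecar"]

PACKAGE_VERSION = "0.1.0"


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (master_seed * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class RunConfig:
    # cohort
    n_patients: int = 10
    timepoints_per_patient: int = 3
    image_height: int = 512
    image_width: int = 512
    traits: list[dict] = field(default_factory=lambda: [
        {"name": "Ki67", "kind": "continuous", "signal_strength": 1.0, "noise_sd": 0.05}])
    background_fraction: float = 0.25
    heterogeneity_patch_fraction: float = 0.15
    # tiling
    tile_size: int = 128
    max_background: float = 0.5
    whiteness_threshold: int = 220
    # labels/splits
    low_q: float = 0.2
    high_q: float = 0.8
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    # autoencoders
    latent_dims: list[int] = field(default_factory=lambda: [512, 64, 2])
    ae_epochs: int = 5
    # classifier
    clf_epochs: int = 20
    # inertia
    inertia_rounds: int = 10
    inertia_permutations: int = 100
    images_per_label: int = 5
    tiles_per_image: int = 100
    # plumbing
    master_seed: int = 0
    log_level: str = "INFO"

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.master_seed, stage)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    def to_dict(self) -> dict:
        d = asdict(self)
        d["split_fractions"] = list(d["split_fractions"])
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["split_fractions"] = tuple(d.get("split_fractions", (0.6, 0.2, 0.2)))
        return cls(**d)

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def smoke_config(master_seed: int = 0) -> RunConfig:
    """Desk-scale profile: 10 patients, reduced dims/epochs/rounds."""
    return RunConfig(n_patients=10, latent_dims=[512, 64, 2], ae_epochs=5,
                     inertia_rounds=10, images_per_label=3, tiles_per_image=6,
                     master_seed=master_seed)


def write_sidecar(artifact: str | Path, config: RunConfig) -> Path:
    """Record provenance (config hash, version) next to an artifact file."""
    artifact = Path(artifact)
    side = artifact.with_suffix(artifact.suffix + ".meta.json")
    side.write_text(json.dumps({
        "config_hash": config.config_hash,
        "package_version": PACKAGE_VERSION,
        "master_seed": config.master_seed,
    }, indent=2))
    return side
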