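"""Run configuration: one flat YAML with dataset presets.

The three published datasets differ only in a handful of hyper-parameters
(jitter profile, epoch budget, per-slide patch caps); presets capture those
verbatim and explicit YAML keys override them.  Every pipeline command
serializes the resolved configuration, the seed and library versions next
to its outputs so runs are self-describing.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .augment import JitterProfile
from .model import ModelConfig
from .patch_sampler import SamplingPolicy
from .train import TrainConfig

#: Per-dataset presets: jitter half-widths, epoch budget, per-slide caps.
PRESETS: dict[str, dict] = {
    "scc": {
        "train": {"max_epochs": 30, "jitter": (0.04, 0.15, 0.08, 0.02)},
        "sampling": {"max_cancer_per_slide": None, "max_normal_per_slide": None},
    },
    "thyroid": {
        "train": {"max_epochs": 70, "jitter": (0.05, 0.05, 0.08, 0.05)},
        "sampling": {"max_cancer_per_slide": None, "max_normal_per_slide": None},
    },
    "lymph_node": {
        "train": {"max_epochs": 20, "jitter": (0.10, 0.10, 0.10, 0.10)},
        "sampling": {"max_cancer_per_slide": 5000, "max_normal_per_slide": 1000},
    },
    "custom": {},
}


@dataclass
class SimulateConfig:
    n_patients: int = 10
    height: int = 1024
    width: int = 1024
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    artifact_fraction: float = 0.0


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    preset: str = "custom"
    seed: int = 0
    downsample_factor: int = 4
    n_boot: int = 200
    tta_jitter: bool = True
    tissue_mask: bool = True
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    sampling: SamplingPolicy = field(default_factory=SamplingPolicy)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["train"]["jitter"] = list(dataclasses.astuple(self.train.jitter))
        return d


def _merge_section(base: dict, override: dict | None) -> dict:
    out = dict(base)
    if override:
        out.update({k: v for k, v in override.items() if v is not None})
    return out


def resolve_config(
    raw: dict | None = None, preset: str | None = None, seed: int | None = None
) -> RunConfig:
    """Build a RunConfig from defaults <- preset <- explicit keys <- CLI seed."""
    raw = dict(raw or {})
    preset = preset or raw.get("preset", "custom")
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; valid presets: {sorted(PRESETS)}")

    sections: dict[str, dict] = {"simulate": {}, "sampling": {}, "model": {}, "train": {}}
    for name in sections:
        sections[name] = _merge_section(PRESETS[preset].get(name, {}), raw.get(name))

    jitter = sections["train"].pop("jitter", None)
    if jitter is not None and not isinstance(jitter, JitterProfile):
        jitter = JitterProfile.preset(jitter) if isinstance(jitter, str) else JitterProfile(*jitter)

    top = {
        k: raw[k]
        for k in ("downsample_factor", "n_boot", "tta_jitter", "tissue_mask", "seed")
        if k in raw
    }
    if seed is not None:
        top["seed"] = seed
    cfg_seed = int(top.get("seed", 0))

    if "split_fractions" in sections["simulate"]:
        sections["simulate"]["split_fractions"] = tuple(sections["simulate"]["split_fractions"])
    train_kwargs = dict(sections["train"])
    if jitter is not None:
        train_kwargs["jitter"] = jitter
    sampling_kwargs = dict(sections["sampling"])
    sampling_kwargs.setdefault("seed", cfg_seed)

    return RunConfig(
        preset=preset,
        seed=cfg_seed,
        downsample_factor=int(top.get("downsample_factor", 4)),
        n_boot=int(top.get("n_boot", 200)),
        tta_jitter=bool(top.get("tta_jitter", True)),
        tissue_mask=bool(top.get("tissue_mask", True)),
        simulate=SimulateConfig(**sections["simulate"]),
        sampling=SamplingPolicy(**sampling_kwargs),
        model=ModelConfig(**sections["model"]),
        train=TrainConfig(**{**train_kwargs, "seed": train_kwargs.get("seed", cfg_seed)}),
    )


def load_config(path=None, preset: str | None = None, seed: int | None = None) -> RunConfig:
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    return resolve_config(raw, preset=preset, seed=seed)


def write_run_log(out_dir, config: RunConfig, inputs: list = ()) -> None:
    """Serialize the resolved config, seed, versions and input checksums."""
    import numpy, skimage, sklearn  # noqa: PLC0415

    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    checksums = {}
    for p in inputs:
        p = Path(p)
        if p.is_file():
            checksums[p.name] = f"crc32:{zlib.crc32(p.read_bytes()):08x}"
    log = {
        "seed": config.seed,
        "preset": config.preset,
        "versions": {
            "histopatch": __version__,
            "numpy": numpy.__version__,
            "scikit-learn": sklearn.__version__,
            "scikit-image": skimage.__version__,
        },
        "input_checksums": checksums,
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))
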