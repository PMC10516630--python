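"""Pipeline configuration: YAML schema, validation, seed derivation.

Keys carry explicit units in their names (``k_on_per_hr``, ``k_m_per_min``,
``period_hr``, ``dt_sample_min``); a key with the wrong unit suffix is an
unknown key and is rejected, which catches unit mistakes at parse time.
Every stage's seed is derived deterministically from the single global seed
via ``numpy.random.SeedSequence(global_seed).spawn``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .synthetic import ImageSpec, PopulationSpec
from .twostate import GlobalWaveform, SimConfig, TwoStateParams

__all__ = ["ConfigError", "PipelineConfig", "validate_config", "stage_seeds"]

# Stage order is the seed-spawn order; it is part of the reproducibility
# contract and must not be reordered.
STAGES = ("population", "imaging", "counts", "stats")


class ConfigError(ValueError):
    """Structured configuration error listing the offending keys."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(problems))


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "globtx_out"
    verbosity: int = 1
    params: TwoStateParams = field(default_factory=TwoStateParams)
    waveform: GlobalWaveform = field(default_factory=GlobalWaveform)
    sim: SimConfig = field(default_factory=SimConfig)
    population: PopulationSpec = field(default_factory=PopulationSpec)
    image: ImageSpec = field(default_factory=ImageSpec)
    run_imaging: bool = False  # image rendering/quantification round trip
    run_counts: bool = True  # count-matrix generation and proxy stats
    counts: dict = field(default_factory=dict)  # generate_count_matrices overrides


def stage_seeds(global_seed: int) -> dict[str, int]:
    """Deterministic child seed per pipeline stage (order fixed by STAGES)."""
    children = np.random.SeedSequence(global_seed).spawn(len(STAGES))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(STAGES, children)
    }


def _build(cls, section: dict, where: str, problems: list[str]):
    known = {f.name for f in fields(cls)}
    unknown = set(section) - known
    for key in sorted(unknown):
        problems.append(f"{where}: unknown key {key!r} (known: {', '.join(sorted(known))})")
    try:
        return cls(**{k: v for k, v in section.items() if k in known})
    except (TypeError, ValueError) as exc:
        problems.append(f"{where}: {exc}")
        return cls()


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Parse, default and schema-check a pipeline configuration.

    ``source`` may be a YAML path or an already-parsed mapping. Unknown
    keys, invalid values and tuple-typed fields given wrong lengths raise a
    single ConfigError listing every offending key.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    problems: list[str] = []
    top_known = {"seed", "out_dir", "verbosity", "params", "waveform", "sim",
                 "population", "image", "run_imaging", "run_counts", "counts"}
    for key in sorted(set(raw) - top_known):
        problems.append(f"top level: unknown key {key!r}")

    cfg = PipelineConfig(
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "globtx_out")),
        verbosity=int(raw.get("verbosity", 1)),
        run_imaging=bool(raw.get("run_imaging", False)),
        run_counts=bool(raw.get("run_counts", True)),
        counts=dict(raw.get("counts", {})),
    )
    cfg.params = _build(TwoStateParams, raw.get("params", {}), "params", problems)
    cfg.waveform = _build(GlobalWaveform, raw.get("waveform", {}), "waveform", problems)
    sim_section = dict(raw.get("sim", {}))
    if "regulon_assignment" in sim_section and sim_section["regulon_assignment"] is not None:
        sim_section["regulon_assignment"] = tuple(sim_section["regulon_assignment"])
    cfg.sim = _build(SimConfig, sim_section, "sim", problems)
    cfg.population = _build(PopulationSpec, raw.get("population", {}), "population", problems)
    image_section = dict(raw.get("image", {}))
    for tup_key in ("frame_shape", "nucleus_radius_px", "background_coeffs"):
        if tup_key in image_section:
            image_section[tup_key] = tuple(image_section[tup_key])
    cfg.image = _build(ImageSpec, image_section, "image", problems)
    if problems:
        raise ConfigError(problems)
    return cfg
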