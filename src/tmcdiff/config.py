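"""Flat key-value configuration with file overrides.

Every numerically consequential knob of the package lives here so that runs
are reproducible from a config snapshot.  Config files are flat YAML mappings
(``key: value``); unknown keys raise, so typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class Config:
    # bond perception
    bond_tolerance: float = 0.4      # A added to covalent-radius sum
    metal_tolerance: float = 0.6     # A, metal-donor (dative) cutoff slack
    clash_factor: float = 0.7        # fraction of covalent sum below which atoms clash
    # embedding
    l_max: int = 12                  # ligand one-hot slots (slot 0 = metal centre)
    scale_r: float = 0.1             # feature scaling of coordinates
    scale_ha: float = 0.25           # feature scaling of atom-type one-hots
    scale_hlc: float = 1.0           # feature scaling of ligand/denticity one-hots
    # diffusion
    steps: int = 1000                # T, number of diffusion steps
    schedule: str = "polynomial"     # polynomial | cosine
    # denoiser
    n_layers: int = 5
    scalar_width: int = 128
    vector_channels: int = 16
    rbf_size: int = 8
    rbf_max: float = 12.0            # A, centre of the outermost radial basis
    time_channels: int = 8
    # training
    learning_rate: float = 1e-3
    batch_size: int = 8
    # fixtures
    jitter: float = 0.05             # A, coordinate jitter in synthetic complexes
    # screening
    spin_gap_threshold: float = 10.0  # kcal/mol, inclusive

    def replace(self, **kwargs) -> "Config":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def load(cls, path: str | Path, **overrides) -> "Config":
        """Read a flat YAML mapping; CLI flag overrides win over the file."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a flat mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise KeyError(f"unknown config keys: {sorted(bad)}")
        raw.update(overrides)
        return cls(**raw)


DEFAULTS = Config()
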