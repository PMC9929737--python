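"""Run configuration: one YAML document covering every pipeline stage.

Defaults reproduce the study protocol (hill height 0.3 kcal/mol deposited
every 1000 steps, widths 0.125 Å / 0.25, T = 300 K, ΔT = 3300 K).  Any
override is echoed to the log together with the well-tempered scale factor
actually in use.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import yaml

from .free_energy import DEFAULT_DELTA_T, DEFAULT_T

log = logging.getLogger("clampdyn")


@dataclass
class RunConfig:
    """Pipeline settings; every random operation draws from ``seed``."""

    outdir: str = "clampdyn_out"
    seed: int = 0
    n_runs: int = 7
    steps: int = 1_000_000          # sampler steps per replicate
    dt: float = 0.005               # ps
    # well-tempered metadynamics protocol
    hill_height: float = 0.3        # kcal/mol
    hill_stride: int = 1000         # steps
    hill_width_d: float = 0.125     # Å
    hill_width_n: float = 0.25
    temperature: float = DEFAULT_T  # K
    bias_temperature: float = DEFAULT_DELTA_T  # ΔT, K
    # collective variables / contacts
    group_a: str = "1-10"
    group_b: str = "11-18"
    contact_cutoff: float = 4.5     # Å
    # ΔG_unb region definitions (None: bound = global minimum region,
    # unbound = last 20% of the sampled distance range)
    bound_region: tuple | None = None
    unbound_region: tuple | None = None
    sampled_threshold: float = 0.05
    profile_smooth_bins: float = 3.0  # Gaussian kernel, grid bins; 0 = off
    # reweighting
    reweight_scheme: str = "balanced_exponential"

    @property
    def wt_scale_factor(self) -> float:
        """(T+ΔT)/ΔT — the factor converting bias to free energy."""
        return (self.temperature + self.bias_temperature) / self.bias_temperature

    @classmethod
    def load(cls, path=None, **overrides) -> "RunConfig":
        data = {}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        defaults = cls()
        for f in dataclasses.fields(cls):
            if getattr(cfg, f.name) != getattr(defaults, f.name):
                log.info("config override: %s = %r", f.name, getattr(cfg, f.name))
        log.info("well-tempered scale factor (T+dT)/dT = %.6f", cfg.wt_scale_factor)
        return cfg

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def metad_params(self):
        from .synthetic_data import MetadParams
        return MetadParams(h0=self.hill_height, stride=self.hill_stride,
                           sigma_d=self.hill_width_d, sigma_n=self.hill_width_n,
                           T=self.temperature, delta_T=self.bias_temperature)
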