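"""Run configuration: one structured-text (YAML) file drives every stage.

Defaults follow the reference parameter tables of the method (metadynamics
hills of 2 kJ/mol height and width 1.0 with bias factor 10, umbrella insert
gap 0.25 with k_s = 200 kJ/mol, z-wall at 0.0064 with k = 2e7). Unknown keys
are rejected with a nearest-key suggestion; every defaulted field is logged
at startup; per-stage seeds derive deterministically from one master seed.
"""

from __future__ import annotations

import copy
import difflib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError
from .geometry import MetricSpec
from .sampling import LangevinParams, MetadParams, WallParams
from .seeding import derive_seed
from .taps import TapsConfig

logger = logging.getLogger("tapspath")

__all__ = ["RunConfig", "load_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "master_seed": 0,
    "output_dir": "taps_output",
    "units": "kcal/mol",
    "system": {"name": "mueller_brown", "params": {}},
    "metric": {"kind": "euclidean", "align_set": None, "rms_set": None},
    "langevin": {
        "temperature": 310.0,
        "friction": 1.0,
        "timestep": 0.01,
        "record_every": 10,
    },
    "tmd": {
        "start": None,
        "target": None,
        "breakpoints": [[0.0, 1000.0]],
        "total_time": 100.0,
        "interval": 1.0,
    },
    "taps": {
        "sampling_time": 4000.0,
        "gap_tolerance": 2.0,
        "median_band": 0.2,
        "max_iterations": 20,
        "convergence_tol": None,
        "inserter": "linear",
        "metad": {"initial_height": 2.0, "width": 1.0, "bias_factor": 10.0, "pace": 5.0},
        "wall": {"z_wall": 0.0064, "k_wall": 2.0e7},
    },
    "umbrella": {
        "gap": 0.25,
        "k_s": 200.0,
        "sampling_time": 4000.0,
        "n_bins": 200,
        "wham_tol": 1.0e-8,
        "burn_in": 0.1,
    },
    "analyze": {"smoothing_window": 5, "min_depth": 0.5},
}


def _merge(defaults: dict, user: dict, path: str, defaulted: list) -> dict:
    out = {}
    for key, dval in defaults.items():
        here = f"{path}.{key}" if path else key
        if key in user:
            uval = user[key]
            if isinstance(dval, dict) and uval is not None:
                if not isinstance(uval, dict):
                    raise ValidationError(
                        f"config key '{here}': expected a mapping, got {type(uval).__name__}"
                    )
                if dval == {}:  # free-form section (e.g. potential parameters)
                    out[key] = copy.deepcopy(uval)
                else:
                    out[key] = _merge(dval, uval, here, defaulted)
            else:
                if (
                    dval is not None
                    and uval is not None
                    and not isinstance(dval, dict)
                    and not isinstance(uval, type(dval))
                    and not (isinstance(dval, float) and isinstance(uval, int))
                ):
                    raise ValidationError(
                        f"config key '{here}': expected {type(dval).__name__}, "
                        f"got {type(uval).__name__}"
                    )
                out[key] = copy.deepcopy(uval)
        else:
            out[key] = copy.deepcopy(dval)
            defaulted.append(here)
    for key in user:
        if key not in defaults:
            here = f"{path}.{key}" if path else key
            near = difflib.get_close_matches(key, defaults.keys(), n=1)
            hint = f"; did you mean '{near[0]}'?" if near else ""
            raise ValidationError(f"unknown config key '{here}'{hint}")
    return out


@dataclass
class RunConfig:
    """Validated configuration with typed accessors for each stage."""

    data: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG))

    @property
    def master_seed(self) -> int:
        return int(self.data["master_seed"])

    @property
    def output_dir(self) -> str:
        return self.data["output_dir"]

    def stage_seed(self, stage: str, index: int = 0) -> int:
        return derive_seed(self.master_seed, stage, index)

    def metric(self) -> MetricSpec:
        m = self.data["metric"]
        return MetricSpec(
            kind=m["kind"],
            align_set=tuple(m["align_set"]) if m.get("align_set") else None,
            rms_set=tuple(m["rms_set"]) if m.get("rms_set") else None,
        )

    def langevin(self, n_steps: int, seed: int) -> LangevinParams:
        lg = self.data["langevin"]
        return LangevinParams(
            temperature=lg["temperature"],
            friction=lg["friction"],
            timestep=lg["timestep"],
            n_steps=n_steps,
            seed=seed,
            record_every=lg["record_every"],
        )

    def metad(self) -> MetadParams:
        m = self.data["taps"]["metad"]
        return MetadParams(
            initial_height=m["initial_height"],
            width=m["width"],
            bias_factor=m["bias_factor"],
            pace=m["pace"],
        )

    def wall(self) -> WallParams:
        w = self.data["taps"]["wall"]
        return WallParams(z_wall=w["z_wall"], k_wall=w["k_wall"])

    def taps(self) -> TapsConfig:
        t = self.data["taps"]
        lg = self.data["langevin"]
        return TapsConfig(
            sampling_time=t["sampling_time"],
            gap_tolerance=t["gap_tolerance"],
            median_band=t["median_band"],
            max_iterations=t["max_iterations"],
            convergence_tol=t["convergence_tol"],
            metad=self.metad(),
            wall=self.wall(),
            seed=self.stage_seed("taps"),
            temperature=lg["temperature"],
            friction=lg["friction"],
            timestep=lg["timestep"],
            inserter=t["inserter"],
        )

    def to_dict(self) -> dict:
        return copy.deepcopy(self.data)


def load_config(file=None) -> RunConfig:
    """Load and validate a YAML configuration; an empty/missing file yields
    the full defaults. Unknown keys and type mismatches raise
    :class:`ValidationError` naming the key."""
    user: dict = {}
    if file is not None:
        text = Path(file).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValidationError("config file must contain a mapping at top level")
        user = loaded
    defaulted: list = []
    data = _merge(DEFAULT_CONFIG, user, "", defaulted)
    for key in defaulted:
        logger.info("config: using default for %s", key)
    return RunConfig(data=data)
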