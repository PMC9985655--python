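"""Run configuration: flat key=value sections, a master seed, and
deterministic per-stage seed derivation.

Per-stage seeds are derived as a hash of (master seed, stage name) so that
toggling one stage never shifts the randomness of another.
"""

from __future__ import annotations

import configparser
import hashlib
import io
import math
from dataclasses import dataclass, field, asdict

__all__ = ["RunConfig", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic 31-bit seed for a named stage."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


_DEFAULTS = {
    "input": {
        "counts": "",
        "counts_format": "tsv",
        "tree": "",
        "metadata": "",
        "taxonomy": "",
    },
    "filter": {"min_sample_depth": 1980, "min_prevalence": 2},
    "transform": {"pseudocount": 1.0, "weighting": "uniform"},
    "permanova": {
        "n_perm": 999,
        "terms": "destination_site origin_site destination_site:origin_site",
    },
    "richness": {"depth": 1980, "reps": 200},
    "nri": {"n_null": 999, "n_swaps": 1000, "abundance_weighted": True},
    "balances": {"reps": 100, "folds": 10, "n_lambda": 25, "threshold": 0.5},
    "run": {
        "seed": 7,
        "out_dir": "phylocomm_out",
        "stages": "validate transform permanova dispersion richness nri balances",
    },
}

_STAGES = ("validate", "transform", "permanova", "dispersion", "richness", "nri", "balances")

_RANGES = {
    ("filter", "min_sample_depth"): (1, None),
    ("filter", "min_prevalence"): (0, None),
    ("transform", "pseudocount"): (1e-12, None),
    ("permanova", "n_perm"): (1, None),
    ("richness", "depth"): (1, None),
    ("richness", "reps"): (1, None),
    ("nri", "n_null"): (1, None),
    ("nri", "n_swaps"): (1, None),
    ("balances", "reps"): (1, None),
    ("balances", "folds"): (2, None),
    ("balances", "n_lambda"): (2, None),
    ("balances", "threshold"): (0.0, 1.0),
}


@dataclass
class RunConfig:
    sections: dict = field(default_factory=lambda: {
        sec: dict(vals) for sec, vals in _DEFAULTS.items()
    })

    def get(self, section: str, key: str):
        return self.sections[section][key]

    def set(self, section: str, key: str, value):
        if key not in _DEFAULTS[section]:
            raise KeyError(f"unknown config key [{section}] {key}")
        default = _DEFAULTS[section][key]
        if isinstance(default, bool):
            value = value if isinstance(value, bool) else str(value).lower() in ("1", "true", "yes")
        elif isinstance(default, int):
            value = int(value)
        elif isinstance(default, float):
            value = float(value)
        else:
            value = str(value)
        self.sections[section][key] = value
        self.validate()

    @property
    def seed(self) -> int:
        return int(self.sections["run"]["seed"])

    @property
    def stages(self) -> list:
        return str(self.sections["run"]["stages"]).split()

    def stage_seed(self, stage: str) -> int:
        return stage_seed(self.seed, stage)

    def validate(self) -> "RunConfig":
        for (sec, key), (lo, hi) in _RANGES.items():
            v = float(self.sections[sec][key])
            if (lo is not None and v < lo) or (hi is not None and v > hi) or not math.isfinite(v):
                raise ValueError(f"config [{sec}] {key}={v} outside allowed range [{lo}, {hi}]")
        for st in self.stages:
            if st not in _STAGES:
                raise ValueError(f"unknown stage {st!r}; known: {_STAGES}")
        if self.sections["transform"]["weighting"] not in ("uniform", "branch_length"):
            raise ValueError("weighting must be uniform or branch_length")
        return self

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        cp = configparser.ConfigParser()
        read = cp.read(path)
        if not read:
            raise FileNotFoundError(path)
        cfg = cls()
        for sec in cp.sections():
            if sec not in _DEFAULTS:
                raise ValueError(f"unknown config section [{sec}]")
            for key, val in cp[sec].items():
                cfg.set(sec, key, val)
        return cfg.validate()

    def dumps(self) -> str:
        cp = configparser.ConfigParser()
        for sec, vals in self.sections.items():
            cp[sec] = {k: str(v) for k, v in vals.items()}
        buf = io.StringIO()
        cp.write(buf)
        return buf.getvalue()

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.dumps())
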