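"""Run configuration: one YAML-serializable object holding every knob.

All randomness in a run flows from the single ``seed`` through named
substreams (see :func:`substream`), so identical configs reproduce
byte-identical tabular outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .hbi import FitConfig
from .simulate import ExperimentConfig


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    out_dir: str = "wagework_run"
    n_subjects: int = 20
    models: tuple[str, ...] = ("alpha:update", "alpha:interference")
    generating_model: str = "alpha:update"
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    fitter: FitConfig = field(default_factory=FitConfig)
    recovery_r_threshold: float = 0.5
    tradeoff_threshold: float = 0.7
    fidelity_repeats: int = 2
    fidelity_iterations: int = 20

    def __post_init__(self) -> None:
        lo, hi = self.experiment.rating_bounds
        if not lo < hi:
            raise ValueError("rating bounds must be ordered")
        if self.experiment.n_rounds <= 0 or self.experiment.n_trials <= 0:
            raise ValueError("experiment constants must be positive")

    def save(self, path: str | Path) -> None:
        data = asdict(self)
        data["models"] = list(self.models)
        for key in ("experiment", "fitter"):
            for k, v in list(data[key].items()):
                if isinstance(v, tuple):
                    data[key][k] = list(v)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        exp = data.pop("experiment", {})
        for k in ("target_range", "lure_range", "rating_bounds", "offer_bounds"):
            if k in exp:
                exp[k] = tuple(exp[k])
        fit = data.pop("fitter", {})
        data["models"] = tuple(data.get("models", ()))
        return cls(
            experiment=ExperimentConfig(**exp), fitter=FitConfig(**fit), **data
        )


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child stream of the run seed."""
    ss = np.random.SeedSequence([seed, int.from_bytes(name.encode(), "little") % (2**32)])
    return np.random.default_rng(ss)
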