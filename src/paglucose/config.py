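"""Run configuration: a single keyed (YAML) file driving every stage.

The defaults reproduce the full study: 3 days × 10 rounds × 10 glucose
classes, 19–23 kHz analysis band, a 30-learner subspace ensemble with
dimension 67 and 10-fold cross-validation.  The configuration is validated
eagerly (each nested block constructs its dataclass, which enforces the
invariants) before any stage runs, and hashed so every artifact can be tied
back to the exact parameters that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .ensemble import EnsembleConfig
from .physics import CellGeometry
from .synthetic import StudyPlan

__all__ = ["RunConfig", "load_config", "save_config"]

_PLAN_KEYS = {
    "days", "rounds_per_day", "concentrations", "pressure",
    "noise_sd_by_concentration", "resolution_step", "shift_sd",
    "background_floor", "day_effect_fraction", "bin_noise_sd", "burst_rate",
    "burst_width_bins", "burst_amplitude", "burst_band", "line_heights",
    "carbon_floor", "carbon_heights", "carbon_width_scale",
    "pressure_doubling", "panels_on", "ambient_level", "band",
}
_CELL_KEYS = {"V0", "resonances", "amplification_limit"}
_ENSEMBLE_KEYS = {"n_learners", "subspace_dim", "base_learner"}


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to run the end-to-end experiment reproducibly."""

    seed: int = 0
    output_dir: str = "paglucose-run"
    plan: StudyPlan = field(default_factory=StudyPlan)
    cell: CellGeometry = field(default_factory=CellGeometry)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    band: tuple[float, float] = (19_000.0, 23_000.0)
    k_folds: int = 10
    preprocess: bool = True
    group_by_day: bool = False
    vote_grouping: str = "class"  # or "sample"

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")
        if self.vote_grouping not in ("class", "sample"):
            raise ValueError("vote_grouping must be 'class' or 'sample'")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "band": list(self.band),
            "k_folds": self.k_folds,
            "preprocess": self.preprocess,
            "group_by_day": self.group_by_day,
            "vote_grouping": self.vote_grouping,
            "plan": {
                k: v for k, v in asdict(self.plan).items() if k in _PLAN_KEYS
            },
            "cell": {k: v for k, v in asdict(self.cell).items() if k in _CELL_KEYS},
            "ensemble": {
                k: v for k, v in asdict(self.ensemble).items() if k in _ENSEMBLE_KEYS
            },
        }
        return d

    def config_hash(self) -> str:
        """Stable short hash identifying the full parameter set."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        plan_kw = dict(data.pop("plan", {}) or {})
        for key in ("concentrations", "line_heights", "carbon_heights",
                    "burst_width_bins", "burst_amplitude", "burst_band", "band"):
            if key in plan_kw and plan_kw[key] is not None:
                plan_kw[key] = tuple(plan_kw[key])
        if "noise_sd_by_concentration" in plan_kw:
            plan_kw["noise_sd_by_concentration"] = {
                float(k): float(v)
                for k, v in plan_kw["noise_sd_by_concentration"].items()
            }
        cell_kw = dict(data.pop("cell", {}) or {})
        if "resonances" in cell_kw:
            cell_kw["resonances"] = tuple(tuple(r) for r in cell_kw["resonances"])
        ens_kw = dict(data.pop("ensemble", {}) or {})
        unknown = set(data) - {
            "seed", "output_dir", "band", "k_folds", "preprocess",
            "group_by_day", "vote_grouping",
        }
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "band" in data:
            data["band"] = tuple(data["band"])
        seed = int(data.get("seed", 0))
        return cls(
            seed=seed,
            output_dir=data.get("output_dir", "paglucose-run"),
            plan=StudyPlan(**plan_kw),
            cell=CellGeometry(**cell_kw),
            ensemble=EnsembleConfig(**ens_kw, seed=seed),
            band=data.get("band", (19_000.0, 23_000.0)),
            k_folds=int(data.get("k_folds", 10)),
            preprocess=bool(data.get("preprocess", True)),
            group_by_day=bool(data.get("group_by_day", False)),
            vote_grouping=data.get("vote_grouping", "class"),
        )

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(
            self, seed=seed, ensemble=replace(self.ensemble, seed=seed)
        )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.from_dict(data or {})


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
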