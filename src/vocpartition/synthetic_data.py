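"""Synthetic feature-table generator with the study's hierarchical structure.

Traits follow a Gaussian linear mixed model

    y = b0 + b_sex + b_phase + b_condition [+ interaction]
        + u_animal + v_recording + eps

with u_animal ~ N(0, s2_animal), v_recording ~ N(0, s2_recording) nested in
animal, eps ~ N(0, s2_resid).  Traits flagged ``log_scale`` are simulated on
the log scale and exponentiated (log-normal traits such as duration, energy,
pitch).  Pitch missingness is MNAR in the design factors: each pitch value
is independently deleted with probability
``logistic(intercept + phase coef + condition coef)``, independent of the
latent pitch value given the factors.

A single NumPy Generator seeded once drives everything, consumed in fixed
design order, so identical seeds give bit-identical tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .io_schema import (
    CONDITION_LEVELS,
    PHASE_LEVELS,
    FeatureTable,
)


class ConfigError(ValueError):
    """Generator configuration is invalid or incomplete."""


@dataclass
class TraitParams:
    """Linear-predictor and variance parameters for one trait.

    Effects are offsets from the reference cell (female, farrowing, normal).
    ``interaction`` maps ``(phase, condition)`` pairs to extra offsets.
    """

    intercept: float
    sex: dict[str, float] = field(default_factory=dict)
    phase: dict[str, float] = field(default_factory=dict)
    condition: dict[str, float] = field(default_factory=dict)
    interaction: dict[tuple[str, str], float] = field(default_factory=dict)
    sigma2_animal: float = 0.0
    sigma2_recording: float = 0.0
    sigma2_resid: float = 1.0
    log_scale: bool = False

    def validate(self, name: str) -> None:
        for label, v in (("sigma2_animal", self.sigma2_animal),
                         ("sigma2_recording", self.sigma2_recording),
                         ("sigma2_resid", self.sigma2_resid)):
            if v < 0:
                raise ConfigError(f"trait {name!r}: {label} must be >= 0, got {v}")


@dataclass
class MissingnessParams:
    """Logit coefficients for the probability that pitch is missing."""

    intercept: float = -np.inf
    phase: dict[str, float] = field(default_factory=dict)
    condition: dict[str, float] = field(default_factory=dict)


#: The study's phase -> available-conditions map: heat stress was never run
#: in farrowing or nursery, thirst never in farrowing.
DEFAULT_AVAILABILITY: dict[str, tuple[str, ...]] = {
    "farrowing": ("normal", "pain", "hunger", "cold"),
    "nursery": ("normal", "pain", "hunger", "thirst", "cold"),
    "growing": ("normal", "pain", "hunger", "thirst", "heat"),
    "finishing": ("normal", "pain", "hunger", "thirst", "heat"),
}


@dataclass
class GeneratorConfig:
    n_animals: int = 40
    sex_split: float = 0.5
    availability: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_AVAILABILITY))
    recordings_per_cell: int = 1
    samples_per_recording: int = 3
    dropout_rate: float = 0.0
    traits: dict[str, TraitParams] = field(default_factory=dict)
    missingness: MissingnessParams = field(default_factory=MissingnessParams)
    seed: int = 17

    def validate(self) -> None:
        if self.n_animals < 1:
            raise ConfigError("n_animals must be >= 1")
        if not 0.0 <= self.sex_split <= 1.0:
            raise ConfigError("sex_split must be in [0, 1]")
        if self.recordings_per_cell < 1:
            raise ConfigError("recordings_per_cell must be >= 1")
        if not 1 <= self.samples_per_recording <= 3:
            raise ConfigError("samples_per_recording must be in 1..3")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must be in [0, 1)")
        for phase, conds in self.availability.items():
            if phase not in PHASE_LEVELS:
                raise ConfigError(f"unknown phase in availability: {phase!r}")
            if len(conds) == 0:
                raise ConfigError(f"phase {phase!r} has empty condition availability")
            bad = set(conds) - set(CONDITION_LEVELS)
            if bad:
                raise ConfigError(f"unknown condition(s) in availability: {sorted(bad)}")
        for name, tp in self.traits.items():
            tp.validate(name)

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for name, tp in d["traits"].items():
            tp["interaction"] = {f"{p}:{c}": v
                                 for (p, c), v in self.traits[name].interaction.items()}
        d["availability"] = {k: list(v) for k, v in self.availability.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        traits = {}
        for name, tp in dict(d.get("traits", {})).items():
            tp = dict(tp)
            inter = {}
            for key, v in dict(tp.pop("interaction", {})).items():
                if isinstance(key, str):
                    p, c = key.split(":")
                else:
                    p, c = key
                inter[(p, c)] = float(v)
            traits[name] = TraitParams(**tp, interaction=inter)
        miss = d.get("missingness", {})
        if not isinstance(miss, MissingnessParams):
            miss = MissingnessParams(**dict(miss))
        avail = {k: tuple(v) for k, v in dict(
            d.get("availability", DEFAULT_AVAILABILITY)).items()}
        cfg = cls(
            n_animals=int(d.get("n_animals", 40)),
            sex_split=float(d.get("sex_split", 0.5)),
            availability=avail,
            recordings_per_cell=int(d.get("recordings_per_cell", 1)),
            samples_per_recording=int(d.get("samples_per_recording", 3)),
            dropout_rate=float(d.get("dropout_rate", 0.0)),
            traits=traits,
            missingness=miss,
            seed=int(d.get("seed", 17)),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_config(seed: int | None = None) -> GeneratorConfig:
    """The packaged default configuration (the study-like design)."""
    ref = resources.files("vocpartition").joinpath("data/default_config.yaml")
    cfg = GeneratorConfig.from_dict(yaml.safe_load(ref.read_text()))
    if seed is not None:
        cfg.seed = int(seed)
    return cfg


# ---- generation --------------------------------------------------------


def _animal_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"{i:0{width}d}" for i in range(1, n + 1)]


def assign_sexes(cfg: GeneratorConfig, rng: np.random.Generator) -> dict[str, str]:
    """Assign each animal a sex; the female fraction is ``sex_split``."""
    ids = _animal_ids(cfg.n_animals)
    n_female = int(round(cfg.n_animals * cfg.sex_split))
    perm = rng.permutation(cfg.n_animals)
    female = {ids[i] for i in perm[:n_female]}
    return {a: ("female" if a in female else "male") for a in ids}


def build_design(cfg: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Enumerate the factor skeleton (no trait columns yet).

    One recording block per (animal x phase x available condition) x
    ``recordings_per_cell``, each expanded to ``samples_per_recording`` rows.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sexes = assign_sexes(cfg, rng)
    rows = []
    for animal in _animal_ids(cfg.n_animals):
        for phase in PHASE_LEVELS:
            for cond in cfg.availability.get(phase, ()):
                for r in range(1, cfg.recordings_per_cell + 1):
                    rec_id = f"{animal}-{phase[:3]}-{cond}-r{r}"
                    for s in range(1, cfg.samples_per_recording + 1):
                        rows.append((animal, sexes[animal], phase, cond, rec_id, s))
    return pd.DataFrame(
        rows, columns=["animal_id", "sex", "phase", "condition",
                       "recording_id", "sample_index"])


def simulate_traits(
    skeleton: pd.DataFrame,
    cfg: GeneratorConfig,
    rng: np.random.Generator | None = None,
    traits: Sequence[str] | None = None,
) -> FeatureTable:
    """Simulate trait values onto a factor skeleton.

    Random effects are drawn per trait in config order: animal intercepts,
    then recording intercepts, then residuals, so the RNG stream is
    consumed in a fixed, reproducible order.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if traits is None:
        traits = list(cfg.traits)
    missing = [t for t in traits if t not in cfg.traits]
    if missing:
        raise ConfigError(f"no parameters configured for trait(s): {missing}")

    df = skeleton.reset_index(drop=True).copy()
    animals = list(dict.fromkeys(df["animal_id"]))
    recordings = list(dict.fromkeys(df["recording_id"]))
    a_idx = df["animal_id"].map({a: i for i, a in enumerate(animals)}).to_numpy()
    r_idx = df["recording_id"].map({r: i for i, r in enumerate(recordings)}).to_numpy()
    n = len(df)

    for name in traits:
        tp = cfg.traits[name]
        lin = np.full(n, tp.intercept, dtype=float)
        lin += df["sex"].map(lambda s: tp.sex.get(s, 0.0)).to_numpy(dtype=float)
        lin += df["phase"].map(lambda p: tp.phase.get(p, 0.0)).to_numpy(dtype=float)
        lin += df["condition"].map(lambda c: tp.condition.get(c, 0.0)).to_numpy(dtype=float)
        if tp.interaction:
            keys = list(zip(df["phase"], df["condition"]))
            lin += np.array([tp.interaction.get(k, 0.0) for k in keys])
        u = rng.normal(0.0, np.sqrt(tp.sigma2_animal), size=len(animals))
        v = rng.normal(0.0, np.sqrt(tp.sigma2_recording), size=len(recordings))
        eps = rng.normal(0.0, np.sqrt(tp.sigma2_resid), size=n)
        y = lin + u[a_idx] + v[r_idx] + eps
        df[name] = np.exp(y) if tp.log_scale else y
    return FeatureTable(df)


def apply_missingness(
    table: FeatureTable,
    cfg: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> FeatureTable:
    """Delete pitch values MNAR-in-design: P(missing) from the logistic model."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    df = table.data.copy()
    if "pitch" not in df.columns:
        return table
    mp = cfg.missingness
    logits = np.full(len(df), float(mp.intercept))
    logits += df["phase"].map(lambda p: mp.phase.get(p, 0.0)).to_numpy(dtype=float)
    logits += df["condition"].map(lambda c: mp.condition.get(c, 0.0)).to_numpy(dtype=float)
    p = expit(logits)
    drop = rng.random(len(df)) < p
    df.loc[drop, "pitch"] = np.nan
    return FeatureTable(df)


def generate_dataset(cfg: GeneratorConfig) -> FeatureTable:
    """Full pipeline: design skeleton -> traits -> missingness -> dropout."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    skeleton = build_design(cfg, rng=rng)
    table = simulate_traits(skeleton, cfg, rng=rng)
    table = apply_missingness(table, cfg, rng=rng)
    if cfg.dropout_rate > 0:
        keep = rng.random(len(table)) >= cfg.dropout_rate
        table = FeatureTable(table.data.loc[keep])
    return table
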