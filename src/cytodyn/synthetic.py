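"""Synthetic multi-tissue cytokine cohorts with planted statistical structure.

The original mouse measurements are not public, so this module generates
cohorts that reproduce the *statistical* shape of the study: 20 mediators in
7 compartments (plus both brain halves in the LPS arms), baseline n=5,
surgery arms n~26-30, LPS arms n=10, right-skewed (log-normal) concentrations,
planted median shifts between arms (the ground-truth velocities), planted
inter-mediator correlations, and injected outliers. Every downstream stage
can therefore be tested against a known ground truth.

Concentrations are drawn as

    log x = log(median * fold) + sigma * (rho * z_block + sqrt(1 - rho^2) * eps)

with ``z_block`` shared by all mediators of a correlation block within one
subject and ``eps`` independent, both standard normal. The log-normal median
is exp(mu), so the configured ``median * fold`` is the exact population
median and planted velocities follow directly from the configured medians.
Two block members with loading rho have log-scale correlation rho^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .core_data import (
    CONDITION_TIMEPOINTS,
    CORE_COMPARTMENTS,
    LPS_COMPARTMENTS,
    MEDIATOR_PANEL,
    TIMEPOINT_COLUMN,
)

#: Group sizes emulating the study design.
DEFAULT_GROUP_SIZES = {
    "baseline": 5,
    "sham": 28,
    "vagotomy": 28,
    "sham_lps": 10,
    "vagotomy_lps": 10,
}

#: (from, to, duration, unit) contrasts for ground-truth velocities. The
#: 7-day contrasts are per day; the LPS contrasts span 3 h from the matching
#: surgery-only arm and are per hour.
VELOCITY_CONTRASTS = (
    ("baseline", "sham", 7.0, "day"),
    ("baseline", "vagotomy", 7.0, "day"),
    ("sham", "sham_lps", 3.0, "hour"),
    ("vagotomy", "vagotomy_lps", 3.0, "hour"),
)


class ConfigError(ValueError):
    """A cohort configuration references unknown tissues/mediators or is invalid."""


@dataclass
class CorrelationBlock:
    """A set of mediators sharing one latent factor in one tissue+condition."""

    tissue: str
    condition: str
    mediators: tuple[str, ...]
    rho: float  # latent loading in [0, 1]; pairwise log-correlation is rho^2


@dataclass
class CohortConfig:
    """Declarative description of a synthetic cohort.

    ``baseline_median`` maps (tissue, mediator) to the baseline population
    median (falling back to ``default_median``); ``fold_change`` maps
    (condition, tissue, mediator) to a multiplicative shift of that median
    (default 1 = no change). ``sigma`` is the log-scale SD of the noise.
    """

    compartments: tuple[str, ...] = CORE_COMPARTMENTS
    lps_compartments: tuple[str, ...] = LPS_COMPARTMENTS
    mediators: tuple[str, ...] = MEDIATOR_PANEL
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    default_median: float = 50.0
    baseline_median: dict = field(default_factory=dict)
    fold_change: dict = field(default_factory=dict)
    sigma: float = 0.2
    correlation_blocks: list = field(default_factory=list)
    outlier_rate: float = 0.0
    outlier_scale: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if any(n < 1 for n in self.group_sizes.values()):
            raise ConfigError("group sizes must be >= 1")
        if self.sigma < 0:
            raise ConfigError("sigma must be >= 0")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ConfigError("outlier_rate must be in [0, 1]")
        if self.outlier_rate > 0 and self.outlier_scale <= 1:
            raise ConfigError("outlier_scale must be > 1")
        if any(m <= 0 for m in self.baseline_median.values()) or self.default_median <= 0:
            raise ConfigError("medians must be > 0")
        blocks = []
        for b in self.correlation_blocks:
            if isinstance(b, dict):
                b = CorrelationBlock(
                    tissue=b["tissue"],
                    condition=b["condition"],
                    mediators=tuple(b["mediators"]),
                    rho=float(b["rho"]),
                )
            if not 0.0 <= b.rho <= 1.0:
                raise ConfigError(f"block rho must be in [0, 1], got {b.rho}")
            unknown = set(b.mediators) - set(self.mediators)
            if unknown:
                raise ConfigError(f"block references unknown mediator(s) {sorted(unknown)}")
            if b.tissue not in set(self.compartments) | set(self.lps_compartments):
                raise ConfigError(f"block references unknown tissue {b.tissue!r}")
            blocks.append(b)
        self.correlation_blocks = blocks

    def tissues_for(self, condition: str) -> tuple[str, ...]:
        return self.lps_compartments if condition.endswith("_lps") else self.compartments

    def median(self, condition: str, tissue: str, mediator: str) -> float:
        base = self.baseline_median.get((tissue, mediator), self.default_median)
        return base * self.fold_change.get((condition, tissue, mediator), 1.0)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("baseline_median", "fold_change"):
            if key in raw:
                raw[key] = {tuple(k.split("|")): v for k, v in raw[key].items()}
        for key in ("compartments", "lps_compartments", "mediators"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Planted structure, derivable from the config alone (plus outlier draws).

    ``velocities`` maps (from_condition, to_condition, tissue, mediator) to
    the planted rate of change of the population median; ``blocks`` lists the
    planted correlation blocks; ``outliers`` lists the records replaced by
    :func:`inject_outliers`.
    """

    velocities: dict
    blocks: list
    outliers: pd.DataFrame | None = None

    def to_json(self) -> dict:
        return {
            "velocities": [
                {"from": k[0], "to": k[1], "tissue": k[2], "mediator": k[3], "value": v}
                for k, v in self.velocities.items()
            ],
            "blocks": [
                {
                    "tissue": b.tissue,
                    "condition": b.condition,
                    "mediators": list(b.mediators),
                    "rho": b.rho,
                }
                for b in self.blocks
            ],
            "n_outliers": 0 if self.outliers is None else int(len(self.outliers)),
        }


def _planted_velocities(config: CohortConfig) -> dict:
    vel = {}
    for from_cond, to_cond, duration, _unit in VELOCITY_CONTRASTS:
        if from_cond not in config.group_sizes or to_cond not in config.group_sizes:
            continue
        tissues = set(config.tissues_for(from_cond)) & set(config.tissues_for(to_cond))
        for tissue in tissues:
            for mediator in config.mediators:
                m0 = config.median(from_cond, tissue, mediator)
                m1 = config.median(to_cond, tissue, mediator)
                vel[(from_cond, to_cond, tissue, mediator)] = (m1 - m0) / duration
    return vel


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw one cohort and return (measurement table, ground truth).

    Deterministic for a fixed ``config.seed``. With ``sigma=0`` and no
    outliers every concentration equals its configured population median
    exactly, so planted velocities are recovered exactly by the pipeline.
    """
    rng = np.random.default_rng(config.seed)
    med_idx = {m: i for i, m in enumerate(config.mediators)}
    rows = []
    for condition in sorted(config.group_sizes):
        n = config.group_sizes[condition]
        tissues = config.tissues_for(condition)
        for tissue in tissues:
            n_med = len(config.mediators)
            eps = rng.standard_normal((n, n_med))
            noise = eps.copy()
            for block in config.correlation_blocks:
                if block.tissue != tissue or block.condition != condition:
                    continue
                z = rng.standard_normal(n)
                cols = [med_idx[m] for m in block.mediators]
                for c in cols:
                    noise[:, c] = block.rho * z + np.sqrt(1 - block.rho**2) * eps[:, c]
            for j, mediator in enumerate(config.mediators):
                # median * exp(noise): exp(mu + s*z) with the log round-trip
                # avoided so the sigma=0 limit hits the median bit-exactly
                conc = config.median(condition, tissue, mediator) * np.exp(
                    config.sigma * noise[:, j]
                )
                for i in range(n):
                    rows.append(
                        (
                            f"{condition}_{i + 1:02d}",
                            condition,
                            tissue,
                            mediator,
                            conc[i],
                            CONDITION_TIMEPOINTS.get(condition, 0.0),
                        )
                    )
    table = pd.DataFrame(
        rows,
        columns=["subject_id", "condition", "tissue", "mediator", "concentration",
                 TIMEPOINT_COLUMN],
    )
    truth = GroundTruth(
        velocities=_planted_velocities(config), blocks=list(config.correlation_blocks)
    )
    if config.outlier_rate > 0:
        table, replaced = inject_outliers(
            table,
            rate=config.outlier_rate,
            scale=config.outlier_scale,
            seed=int(rng.integers(2**31 - 1)),
        )
        truth.outliers = replaced
    return table, truth


def inject_outliers(
    table: pd.DataFrame, rate: float, scale: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace each record's value by value*scale with probability ``rate``.

    Returns (table with outliers, the replaced records in their original
    form). Multiplicative corruption matches the concentration scale.
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigError(f"rate must be in [0, 1], got {rate}")
    if scale <= 1.0:
        raise ConfigError(f"scale must be > 1, got {scale}")
    rng = np.random.default_rng(seed)
    hit = rng.random(len(table)) < rate
    out = table.copy()
    replaced = table[hit].copy()
    out.loc[hit, "concentration"] = out.loc[hit, "concentration"] * scale
    return out, replaced


def study_default_config(seed: int = 0, **overrides) -> CohortConfig:
    """A cohort emulating the study arms with mild planted structure.

    Most mediators rise after surgery (fold 1.5-3 vs baseline) and rise
    further after LPS; MIG falls after vagotomy in every tissue (the
    vagotomy signature), and IP-10/MIG rise in the spleen after sham but
    fall after vagotomy. A handful of mediators decline after surgery
    (IL-13, MCP-1, MIP-1a in a few compartments) so both sign classes of
    the hyperedge rule are populated. One correlated block (IFNg, IL-1b,
    TNF) is planted per surgery arm in the heart.
    """
    fold: dict = {}
    for tissue in CORE_COMPARTMENTS:
        for mediator in MEDIATOR_PANEL:
            fold[("sham", tissue, mediator)] = 2.0
            fold[("vagotomy", tissue, mediator)] = 1.8
    for tissue in CORE_COMPARTMENTS:
        fold[("vagotomy", tissue, "MIG")] = 0.5
    fold[("sham", "spleen", "MIG")] = 4.0
    fold[("sham", "spleen", "IP-10")] = 3.0
    fold[("vagotomy", "spleen", "IP-10")] = 0.7
    # coordinated post-surgery downregulation in a few compartments
    for cond in ("sham", "vagotomy"):
        for tissue in ("kidney", "gut", "lung"):
            fold[(cond, tissue, "IL-13")] = 0.7
            fold[(cond, tissue, "MCP-1")] = 0.75
            fold[(cond, tissue, "MIP-1a")] = 0.85
    fold[("vagotomy", "gut", "MIG")] = 0.2
    fold[("vagotomy", "kidney", "MIG")] = 0.2
    for tissue in LPS_COMPARTMENTS:
        for mediator in MEDIATOR_PANEL:
            fold[("sham_lps", tissue, mediator)] = 4.0
            fold[("vagotomy_lps", tissue, mediator)] = 3.5
    blocks = [
        CorrelationBlock("heart", cond, ("IFNg", "IL-1b", "TNF"), 0.98)
        for cond in ("sham", "vagotomy")
    ]
    cfg = dict(
        fold_change=fold,
        correlation_blocks=blocks,
        sigma=0.2,
        outlier_rate=0.01,
        outlier_scale=8.0,
        seed=seed,
    )
    cfg.update(overrides)
    return CohortConfig(**cfg)
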