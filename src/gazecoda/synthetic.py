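"""Seeded generator of synthetic AOI dwell-time experiments.

The generator draws logistic-normal compositions: for participant i under
task k the composition is mu_k (+) p_i (+) e_ik, where the participant
effect p_i and the noise e_ik are inverse-ilr images of isotropic Gaussian
draws (standard deviations ``sigma_participant`` and ``sigma_noise`` in ilr
space). The row is then scaled to a lognormal total viewing time in ms, so
the absolute (classical) track sees participant- and task-specific
magnitudes while the relative (compositional) track is untouched by them.
This is exactly the error model under which compositional MANOVA's normality
and homoscedasticity assumptions hold.

Defaults emulate a seven-task, seven-AOI, 144-participant viewing experiment:
the pooled mean composition is (12.52, 2.33, 19.21, 16.19, 20.22, 17.71,
11.82) percent over (Background, Furniture, Kids, Maid, Man, Mother, Wife),
sigma_participant = 0.3, sigma_noise = 0.5, and totals are
lognormal(ln 15000, 0.5) ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coda import close, ilr_pivot, ilr_inverse, perturb
from .ingest import AOITable, STUDY_AOIS

__all__ = ["GeneratorConfig", "POOLED_MEAN_PCT", "inject_zeros",
           "simulate_experiment", "simulate_null", "yarbus_like_task_means"]

#: pooled mean dwell-time composition over the seven AOIs, in percent
POOLED_MEAN_PCT = np.array([12.52, 2.33, 19.21, 16.19, 20.22, 17.71, 11.82])


def yarbus_like_task_means() -> dict[int, np.ndarray]:
    """Illustrative per-task mean compositions (percent, 7 AOIs).

    A qualitative scenario, not a fit to any recorded dataset: tasks 1, 2,
    4 and 6 keep substantial Furniture and Background shares; tasks 3, 5 and
    7 suppress Furniture in favour of the person AOIs; task 4 elevates Kids
    and task 7 elevates Man. Each mean sums to 100.
    """
    base = POOLED_MEAN_PCT
    # perturbation factors per AOI: (Bg, Furn, Kids, Maid, Man, Mother, Wife)
    factors = {
        1: [2.6, 3.5, 0.7, 0.7, 0.7, 0.7, 0.7],   # free viewing: context-heavy
        2: [1.3, 2.0, 0.9, 0.9, 0.9, 0.9, 0.9],
        3: [0.5, 0.08, 1.3, 1.3, 1.3, 1.3, 1.3],  # ages: persons only
        4: [1.0, 2.2, 2.0, 0.7, 0.6, 0.7, 0.7],   # prior activity: kids + table
        5: [0.6, 0.12, 1.2, 1.2, 1.2, 1.2, 1.2],  # clothes: persons
        6: [1.9, 1.8, 0.8, 0.8, 0.8, 0.8, 0.8],   # positions: whole room
        7: [0.5, 0.10, 0.8, 0.8, 3.6, 0.9, 0.9],  # absence: the man
    }
    return {t: perturb(base, np.array(f), kappa=100.0) for t, f in factors.items()}


@dataclass
class GeneratorConfig:
    """Design and distributional parameters of a synthetic experiment.

    ``task_means`` maps task id to a strictly positive mean composition
    closed to 100. ``sigma_participant`` and ``sigma_noise`` are ilr-space
    standard deviations; ``total_meanlog``/``total_sdlog`` parameterise the
    lognormal total viewing time in ms (scalars, or per-task dicts).
    ``zero_rate`` in [0, 0.5] optionally knocks random cells to zero to
    emulate never-visited AOIs.
    """

    n_participants: int = 144
    aois: list[str] = field(default_factory=lambda: list(STUDY_AOIS))
    task_means: dict = field(default_factory=yarbus_like_task_means)
    sigma_participant: float = 0.3
    sigma_noise: float = 0.5
    total_meanlog: float | dict = np.log(15000.0)
    total_sdlog: float | dict = 0.5
    zero_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        D = len(self.aois)
        for t, mu in self.task_means.items():
            mu = np.asarray(mu, dtype=float)
            if mu.shape != (D,) or np.any(mu <= 0):
                raise ValueError(f"task {t!r} mean must be {D} strictly positive parts")
            if not np.isclose(mu.sum(), 100.0, atol=1e-6):
                raise ValueError(f"task {t!r} mean must be closed to 100, sums {mu.sum():.4g}")
            self.task_means[t] = mu
        if self.sigma_participant < 0 or self.sigma_noise < 0:
            raise ValueError("scales must be nonnegative")
        if not 0 <= self.zero_rate <= 0.5:
            raise ValueError(f"zero_rate must lie in [0, 0.5], got {self.zero_rate}")

    def _task_param(self, value, task) -> float:
        return float(value[task]) if isinstance(value, dict) else float(value)


def simulate_experiment(config: GeneratorConfig) -> AOITable:
    """Draw a full synthetic experiment as a long AOITable.

    Deterministic given the config's seed: row order is participants outer,
    tasks inner, AOIs in ``config.aois`` order.
    """
    rng = np.random.default_rng(config.seed)
    D = len(config.aois)
    tasks = sorted(config.task_means)
    records = []
    for i in range(1, config.n_participants + 1):
        p_eff = ilr_inverse(rng.normal(0.0, 1.0, D - 1) * config.sigma_participant)
        for t in tasks:
            e_eff = ilr_inverse(rng.normal(0.0, 1.0, D - 1) * config.sigma_noise)
            comp = close(config.task_means[t] * p_eff * e_eff, 1.0)
            total = rng.lognormal(config._task_param(config.total_meanlog, t),
                                  config._task_param(config.total_sdlog, t))
            for aoi, v in zip(config.aois, comp * total):
                records.append((f"P{i:03d}", t, aoi, v))
    table = AOITable(
        pd.DataFrame(records, columns=["participant", "task", "aoi", "tdof_ms"]),
        list(config.aois),
    )
    if config.zero_rate > 0:
        table = inject_zeros(table, config.zero_rate, seed=int(rng.integers(2**31)))
    return table


def simulate_null(config: GeneratorConfig) -> AOITable:
    """As :func:`simulate_experiment` but with every task mean equal.

    The common mean is the closed geometric mean of the configured task
    means; used for type-I-error and chance-level-classification harnesses.
    """
    mus = np.vstack([config.task_means[t] for t in sorted(config.task_means)])
    common = close(np.exp(np.log(mus).mean(axis=0)), 100.0)
    null_cfg = GeneratorConfig(
        n_participants=config.n_participants,
        aois=list(config.aois),
        task_means={t: common.copy() for t in config.task_means},
        sigma_participant=config.sigma_participant,
        sigma_noise=config.sigma_noise,
        total_meanlog=config.total_meanlog,
        total_sdlog=config.total_sdlog,
        zero_rate=config.zero_rate,
        seed=config.seed,
    )
    return simulate_experiment(null_cfg)


def inject_zeros(table: AOITable, rate: float, seed: int = 0) -> AOITable:
    """Set randomly chosen cells to zero, never blanking an entire row.

    Emulates structural zeros from never-visited AOIs. Deterministic per
    seed; cell selection is Bernoulli(rate), with one randomly retained
    positive cell whenever a whole row would otherwise vanish.
    """
    if not 0 <= rate <= 0.5:
        raise ValueError(f"rate must lie in [0, 0.5], got {rate}")
    if rate == 0:
        return table
    rng = np.random.default_rng(seed)
    df = table.data.copy()
    D = len(table.aoi_set)
    n_rows = len(df) // D
    mask = rng.random((n_rows, D)) < rate
    for r in np.nonzero(mask.all(axis=1))[0]:
        mask[r, rng.integers(D)] = False
    df["tdof_ms"] = np.where(mask.ravel(), 0.0, df["tdof_ms"].to_numpy())
    return AOITable(df, list(table.aoi_set))
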