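"""Synthetic cohort generator emulating the lesion-study design.

Simulated choosers discount hyperbolically, SV = A / (1 + k·D), with a
per-day discount rate k that is modulated multiplicatively by reward
magnitude (k_large = m · k_small; a magnitude effect is m < 1) and by
the episodic-future-thinking condition (k_EFT = e · k_Standard; an EFT
effect is e < 1).  Choices between an immediate offer and the delayed
reward are stochastic: a logistic function of the value difference
normalized by the delayed amount (so noise is scale-invariant across
the two reward magnitudes), plus a small lapse rate of uniformly random
choices.  Low inverse temperature and lapses produce the occasional
nonmonotone indifference curves that the consistency screen targets.

A study is two groups of agents (12 patients, 41 controls by default)
run through the full task: per condition, 14 staircase blocks (2
amounts x 7 delays) of 6 choices, presented in seeded-random order.
Group parameter distributions are log-normal in k and in the two
multipliers, reflecting the right-skewed discount rates seen
empirically.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import staircase as sc
from .curves import auc_from_points
from .staircase import DELAY_DAYS, DELAY_MONTHS, TaskDesign

__all__ = [
    "AgentParams",
    "GroupModel",
    "StudySpec",
    "calibrate_defaults",
    "choose",
    "exact_indifference",
    "p_delayed",
    "simulate_auc_panel",
    "simulate_study",
]


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of one simulated chooser.

    k_small
        Per-day hyperbolic discount rate for the small reward in the
        Standard condition.
    magnitude_multiplier
        m with k_large = m * k_small; m < 1 yields a magnitude effect.
    eft_multiplier
        e with k_EFT = e * k_Standard; e < 1 yields an EFT effect.
    beta
        Inverse temperature of the logistic choice rule applied to the
        value difference normalized by the delayed amount.
    lapse
        Probability of a uniformly random choice on any trial.
    """

    k_small: float
    magnitude_multiplier: float = 1.0
    eft_multiplier: float = 1.0
    beta: float = 10.0
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if self.k_small <= 0:
            raise ValueError("k_small must be positive")
        if not (0 < self.magnitude_multiplier <= 2):
            raise ValueError("magnitude_multiplier must be in (0, 2]")
        if not (0 < self.eft_multiplier <= 2):
            raise ValueError("eft_multiplier must be in (0, 2]")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not (0 <= self.lapse < 0.5):
            raise ValueError("lapse must be in [0, 0.5)")

    def effective_k(self, magnitude: str, condition: str) -> float:
        k = self.k_small
        if magnitude == "large":
            k *= self.magnitude_multiplier
        if condition == "EFT":
            k *= self.eft_multiplier
        return k


@dataclass(frozen=True)
class GroupModel:
    """Log-normal population distributions of agent parameters.

    ``log_*`` fields are natural-log means/sds; multipliers are clipped
    to (0, 2].  ``beta`` and ``lapse`` are shared within the group.
    """

    log_k_mean: float
    log_k_sd: float
    log_m_mean: float = 0.0
    log_m_sd: float = 0.0
    log_e_mean: float = 0.0
    log_e_sd: float = 0.0
    beta: float = 10.0
    lapse: float = 0.0

    def sample(self, n: int, rng: np.random.Generator) -> list[AgentParams]:
        k = np.exp(rng.normal(self.log_k_mean, self.log_k_sd, n))
        m = np.clip(np.exp(rng.normal(self.log_m_mean, self.log_m_sd, n)), 1e-6, 2.0)
        e = np.clip(np.exp(rng.normal(self.log_e_mean, self.log_e_sd, n)), 1e-6, 2.0)
        return [
            AgentParams(
                k_small=float(k[i]),
                magnitude_multiplier=float(m[i]),
                eft_multiplier=float(e[i]),
                beta=self.beta,
                lapse=self.lapse,
            )
            for i in range(n)
        ]


@dataclass(frozen=True)
class StudySpec:
    """A complete simulated-study recipe: who, what task, which seed."""

    n_patients: int = 12
    n_controls: int = 41
    patients: GroupModel = field(default_factory=lambda: GroupModel(-6.2, 1.0))
    controls: GroupModel = field(default_factory=lambda: GroupModel(-6.0, 1.0))
    design: TaskDesign = field(default_factory=TaskDesign)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("group sizes must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def calibrate_defaults() -> StudySpec:
    """The package's shipped default study parameterization.

    The medians of the group log-normal distributions were fixed by a
    one-time Monte-Carlo calibration so that, on average over simulated
    studies, controls show an EFT effect (AuC_EFT - AuC_Standard) near
    0.26 and a magnitude effect (AuC_large - AuC_small) near 0.14,
    while patients show an EFT effect near 0.17 and no magnitude effect
    (near 0.01) — the group-level pattern the design is built to probe.
    Patients are noisier choosers (lower beta, higher lapse), which
    yields more inconsistent preferences.
    """
    return StudySpec(
        n_patients=12,
        n_controls=41,
        patients=GroupModel(
            log_k_mean=float(np.log(2.6e-3)),
            log_k_sd=1.1,
            log_m_mean=0.0,
            log_m_sd=0.25,
            log_e_mean=float(np.log(0.20)),
            log_e_sd=1.2,
            beta=6.0,
            lapse=0.06,
        ),
        controls=GroupModel(
            log_k_mean=float(np.log(3.2e-3)),
            log_k_sd=1.0,
            log_m_mean=float(np.log(0.33)),
            log_m_sd=0.55,
            log_e_mean=float(np.log(0.13)),
            log_e_sd=1.0,
            beta=8.0,
            lapse=0.03,
        ),
    )


def exact_indifference(agent: AgentParams, magnitude: str, condition: str,
                       delay_months: float) -> float:
    """Noiseless normalized indifference point 1 / (1 + k·D)."""
    d = DELAY_DAYS.get(delay_months, delay_months * 30.0)
    return 1.0 / (1.0 + agent.effective_k(magnitude, condition) * d)


def p_delayed(
    agent: AgentParams,
    immediate: float,
    delayed: float,
    delay_days: float,
    condition: str,
    magnitude: str,
) -> float:
    """Probability that the agent picks the delayed reward."""
    v = delayed / (1.0 + agent.effective_k(magnitude, condition) * delay_days)
    core = expit(agent.beta * (v - immediate) / delayed)
    return agent.lapse / 2.0 + (1.0 - agent.lapse) * core


def choose(
    agent: AgentParams,
    immediate: float,
    delayed: float,
    delay_days: float,
    condition: str,
    magnitude: str,
    rng: np.random.Generator,
) -> str:
    """Draw one choice from the agent's stochastic policy."""
    p = p_delayed(agent, immediate, delayed, delay_days, condition, magnitude)
    return "delayed" if rng.random() < p else "immediate"


# --------------------------------------------------------------------------
# Study simulation (vectorized over blocks; arithmetic identical to the
# staircase module, which replay tests verify)
# --------------------------------------------------------------------------


def _round_half_away_vec(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(np.int64)


def _simulate_core(spec: StudySpec, rng: np.random.Generator):
    """Run every block of the study at once.

    Returns a dict of per-block arrays: participant index, group label,
    condition, magnitude, delay, presentation order, the 6 offers and
    choices, and the final subjective value (trial-7 offer).
    """
    design = spec.design
    agents = spec.patients.sample(spec.n_patients, rng) + spec.controls.sample(
        spec.n_controls, rng
    )
    groups = ["patient"] * spec.n_patients + ["control"] * spec.n_controls
    n = len(agents)
    n_blocks = design.n_blocks
    amounts = np.asarray(design.delayed_amounts)
    large_amount = amounts.max()

    # Block table in canonical order: participant x condition x (amount, delay).
    block_amt, block_delay = [], []
    for a in design.delayed_amounts:
        for dm in design.delays_months:
            block_amt.append(a)
            block_delay.append(dm)
    block_amt = np.array(block_amt)
    block_delay = np.array(block_delay)
    days = np.array([DELAY_DAYS.get(m, m * 30.0) for m in block_delay])

    conds = list(design.conditions)
    B = n * len(conds) * n_blocks
    part = np.repeat(np.arange(n), len(conds) * n_blocks)
    cond = np.tile(np.repeat(np.arange(len(conds)), n_blocks), n)
    amt = np.tile(block_amt, n * len(conds))
    delay_m = np.tile(block_delay, n * len(conds))
    delay_d = np.tile(days, n * len(conds))

    # Presentation order of the 14 blocks within each participant x condition.
    order = np.empty(B, dtype=np.int64)
    for i in range(n * len(conds)):
        order[i * n_blocks : (i + 1) * n_blocks] = rng.permutation(n_blocks)

    k_small = np.array([a.k_small for a in agents])[part]
    mmul = np.array([a.magnitude_multiplier for a in agents])[part]
    emul = np.array([a.eft_multiplier for a in agents])[part]
    beta = np.array([a.beta for a in agents])[part]
    lapse = np.array([a.lapse for a in agents])[part]
    is_large = amt == large_amount
    is_eft = np.array([conds[c] == "EFT" for c in cond])
    k_eff = k_small * np.where(is_large, mmul, 1.0) * np.where(is_eft, emul, 1.0)
    value = amt / (1.0 + k_eff * delay_d)

    u = rng.random((B, design.trials_per_block))
    offer = _round_half_away_vec(amt / 2.0)
    adj = _round_half_away_vec((amt - offer) / 2.0)
    offers = np.empty((B, design.trials_per_block), dtype=np.int64)
    chose_delayed = np.empty((B, design.trials_per_block), dtype=bool)
    for t in range(design.trials_per_block):
        offers[:, t] = offer
        p = lapse / 2.0 + (1.0 - lapse) * expit(beta * (value - offer) / amt)
        chose_delayed[:, t] = u[:, t] < p
        offer = offer + np.where(chose_delayed[:, t], adj, -adj)
        offer = np.clip(offer, 0, amt)
        adj = _round_half_away_vec(adj / 2.0)
    sv = offer  # the hypothetical next-trial offer

    return {
        "participant": part,
        "group": np.array(groups, dtype=object)[part],
        "condition": np.array([conds[c] for c in cond], dtype=object),
        "magnitude": np.where(is_large, "large", "small"),
        "delayed_amount": amt,
        "delay_months": delay_m,
        "order": order,
        "offers": offers,
        "choices": chose_delayed,
        "sv": sv,
        "agents": agents,
    }


def simulate_study(spec: StudySpec) -> pd.DataFrame:
    """Simulate the full study as a long-format choice table.

    One row per trial; per participant and condition the 14 blocks
    appear in their seeded-random presentation order.  Deterministic
    given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    core = _simulate_core(spec, rng)
    B, T = core["offers"].shape
    n_per_pc = spec.design.n_blocks

    # Reorder blocks within each participant x condition by presentation order.
    idx = np.arange(B).reshape(-1, n_per_pc)
    for i in range(idx.shape[0]):
        idx[i] = idx[i][np.argsort(core["order"][idx[i]], kind="stable")]
    idx = idx.ravel()

    rows = {
        "participant_id": np.repeat(
            np.char.add("S", (core["participant"][idx] + 1).astype(str)), T
        ),
        "group": np.repeat(core["group"][idx], T),
        "condition": np.repeat(core["condition"][idx], T),
        "magnitude": np.repeat(core["magnitude"][idx], T),
        "delayed_amount": np.repeat(core["delayed_amount"][idx], T),
        "delay_months": np.repeat(core["delay_months"][idx], T),
        "trial": np.tile(np.arange(1, T + 1), B),
        "immediate_offer": core["offers"][idx].ravel(),
        "choice": np.where(core["choices"][idx].ravel(), "delayed", "immediate"),
    }
    return pd.DataFrame(rows)


def simulate_auc_panel(spec: StudySpec) -> pd.DataFrame:
    """Fast path: simulate a study and return per-cell AuC directly.

    Returns a long table (participant_id, group, condition, magnitude,
    auc) — the input schema of the group-level ANOVA — without building
    the trial-level record table.  Uses the same simulation core and
    RNG stream as :func:`simulate_study`.
    """
    rng = np.random.default_rng(spec.seed)
    core = _simulate_core(spec, rng)
    design = spec.design
    n_delays = len(design.delays_months)
    n_amounts = len(design.delayed_amounts)
    sv_norm = core["sv"] / core["delayed_amount"]
    # canonical order: participant x condition x amount x delay
    sv4 = sv_norm.reshape(-1, len(design.conditions), n_amounts, n_delays)
    x = np.concatenate([[0.0], np.asarray(design.delays_months) / 120.0])
    y = np.concatenate(
        [np.ones(sv4.shape[:-1] + (1,)), sv4], axis=-1
    )
    aucs = np.trapezoid(y, x, axis=-1)

    n = sv4.shape[0]
    recs = []
    groups = ["patient"] * spec.n_patients + ["control"] * spec.n_controls
    mags = ["small" if a != max(design.delayed_amounts) else "large"
            for a in design.delayed_amounts]
    for i in range(n):
        for ci, c in enumerate(design.conditions):
            for ai, mag in enumerate(mags):
                recs.append(
                    {
                        "participant_id": f"S{i + 1}",
                        "group": groups[i],
                        "condition": c,
                        "magnitude": mag,
                        "auc": float(aucs[i, ci, ai]),
                    }
                )
    return pd.DataFrame(recs)
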