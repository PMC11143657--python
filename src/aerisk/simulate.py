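"""Constant-hazards competing-risks trial simulator with closed-form truths.

The generator draws, per subject, a latent first-event time from an
exponential with total rate ``alpha + beta`` (AE hazard plus competing-event
hazard) and assigns the type AE with probability ``alpha / (alpha + beta)``
— exactly equivalent to latent competing exponentials, but cheaper.
Censoring is the minimum of an exponential random-censoring time (hazard
``gamma``) and an administrative horizon reduced by a uniform staggered-entry
offset, which is what produces varying follow-up times across subjects.

Hazards are per year by convention; with all hazards constant every
population quantity has a closed form (:func:`true_cif_ae`,
:func:`km_estimand`, :class:`ScenarioTruth`), so estimator bias can be
measured against analytic truth rather than against another estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ADVERSE_EVENT, CENSORED, COMPETING_EVENT, CONTROL, EXPERIMENTAL, TrialDataset


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of a two-arm (or one-arm) constant-hazards scenario.

    All hazards are per time unit (years by convention).  Set the control-arm
    hazards to ``None`` for a one-arm scenario.  ``admin_time`` is the
    administrative censoring horizon (end of study); ``entry_window`` is the
    width of the uniform staggered-entry distribution, which truncates the
    administrative follow-up per subject (width 0 recovers common follow-up).
    """

    n_per_arm: int
    alpha_E: float
    beta_E: float = 0.0
    alpha_C: float | None = None
    beta_C: float | None = None
    gamma: float = 0.0
    admin_time: float | None = None
    entry_window: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be a positive integer")
        hazards = [self.alpha_E, self.beta_E, self.gamma]
        if (self.alpha_C is None) != (self.beta_C is None):
            raise ValueError("set both alpha_C and beta_C, or neither (one-arm scenario)")
        if self.alpha_C is not None:
            hazards += [self.alpha_C, self.beta_C]
        if any(h < 0 for h in hazards):
            raise ValueError("hazards must be >= 0")
        event_hazards = [self.alpha_E, self.beta_E] + (
            [self.alpha_C, self.beta_C] if self.alpha_C is not None else []
        )
        if all(h == 0 for h in event_hazards):
            raise ValueError("at least one event hazard must be > 0")
        if self.admin_time is not None and self.admin_time <= 0:
            raise ValueError("admin_time must be > 0 when set")
        if self.entry_window < 0:
            raise ValueError("entry_window must be >= 0")
        if self.entry_window > 0:
            if self.admin_time is None:
                raise ValueError("entry_window requires admin_time (staggered entry only "
                                 "matters through the administrative horizon)")
            if self.entry_window >= self.admin_time:
                raise ValueError("entry_window must be smaller than admin_time")

    @property
    def single_arm(self) -> bool:
        return self.alpha_C is None

    def arm_hazards(self, arm: str) -> tuple[float, float]:
        if arm == EXPERIMENTAL or self.single_arm:
            return self.alpha_E, self.beta_E
        return self.alpha_C, self.beta_C


def _simulate_arm(rng: np.random.Generator, n: int, alpha: float, beta: float,
                  gamma: float, admin_time: float | None, entry_window: float) -> tuple[np.ndarray, np.ndarray]:
    total = alpha + beta
    if total > 0:
        latent = rng.exponential(1.0 / total, size=n)
        is_ae = rng.random(n) < (alpha / total)
    else:
        latent = np.full(n, np.inf)
        is_ae = np.zeros(n, dtype=bool)
    cens = np.full(n, np.inf)
    if gamma > 0:
        cens = rng.exponential(1.0 / gamma, size=n)
    if admin_time is not None:
        entry = rng.uniform(0.0, entry_window, size=n) if entry_window > 0 else np.zeros(n)
        cens = np.minimum(cens, admin_time - entry)
    time = np.minimum(latent, cens)
    if not np.all(np.isfinite(time)):
        raise ValueError("some subjects are never observed: all hazards 0 and no "
                         "administrative censoring")
    event = np.where(latent <= cens,
                     np.where(is_ae, ADVERSE_EVENT, COMPETING_EVENT),
                     CENSORED)
    return time, event


def simulate_trial(config: ScenarioConfig, seed=None) -> TrialDataset:
    """Draw one trial dataset; reproducible for a fixed seed.

    ``seed`` overrides ``config.seed``; the experimental arm is drawn first.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    arms = {}
    t, e = _simulate_arm(rng, config.n_per_arm, config.alpha_E, config.beta_E,
                         config.gamma, config.admin_time, config.entry_window)
    arms[EXPERIMENTAL] = (t, e)
    if not config.single_arm:
        t, e = _simulate_arm(rng, config.n_per_arm, config.alpha_C, config.beta_C,
                             config.gamma, config.admin_time, config.entry_window)
        arms[CONTROL] = (t, e)
    return TrialDataset.from_arrays(arms, trial_id="sim", ae_id="AE")


# ---------------------------------------------------------------------------
# closed-form truths
# ---------------------------------------------------------------------------

def _check_nonneg(**kwargs) -> None:
    for name, value in kwargs.items():
        if np.any(np.asarray(value) < 0):
            raise ValueError(f"{name} must be >= 0")


def true_cif_ae(alpha: float, beta: float, t):
    """True cumulative incidence of the AE under constant hazards.

    ``alpha/(alpha+beta) * (1 - exp(-(alpha+beta) t))``; 0 when ``alpha = 0``
    and ``1 - exp(-alpha t)`` when ``beta = 0``.
    """
    _check_nonneg(alpha=alpha, beta=beta, t=t)
    t = np.asarray(t, dtype=float)
    s = alpha + beta
    if s == 0:
        out = np.zeros_like(t)
    else:
        out = (alpha / s) * -np.expm1(-s * t)  # expm1 keeps precision at small s*t
    return float(out) if t.ndim == 0 else out


def true_cif_ce(alpha: float, beta: float, t):
    """True cumulative incidence of the competing event under constant hazards."""
    return true_cif_ae(beta, alpha, t)


def km_estimand(alpha: float, t):
    """The quantity one minus Kaplan-Meier targets: ``1 - exp(-alpha t)``.

    Always >= :func:`true_cif_ae` with equality iff ``beta = 0`` or ``t = 0``;
    their ratio tends to ``(alpha+beta)/alpha`` as ``t`` grows, which is the
    structural upward bias of treating competing events as censorings.
    """
    _check_nonneg(alpha=alpha, t=t)
    t = np.asarray(t, dtype=float)
    out = -np.expm1(-alpha * t)
    return float(out) if t.ndim == 0 else out


@dataclass(frozen=True)
class ScenarioTruth:
    """Closed-form population quantities of a constant-hazards scenario."""

    alpha_E: float
    beta_E: float
    alpha_C: float | None = None
    beta_C: float | None = None

    @classmethod
    def from_config(cls, config: ScenarioConfig) -> "ScenarioTruth":
        return cls(config.alpha_E, config.beta_E, config.alpha_C, config.beta_C)

    def _hazards(self, arm: str) -> tuple[float, float]:
        if arm == EXPERIMENTAL or self.alpha_C is None:
            return self.alpha_E, self.beta_E
        return self.alpha_C, self.beta_C

    def cif_ae(self, t, arm: str = EXPERIMENTAL):
        a, b = self._hazards(arm)
        return true_cif_ae(a, b, t)

    def cif_ce(self, t, arm: str = EXPERIMENTAL):
        a, b = self._hazards(arm)
        return true_cif_ce(a, b, t)

    def km(self, t, arm: str = EXPERIMENTAL):
        a, _ = self._hazards(arm)
        return km_estimand(a, t)

    def risk_ratio(self, t) -> float:
        """True RR at ``t``: CIF_AE,experimental / CIF_AE,control."""
        if self.alpha_C is None:
            raise ValueError("risk ratio requires a two-arm scenario")
        qc = true_cif_ae(self.alpha_C, self.beta_C, t)
        qe = true_cif_ae(self.alpha_E, self.beta_E, t)
        return qe / qc

    @property
    def hazard_ratio_ae(self) -> float:
        if self.alpha_C is None or self.alpha_C == 0:
            raise ValueError("AE hazard ratio requires a two-arm scenario with alpha_C > 0")
        return self.alpha_E / self.alpha_C

    @property
    def hazard_ratio_ce(self) -> float:
        if self.beta_C is None or self.beta_C == 0:
            raise ValueError("CE hazard ratio requires a two-arm scenario with beta_C > 0")
        return self.beta_E / self.beta_C


def read_scenario(path) -> ScenarioConfig:
    """Read a flat key-value scenario file (TOML)."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return ScenarioConfig(**raw)
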