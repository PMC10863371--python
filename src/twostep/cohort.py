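"""Synthetic cohort generator emulating the cross-over study design.

Produces trial tables, ground-truth agent parameters, and four-timepoint
blood tryptophan-ratio series for a cohort of simulated subjects, each
completing one session per intervention (ATD / BAL / ATL) in randomized
order.  The default configuration is 98 subjects x 3 sessions x 201 trials,
with subject-level heterogeneity in all seven agent
parameters and an all-zero intervention effect (the null world).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from .agent import PARAM_NAMES, AgentParams, make_agent
from .fitting import _from_unconstrained, to_unconstrained
from .task import TaskConfig, run_session

INTERVENTIONS = ("ATD", "BAL", "ATL")

# Piecewise-linear template tryptophan/sum(LNAA) ratio curves at hours
# (0, 1, 3, 6.5): loading peaks and depletion bottoms out at the 3-hour
# sample, the balanced mixture stays near baseline.  Synthetic stand-ins
# on a plausible absolute scale, not measured values.
BLOOD_TEMPLATES = {
    "ATD": (0.100, 0.055, 0.030, 0.045),
    "BAL": (0.100, 0.102, 0.100, 0.097),
    "ATL": (0.100, 0.190, 0.260, 0.200),
}
_FLAT_TEMPLATE = (0.100, 0.100, 0.100, 0.100)


@dataclasses.dataclass(frozen=True)
class Prior:
    """One-dimensional sampling distribution for a single agent parameter."""

    dist: str  # truncnorm01 | uniform | lognormal | normal | point
    args: tuple

    def draw(self, rng: np.random.Generator) -> float:
        a = self.args
        if self.dist == "truncnorm01":
            mu, sd = a
            lo, hi = (0.0 - mu) / sd, (1.0 - mu) / sd
            return float(sps.truncnorm.rvs(lo, hi, loc=mu, scale=sd, random_state=rng))
        if self.dist == "uniform":
            return float(rng.uniform(*a))
        if self.dist == "beta":
            return float(rng.beta(*a))
        if self.dist == "lognormal":
            return float(rng.lognormal(mean=a[0], sigma=a[1]))
        if self.dist == "normal":
            return float(rng.normal(*a))
        if self.dist == "point":
            return float(a[0])
        raise ValueError(f"unknown prior distribution {self.dist!r}")

    def mean(self, n_mc: int = 200_000, seed: int = 12345) -> float:
        """Analytic mean where available, Monte-Carlo otherwise."""
        a = self.args
        if self.dist == "truncnorm01":
            mu, sd = a
            lo, hi = (0.0 - mu) / sd, (1.0 - mu) / sd
            return float(sps.truncnorm.mean(lo, hi, loc=mu, scale=sd))
        if self.dist == "uniform":
            return (a[0] + a[1]) / 2.0
        if self.dist == "beta":
            return a[0] / (a[0] + a[1])
        if self.dist == "lognormal":
            return math.exp(a[0] + a[1] ** 2 / 2.0)
        if self.dist == "normal":
            return a[0]
        if self.dist == "point":
            return float(a[0])
        rng = np.random.default_rng(seed)
        return float(np.mean([self.draw(rng) for _ in range(n_mc)]))


def default_param_prior() -> dict:
    """Subject-level parameter heterogeneity for the synthetic cohort.

    omega is centred on a typical empirical group mean (0.41, SD 0.29),
    truncated to [0, 1]; the remaining priors are conventional choices for
    this model family, tightened enough that omega stays identifiable from a 201-trial session —
    fully diffuse learning rates / inverse temperatures produce many subjects
    whose data carry no information about omega at all.
    """
    return {
        "beta1": Prior("lognormal", (math.log(4.0), 0.35)),
        "beta2": Prior("lognormal", (math.log(4.0), 0.35)),
        "alpha1": Prior("beta", (3.0, 2.0)),
        "alpha2": Prior("beta", (3.0, 2.0)),
        "lam": Prior("beta", (2.0, 2.0)),
        "omega": Prior("truncnorm01", (0.41, 0.29)),
        "pi": Prior("normal", (0.2, 0.2)),
    }


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort.

    ``effect_spec`` maps intervention label -> {parameter: additive shift on
    the unconstrained scale}; the default (empty) is the null world.
    ``missing_rate_beta`` are the Beta parameters of the per-subject
    trial-missingness probability.
    """

    n_subjects: int = 98
    interventions: tuple[str, ...] = INTERVENTIONS
    order_randomized: bool = True
    param_prior: dict = dataclasses.field(default_factory=default_param_prior)
    effect_spec: dict = dataclasses.field(default_factory=dict)
    missing_rate_beta: tuple[float, float] = (1.0, 49.0)
    blood_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if len(set(self.interventions)) != len(self.interventions) or len(self.interventions) < 2:
            raise ValueError("interventions must be >= 2 unique labels")
        missing_priors = set(PARAM_NAMES) - set(self.param_prior)
        if missing_priors:
            raise ValueError(f"param_prior missing entries for {sorted(missing_priors)}")
        for cond, shifts in self.effect_spec.items():
            if cond not in self.interventions:
                raise ValueError(f"effect_spec references unknown intervention {cond!r}")
            bad = set(shifts) - set(PARAM_NAMES)
            if bad:
                raise ValueError(f"effect_spec references unknown parameters {sorted(bad)}")
        a, b = self.missing_rate_beta
        if a <= 0 or b <= 0:
            raise ValueError("missing_rate_beta parameters must be positive")


@dataclasses.dataclass
class CohortData:
    trials: pd.DataFrame
    true_params: pd.DataFrame
    blood: pd.DataFrame
    spec: CohortSpec
    task_config: TaskConfig


def draw_subject_params(spec: CohortSpec, rng: np.random.Generator) -> AgentParams:
    """One legal AgentParams draw from the cohort prior."""
    return AgentParams(**{name: spec.param_prior[name].draw(rng) for name in PARAM_NAMES})


def apply_effect(base: AgentParams, shifts: dict | None) -> AgentParams:
    """Shift parameters on the unconstrained scale (logit for unit-interval
    parameters, log for betas) so the result always stays in-domain."""
    if not shifts:
        return base
    u = to_unconstrained(base)
    for name, shift in shifts.items():
        u[PARAM_NAMES.index(name)] += shift
    moved = _from_unconstrained(u)
    new = {
        name: moved[PARAM_NAMES.index(name)] for name in shifts
    }  # untouched parameters stay bit-identical
    return dataclasses.replace(base, **new)


def _blood_series(intervention: str, cv: float, rng: np.random.Generator) -> np.ndarray:
    template = np.array(BLOOD_TEMPLATES.get(intervention, _FLAT_TEMPLATE))
    return template * np.exp(rng.normal(0.0, cv, size=4))


def generate_cohort(spec: CohortSpec, task_config: TaskConfig | None = None) -> CohortData:
    """Simulate the full cohort: trials, true parameters, and blood series.

    Deterministic given ``spec.seed``; each subject consumes an independent
    child stream so per-subject results do not depend on cohort size.
    """
    config = task_config or TaskConfig()
    ss = np.random.SeedSequence(spec.seed)
    trial_frames, param_rows, blood_rows = [], [], []
    for i, child in enumerate(ss.spawn(spec.n_subjects)):
        rng = np.random.default_rng(child)
        sid = f"S{i:03d}"
        base = draw_subject_params(spec, rng)
        missing_rate = float(rng.beta(*spec.missing_rate_beta))
        order = list(spec.interventions)
        if spec.order_randomized:
            order = [spec.interventions[j] for j in rng.permutation(len(spec.interventions))]
        for session_order, cond in enumerate(order):
            params = apply_effect(base, spec.effect_spec.get(cond))
            session = run_session(
                make_agent(params, p_common=config.p_common), config, rng, missing_rate=missing_rate
            )
            session.insert(0, "subject_id", sid)
            session.insert(1, "intervention", cond)
            session.insert(2, "session_order", session_order)
            trial_frames.append(session)
            param_rows.append(
                {
                    "subject_id": sid,
                    "intervention": cond,
                    "session_order": session_order,
                    **params.to_dict(),
                    "missing_rate": missing_rate,
                }
            )
            t0, t1, t2, t3 = _blood_series(cond, spec.blood_cv, rng)
            blood_rows.append(
                {"subject_id": sid, "intervention": cond, "t0": t0, "t1": t1, "t2": t2, "t3": t3}
            )
    trials = pd.concat(trial_frames, ignore_index=True)
    return CohortData(
        trials=trials,
        true_params=pd.DataFrame(param_rows),
        blood=pd.DataFrame(blood_rows),
        spec=spec,
        task_config=config,
    )
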