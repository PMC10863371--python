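"""Per-session maximum-likelihood estimation of the hybrid-agent parameters.

Two likelihood code paths are provided on purpose: :func:`session_negll` is an
optimized scalar loop used inside the optimizer, and
:func:`naive_session_negll` is a straight-line re-implementation built
directly on the agent module's step functions.  The two must agree to 1e-10;
the tests enforce this.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from . import agent as agent_mod
from .agent import PARAM_NAMES, AgentParams, QState

#: unconstrained coordinates beyond this magnitude are clamped
UNCONSTRAINED_CLIP = 50.0

#: below this many non-missing trials a session is considered degenerate
MIN_TRIALS = 30


class DegenerateSessionError(ValueError):
    """Too few likelihood-bearing trials to fit a session."""


@dataclasses.dataclass(frozen=True)
class FitResult:
    params_hat: AgentParams
    neg_log_lik: float
    n_restarts: int
    converged: bool
    best_start_index: int
    n_trials_used: int


# ---------------------------------------------------------------------------
# parameter transforms

def to_unconstrained(params: AgentParams) -> np.ndarray:
    """Map AgentParams to R^7: log for betas, logit for unit-interval
    parameters, identity for pi.  Exact inverse of :func:`from_unconstrained`
    on the open domain; boundary values (0/1 rates, 0 betas) have no finite
    preimage and raise."""
    vals = params.astuple()
    out = np.empty(7)
    for i, (name, v) in enumerate(zip(PARAM_NAMES, vals)):
        if name in ("beta1", "beta2"):
            if v <= 0:
                raise ValueError(f"{name}={v} is on the boundary; no finite unconstrained preimage")
            out[i] = math.log(v)
        elif name == "pi":
            out[i] = v
        else:
            if v <= 0.0 or v >= 1.0:
                raise ValueError(f"{name}={v} is on the boundary; no finite unconstrained preimage")
            out[i] = logit(v)
    return out


def _from_unconstrained(x: np.ndarray) -> tuple[float, ...]:
    x = np.clip(np.asarray(x, dtype=float), -UNCONSTRAINED_CLIP, UNCONSTRAINED_CLIP)
    return (
        math.exp(x[0]),
        math.exp(x[1]),
        float(expit(x[2])),
        float(expit(x[3])),
        float(expit(x[4])),
        float(expit(x[5])),
        float(x[6]),
    )


def from_unconstrained(x: np.ndarray) -> AgentParams:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("unconstrained vector must be finite")
    if np.any(np.abs(x) > UNCONSTRAINED_CLIP):
        warnings.warn(
            f"unconstrained parameters clipped to +-{UNCONSTRAINED_CLIP}",
            RuntimeWarning,
            stacklevel=2,
        )
    return AgentParams(*_from_unconstrained(x))


# ---------------------------------------------------------------------------
# likelihood

def session_arrays(trials: pd.DataFrame) -> tuple[list, list, list, list]:
    """Extract non-missing trials as plain int lists (choice1, state2,
    choice2, reward).  Missing trials freeze the agent state, so dropping the
    rows is likelihood-equivalent."""
    keep = ~trials["missing"].to_numpy(dtype=bool)
    if not keep.any():
        raise ValueError("no likelihood-bearing trials")
    sub = trials.loc[keep]
    return (
        [int(v) for v in sub["choice1"]],
        [int(v) for v in sub["state2"]],
        [int(v) for v in sub["choice2"]],
        [float(v) for v in sub["reward"]],
    )


def _negll_core(theta, c1, s2, c2, rw, q_init, p_common):
    # scalar hot loop: local floats only, no numpy
    b1, b2, a1, a2, lam, om, pi = theta
    log, exp = math.log, math.exp
    q00 = q01 = q10 = q11 = q_init
    f0 = f1 = q_init
    prev = -1
    pc = p_common
    pr = 1.0 - p_common
    omc = 1.0 - om
    nll = 0.0
    for i in range(len(c1)):
        ci = c1[i]
        m0 = q00 if q00 > q01 else q01
        m1 = q10 if q10 > q11 else q11
        v0 = om * (pc * m0 + pr * m1) + omc * f0
        v1 = om * (pc * m1 + pr * m0) + omc * f1
        x0 = b1 * v0
        x1 = b1 * v1
        if prev == 0:
            x0 += pi
        elif prev == 1:
            x1 += pi
        if x0 > x1:
            lse = x0 + log(1.0 + exp(x1 - x0))
        else:
            lse = x1 + log(1.0 + exp(x0 - x1))
        nll += lse - (x0 if ci == 0 else x1)
        si = s2[i]
        cj = c2[i]
        if si == 0:
            y0 = b2 * q00
            y1 = b2 * q01
        else:
            y0 = b2 * q10
            y1 = b2 * q11
        if y0 > y1:
            lse2 = y0 + log(1.0 + exp(y1 - y0))
        else:
            lse2 = y1 + log(1.0 + exp(y0 - y1))
        nll += lse2 - (y0 if cj == 0 else y1)
        # SARSA updates
        if si == 0:
            qsc = q00 if cj == 0 else q01
        else:
            qsc = q10 if cj == 0 else q11
        d1 = qsc - (f0 if ci == 0 else f1)
        d2 = rw[i] - qsc
        qsc += a2 * d2
        if si == 0:
            if cj == 0:
                q00 = qsc
            else:
                q01 = qsc
        else:
            if cj == 0:
                q10 = qsc
            else:
                q11 = qsc
        if ci == 0:
            f0 += a1 * (d1 + lam * d2)
        else:
            f1 += a1 * (d1 + lam * d2)
        prev = ci
    return nll


def session_negll(
    params: AgentParams,
    trials: pd.DataFrame,
    q_init: float = agent_mod.DEFAULT_Q_INIT,
    p_common: float = 0.7,
) -> float:
    """Negative log-likelihood of one session's observed choices."""
    c1, s2, c2, rw = session_arrays(trials)
    return _negll_core(params.astuple(), c1, s2, c2, rw, q_init, p_common)


def naive_session_negll(
    params: AgentParams,
    trials: pd.DataFrame,
    q_init: float = agent_mod.DEFAULT_Q_INIT,
    p_common: float = 0.7,
) -> float:
    """Brute-force oracle: trial-by-trial likelihood via the agent module."""
    c1, s2, c2, rw = session_arrays(trials)
    qstate = QState.fresh(q_init)
    nll = 0.0
    for ci, si, cj, r in zip(c1, s2, c2, rw):
        p1 = agent_mod.stage1_choice_probs(qstate, params, p_common)
        nll -= math.log(p1[ci])
        p2 = agent_mod.stage2_choice_probs(qstate, si, params)
        nll -= math.log(p2[cj])
        qstate = agent_mod.update_mf(qstate, ci, si, cj, r, params)
    return nll


# ---------------------------------------------------------------------------
# fitting

def fit_subject_session(
    trials: pd.DataFrame,
    n_restarts: int = 10,
    seed: int = 0,
    q_init: float = agent_mod.DEFAULT_Q_INIT,
    p_common: float = 0.7,
    tol: float = 1e-6,
    min_trials: int = MIN_TRIALS,
) -> FitResult:
    """Multi-start L-BFGS-B minimization of the session likelihood over the
    unconstrained parameter space.

    The first start is the neutral origin (all rates 0.5, betas 1, pi 0); the
    remaining ``n_restarts - 1`` starts are standard-normal draws seeded by
    ``seed``.  Deterministic given the seed.
    """
    c1, s2, c2, rw = session_arrays(trials)
    n_used = len(c1)
    if n_used < min_trials:
        raise DegenerateSessionError(
            f"only {n_used} non-missing trials (< {min_trials}); session is degenerate"
        )

    def objective(x):
        return _negll_core(_from_unconstrained(x), c1, s2, c2, rw, q_init, p_common)

    rng = np.random.default_rng(seed)
    starts = [np.zeros(7)]
    starts += [rng.standard_normal(7) for _ in range(max(0, n_restarts - 1))]

    best_fun = math.inf
    best_x = starts[0]
    best_idx = 0
    any_success = False
    for idx, x0 in enumerate(starts):
        res = minimize(objective, x0, method="L-BFGS-B", options={"ftol": tol, "maxiter": 500})
        any_success = any_success or bool(res.success)
        if math.isfinite(res.fun) and res.fun < best_fun:
            best_fun = float(res.fun)
            best_x = np.asarray(res.x)
            best_idx = idx
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        params_hat = from_unconstrained(best_x)
    return FitResult(
        params_hat=params_hat,
        neg_log_lik=best_fun,
        n_restarts=len(starts),
        converged=any_success,
        best_start_index=best_idx,
        n_trials_used=n_used,
    )


FIT_COLUMNS = ["subject_id", "intervention", *PARAM_NAMES, "negll", "converged", "n_restarts"]


def fit_cohort(
    trials: pd.DataFrame,
    n_restarts: int = 10,
    seed: int = 0,
    q_init: float = agent_mod.DEFAULT_Q_INIT,
    p_common: float = 0.7,
) -> pd.DataFrame:
    """Fit every (subject, intervention) session in a cohort trial table.

    Degenerate sessions (too few usable trials) are skipped with a warning.
    """
    rows = []
    groups = trials.groupby(["subject_id", "intervention"], sort=True)
    for k, (key, session) in enumerate(groups):
        subject_id, intervention = key
        try:
            fit = fit_subject_session(
                session, n_restarts=n_restarts, seed=seed + k, q_init=q_init, p_common=p_common
            )
        except DegenerateSessionError as exc:
            warnings.warn(f"skipping {subject_id}/{intervention}: {exc}", stacklevel=2)
            continue
        rows.append(
            {
                "subject_id": subject_id,
                "intervention": intervention,
                **fit.params_hat.to_dict(),
                "negll": fit.neg_log_lik,
                "converged": fit.converged,
                "n_restarts": fit.n_restarts,
            }
        )
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


# ---------------------------------------------------------------------------
# parameter recovery

@dataclasses.dataclass
class RecoveryReport:
    """True-vs-estimated audit of simulate-then-fit identifiability."""

    true_params: pd.DataFrame
    est_params: pd.DataFrame
    summary: pd.DataFrame  # index: parameter; columns: r, bias, rmse, n

    def __post_init__(self) -> None:
        r = self.summary["r"].dropna()
        if ((r < -1 - 1e-12) | (r > 1 + 1e-12)).any():
            raise ValueError("correlations outside [-1, 1]")
        bad = self.summary["rmse"] ** 2 < self.summary["bias"] ** 2 - 1e-12
        if bad.any():
            raise ValueError("RMSE^2 < bias^2 is impossible")


def recovery_study(
    param_draws: list[AgentParams],
    task_config=None,
    n_restarts: int = 5,
    seed: int = 0,
    n_sessions: int = 1,
    q_init: float = agent_mod.DEFAULT_Q_INIT,
) -> RecoveryReport:
    """Simulate ``n_sessions`` sessions per parameter draw, fit each back
    independently, and tabulate per-parameter correlation, bias, and RMSE of
    the per-subject mean estimate."""
    from .task import TaskConfig, run_session

    config = task_config or TaskConfig()
    ss = np.random.SeedSequence(seed)
    true_rows, est_rows = [], []
    for i, (params, child) in enumerate(zip(param_draws, ss.spawn(len(param_draws)))):
        rng = np.random.default_rng(child)
        session_estimates = []
        for j in range(n_sessions):
            session = run_session(
                agent_mod.make_agent(params, p_common=config.p_common, q_init=q_init), config, rng
            )
            fit = fit_subject_session(
                session,
                n_restarts=n_restarts,
                seed=seed * 7919 + i * 31 + j,
                q_init=q_init,
                p_common=config.p_common,
            )
            session_estimates.append(fit.params_hat.to_dict())
        true_rows.append(params.to_dict())
        est_rows.append(pd.DataFrame(session_estimates).mean().to_dict())
    true_df = pd.DataFrame(true_rows)
    est_df = pd.DataFrame(est_rows)
    rows = {}
    for name in PARAM_NAMES:
        t = true_df[name].to_numpy()
        e = est_df[name].to_numpy()
        err = e - t
        r = np.nan
        if np.std(t) > 0 and np.std(e) > 0:
            r = float(np.corrcoef(t, e)[0, 1])
        rows[name] = {
            "r": r,
            "bias": float(err.mean()),
            "rmse": float(np.sqrt((err**2).mean())),
            "n": len(t),
        }
    summary = pd.DataFrame(rows).T
    return RecoveryReport(true_params=true_df, est_params=est_df, summary=summary)
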