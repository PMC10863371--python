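"""Model-agnostic behavioural analyses.

Stay probabilities factored by the previous trial's reward and transition
type, the derived model-free and model-based scores, the missing-trial
exclusion filter, and the one-way repeated-measures ANOVA (with partial eta
squared) used to test intervention effects.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .agent import PARAM_NAMES
from .task import COMMON, RARE

CELLS = ("com_plus", "rar_plus", "com_minus", "rar_minus")


class EmptyCellError(ValueError):
    """A stay-probability cell has no valid trial pairs."""


@dataclasses.dataclass(frozen=True)
class StayTable:
    """2x2 stay probabilities (previous reward x previous transition) for one
    subject-session, plus pair counts per cell.

    Cells with no valid pairs carry NaN probability and appear in
    ``flagged_cells``; the derived scores refuse to compute from them.
    """

    p_com_plus: float
    p_rar_plus: float
    p_com_minus: float
    p_rar_minus: float
    n_com_plus: int
    n_rar_plus: int
    n_com_minus: int
    n_rar_minus: int

    @property
    def flagged_cells(self) -> tuple[str, ...]:
        return tuple(c for c in CELLS if getattr(self, f"n_{c}") == 0)

    @property
    def mf_effect(self) -> float:
        return mf_effect(self)

    @property
    def mb_effect(self) -> float:
        return mb_effect(self)


def mf_effect(table: StayTable) -> float:
    """Mean stay probability after rewarded minus after unrewarded trials:
    (p_com+ + p_rar+ - p_com- - p_rar-) / 2."""
    _require_full(table)
    return (table.p_com_plus + table.p_rar_plus - table.p_com_minus - table.p_rar_minus) / 2.0


def mb_effect(table: StayTable) -> float:
    """Reward-by-transition interaction:
    (p_com+ - p_rar+ - p_com- + p_rar-) / 2."""
    _require_full(table)
    return (table.p_com_plus - table.p_rar_plus - table.p_com_minus + table.p_rar_minus) / 2.0


def _require_full(table: StayTable) -> None:
    if table.flagged_cells:
        raise EmptyCellError(f"empty stay-table cells: {table.flagged_cells}; no imputation performed")


def stay_table(trials: pd.DataFrame) -> StayTable:
    """Tally stay probabilities for a single-session trial table.

    A pair of consecutive trials (t, t+1) is valid iff both are non-missing;
    it counts as a stay iff choice1 repeats, in the cell keyed by trial t's
    reward and transition type.  Pairs spanning a missing trial are dropped
    (not bridged to the last valid trial).
    """
    missing = trials["missing"].to_numpy(dtype=bool)
    if missing.all():
        raise ValueError("all trials missing; stay table undefined")
    c1 = trials["choice1"].to_numpy()
    rew = trials["reward"].to_numpy()
    tr = trials["transition"].to_numpy()
    stays = {c: 0 for c in CELLS}
    counts = {c: 0 for c in CELLS}
    for t in range(len(trials) - 1):
        if missing[t] or missing[t + 1]:
            continue
        cell = ("com" if tr[t] == COMMON else "rar") + ("_plus" if rew[t] else "_minus")
        counts[cell] += 1
        stays[cell] += int(c1[t + 1] == c1[t])
    probs = {c: (stays[c] / counts[c] if counts[c] else math.nan) for c in CELLS}
    return StayTable(
        p_com_plus=probs["com_plus"],
        p_rar_plus=probs["rar_plus"],
        p_com_minus=probs["com_minus"],
        p_rar_minus=probs["rar_minus"],
        n_com_plus=counts["com_plus"],
        n_rar_plus=counts["rar_plus"],
        n_com_minus=counts["com_minus"],
        n_rar_minus=counts["rar_minus"],
    )


# ---------------------------------------------------------------------------
# exclusion filter

def exclusion_filter(
    trials: pd.DataFrame, threshold: float = 0.30
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop subjects with strictly more than ``threshold`` missing trials in
    at least one session.

    Returns (kept trial table, exclusion log).  The log has one row per
    excluded subject-session over threshold, with the offending fraction.
    """
    frac = (
        trials.groupby(["subject_id", "intervention"], sort=True)["missing"]
        .mean()
        .rename("missing_fraction")
        .reset_index()
    )
    over = frac[frac["missing_fraction"] > threshold]
    excluded = set(over["subject_id"])
    kept = trials[~trials["subject_id"].isin(excluded)].reset_index(drop=True)
    log = over.reset_index(drop=True)
    return kept, log


# ---------------------------------------------------------------------------
# repeated-measures ANOVA

@dataclasses.dataclass(frozen=True)
class RMAnovaResult:
    F: float
    df_num: int
    df_den: int
    p: float
    eta_p_sq: float
    condition_means: tuple[float, ...]
    n_subjects: int


def rm_anova_oneway(data: np.ndarray) -> RMAnovaResult:
    """Classical one-way within-subject ANOVA on an n-subjects x k-conditions
    matrix of complete data.

    Decomposes total variation into subject, condition, and error strata;
    F = MS_cond / MS_error with df (k-1, (k-1)(n-1)); partial eta squared is
    SS_cond / (SS_cond + SS_error).  Zero error variance with a non-zero
    effect yields an infinite-F sentinel (p = 0); a constant matrix yields
    F = 0, p = 1.  Both warn.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be a 2-D subjects x conditions matrix")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 subjects and 2 conditions, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise ValueError("data must be complete (apply listwise deletion upstream)")
    grand = data.mean()
    cond_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_cond = n * float(((cond_means - grand) ** 2).sum())
    ss_subj = k * float(((subj_means - grand) ** 2).sum())
    ss_total = float(((data - grand) ** 2).sum())
    ss_err = max(ss_total - ss_cond - ss_subj, 0.0)
    df_num = k - 1
    df_den = (k - 1) * (n - 1)
    scale = max(ss_total, 1.0)
    if ss_err <= scale * 1e-14:
        if ss_cond <= scale * 1e-14:
            warnings.warn("constant data: F undefined, reporting F=0, p=1", stacklevel=2)
            return RMAnovaResult(0.0, df_num, df_den, 1.0, 0.0, tuple(cond_means), n)
        warnings.warn("zero error variance with non-zero effect: infinite-F sentinel", stacklevel=2)
        return RMAnovaResult(math.inf, df_num, df_den, 0.0, 1.0, tuple(cond_means), n)
    F = (ss_cond / df_num) / (ss_err / df_den)
    p = float(sps.f.sf(F, df_num, df_den))
    eta = ss_cond / (ss_cond + ss_err)
    return RMAnovaResult(float(F), df_num, df_den, p, float(eta), tuple(cond_means), n)


# ---------------------------------------------------------------------------
# intervention analysis

STAYTABLE_COLUMNS = [
    "subject_id",
    "intervention",
    "p_com_plus",
    "p_rar_plus",
    "p_com_minus",
    "p_rar_minus",
    "n_com_plus",
    "n_rar_plus",
    "n_com_minus",
    "n_rar_minus",
    "mf_effect",
    "mb_effect",
]

REPORT_COLUMNS = ["outcome", "F", "df_num", "df_den", "p", "eta_p_sq", "n"]


@dataclasses.dataclass
class AnalysisReport:
    """Tidy per-outcome ANOVA table plus the per-session stay tables and the
    bookkeeping of who was excluded or dropped along the way."""

    report: pd.DataFrame
    staytables: pd.DataFrame
    exclusions: pd.DataFrame
    dropped_subjects: list


def cohort_staytables(trials: pd.DataFrame) -> pd.DataFrame:
    """Per (subject, intervention) stay-probability cells and derived scores.

    Sessions with an empty cell get NaN scores (dropped downstream).
    """
    rows = []
    for (sid, cond), session in trials.groupby(["subject_id", "intervention"], sort=True):
        tab = stay_table(session)
        try:
            mf, mb = tab.mf_effect, tab.mb_effect
        except EmptyCellError:
            mf = mb = math.nan
        rows.append(
            {
                "subject_id": sid,
                "intervention": cond,
                **{f"p_{c}": getattr(tab, f"p_{c}") for c in CELLS},
                **{f"n_{c}": getattr(tab, f"n_{c}") for c in CELLS},
                "mf_effect": mf,
                "mb_effect": mb,
            }
        )
    return pd.DataFrame(rows, columns=STAYTABLE_COLUMNS)


def _complete_matrix(long: pd.DataFrame, value: str, interventions: list[str]) -> tuple[np.ndarray, list]:
    wide = long.pivot(index="subject_id", columns="intervention", values=value)
    wide = wide.reindex(columns=interventions)
    complete = wide.dropna()
    dropped = sorted(set(wide.index) - set(complete.index))
    return complete.to_numpy(dtype=float), dropped


def intervention_analysis(
    trials: pd.DataFrame,
    fits: pd.DataFrame,
    exclusion_threshold: float = 0.30,
) -> AnalysisReport:
    """Run the within-subject intervention ANOVA on every behavioural outcome.

    Outcomes: mf_effect, mb_effect, and the seven fitted model parameters.
    Subjects failing the missingness exclusion rule, or lacking a usable value
    in any intervention condition, are dropped (and logged) per outcome family.
    """
    kept, exclusions = exclusion_filter(trials, threshold=exclusion_threshold)
    interventions = sorted(kept["intervention"].unique())
    if len(interventions) < 2:
        raise ValueError("need at least 2 intervention conditions")
    stay = cohort_staytables(kept)
    excluded = set(trials["subject_id"]) - set(kept["subject_id"])
    dropped: set = set()
    rows = []
    for outcome in ("mf_effect", "mb_effect"):
        mat, drop = _complete_matrix(stay, outcome, interventions)
        dropped.update(drop)
        if mat.shape[0] < 2:
            raise ValueError(f"fewer than 2 complete subjects for outcome {outcome!r}")
        res = rm_anova_oneway(mat)
        rows.append((outcome, res))
    fits_kept = fits[fits["subject_id"].isin(set(kept["subject_id"]))]
    for name in PARAM_NAMES:
        mat, drop = _complete_matrix(fits_kept, name, interventions)
        dropped.update(drop)
        if mat.shape[0] < 2:
            raise ValueError(f"fewer than 2 complete subjects for parameter {name!r}")
        res = rm_anova_oneway(mat)
        rows.append((name, res))
    report = pd.DataFrame(
        [
            {
                "outcome": name,
                "F": res.F,
                "df_num": res.df_num,
                "df_den": res.df_den,
                "p": res.p,
                "eta_p_sq": res.eta_p_sq,
                "n": res.n_subjects,
            }
            for name, res in rows
        ],
        columns=REPORT_COLUMNS,
    )
    return AnalysisReport(
        report=report,
        staytables=stay,
        exclusions=exclusions,
        dropped_subjects=sorted(dropped | excluded),
    )
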