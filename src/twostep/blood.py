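"""Blood-marker validation of the dietary intervention.

Tryptophan availability to the brain is indexed by the ratio of tryptophan to
the sum of competing large neutral amino acids (LNAAs); threonine, lysine and
methionine are in the mixtures for tolerability only, compete at the
transporter not at all, and are excluded from the sum.  Per session the ratio
is sampled at four timepoints, normalized to baseline, integrated by the
trapezoidal rule, and the per-subject AUCs are compared across interventions
with the one-way repeated-measures ANOVA.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .stats import RMAnovaResult, rm_anova_oneway

#: blood sampling grid in hours after drinking the mixture
TIMEPOINTS_H = (0.0, 1.0, 3.0, 6.5)

#: amino acids present in the mixture but not tryptophan competitors
EXCLUDED_FROM_SUM = frozenset({"threonine", "lysine", "methionine"})


@dataclasses.dataclass(frozen=True)
class AminoProfile:
    """Amino-acid concentrations (any consistent units) for one blood sample."""

    concentrations: dict

    def __post_init__(self) -> None:
        if "tryptophan" not in self.concentrations:
            raise ValueError("profile must contain tryptophan")
        for name, v in self.concentrations.items():
            if not v > 0:
                raise ValueError(f"concentration of {name} must be positive, got {v!r}")


def trp_lnaa_ratio(profile: AminoProfile) -> float:
    """Tryptophan / sum of competing LNAAs (exclusion set removed)."""
    total = sum(
        v
        for name, v in profile.concentrations.items()
        if name != "tryptophan" and name not in EXCLUDED_FROM_SUM
    )
    if total <= 0:
        raise ValueError("LNAA sum must be positive after exclusions")
    return profile.concentrations["tryptophan"] / total


def auc_normalized(ratios, timepoints=TIMEPOINTS_H, mode: str = "divide") -> float:
    """Baseline-normalized area under the ratio curve.

    ``mode='divide'`` (default) divides the series by its first value;
    ``mode='subtract'`` subtracts it (alternative baseline convention).
    Integration is trapezoidal over the sampling grid in hours.
    """
    r = np.asarray(ratios, dtype=float)
    t = np.asarray(timepoints, dtype=float)
    if r.shape != t.shape or r.ndim != 1 or len(r) < 2:
        raise ValueError("ratios and timepoints must be matching 1-D series")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    if mode == "divide":
        if r[0] <= 0:
            raise ValueError("baseline (T0) value must be positive for divisive normalization")
        norm = r / r[0]
    elif mode == "subtract":
        norm = r - r[0]
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return float(np.trapezoid(norm, t))


BLOOD_COLUMNS = ["subject_id", "intervention", "t0", "t1", "t2", "t3"]
AUC_COLUMNS = ["subject_id", "intervention", "auc"]


def cohort_auc(blood: pd.DataFrame, mode: str = "divide") -> pd.DataFrame:
    """Per-row normalized AUC of a cohort blood table (t0..t3 columns)."""
    out = blood[["subject_id", "intervention"]].copy()
    series = blood[["t0", "t1", "t2", "t3"]].to_numpy(dtype=float)
    out["auc"] = [auc_normalized(row, mode=mode) for row in series]
    return out


def intervention_auc_anova(blood: pd.DataFrame, mode: str = "divide") -> RMAnovaResult:
    """Within-subject ANOVA of normalized AUC across interventions."""
    auc = cohort_auc(blood, mode=mode)
    wide = auc.pivot(index="subject_id", columns="intervention", values="auc").dropna()
    return rm_anova_oneway(wide.to_numpy(dtype=float))
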