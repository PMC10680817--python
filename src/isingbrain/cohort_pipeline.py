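"""Per-subject fitting, QC rules and cohort-level aging statistics.

Orchestrates the pipeline: slope-sign binarization -> synchrony -> moments ->
maximum-entropy coupling fit -> empirical Pseg at the data set's calibrated
threshold, with the exclusion rules used on real cohorts (non-modal scan
length, age cap, negative fitted coupling), followed by the aging statistics:
Spearman correlation of age with Pseg, 5-year bin summaries (median +/-
standard error), and an additive OLS of Pseg on age, sex and handedness.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import spearmanr

from .meanfield import fit_lambda
from .synchrony import (
    RegionTimeSeries,
    binarize,
    compute_synchrony,
    empirical_moments,
    pseg_empirical,
)

logger = logging.getLogger("isingbrain")

__all__ = [
    "SubjectFit",
    "AgeTrendResult",
    "qc_filter",
    "fit_subject",
    "fit_cohort",
    "age_trend",
    "fits_to_frame",
]

# normal-approximation factor for the standard error of a median
_MEDIAN_SE_FACTOR = 1.2533


@dataclass
class SubjectFit:
    subject_id: str
    age: Optional[float]
    sex: Optional[str]
    handedness: Optional[str]
    t_scan: int
    m2: float
    m4: float
    lam_hat: float
    pseg: float
    pint: float
    included: bool
    exclusion_reason: str  # one of: negative_lambda, scan_length, age_cap, none
    pseg_std: Optional[float] = None  # windowed per-subject Pseg variability


@dataclass
class AgeTrendResult:
    spearman_rho: float
    p_value: float
    n_included: int
    bins: pd.DataFrame  # bin_label, n, median_pseg, se_median
    regression: pd.DataFrame  # term, coef, p_value
    pseg_std_by_subject: Optional[pd.DataFrame] = field(default=None, repr=False)


def qc_filter(subjects: Sequence[RegionTimeSeries], *,
              age_cap: Optional[float] = 90.0
              ) -> tuple[list, list]:
    """Keep subjects at the modal scan length and below the age cap.

    Returns ``(included, exclusion_log)`` where the log holds
    ``(subject_id, reason)`` pairs; every input subject lands in exactly one
    of the two. Ties in the scan-length mode are broken toward the longer
    scan.
    """
    if not subjects:
        raise ValueError("no subjects given")
    counts = Counter(ts.t_scan for ts in subjects)
    top = max(counts.values())
    modal_t = max(t for t, c in counts.items() if c == top)

    included, log = [], []
    for ts in subjects:
        if ts.t_scan != modal_t:
            log.append((ts.subject_id, "scan_length"))
        elif age_cap is not None and ts.age is not None and ts.age >= age_cap:
            log.append((ts.subject_id, "age_cap"))
        else:
            included.append(ts)
    for sid, reason in log:
        logger.info("excluded %s (%s)", sid, reason)
    return included, log


def fit_subject(ts: RegionTimeSeries, n_eff: int, s_star: float,
                *, pseg_window: Optional[int] = 60) -> SubjectFit:
    """Full single-subject pipeline at a fixed (n_eff, s_star).

    A fitted coupling below zero (observed m2 under the uncoupled value
    1/n_eff) marks the subject excluded with reason ``negative_lambda``; the
    diagnostic negative root is retained in ``lam_hat``. When ``pseg_window``
    is set, a per-subject Pseg standard deviation over non-overlapping
    windows of that many synchrony points is recorded (None when fewer than
    two full windows fit).
    """
    try:
        spins = binarize(ts)
        s = compute_synchrony(spins)
        mom = empirical_moments(s)
        fit = fit_lambda(mom.m2, n_eff)
        pseg, pint = pseg_empirical(s, s_star)
    except Exception as exc:
        raise type(exc)(f"subject {ts.subject_id!r}: {exc}") from exc

    pseg_std = None
    if pseg_window and s.size >= 2 * pseg_window:
        n_win = s.size // pseg_window
        chunks = s[: n_win * pseg_window].reshape(n_win, pseg_window)
        win_pseg = np.mean(np.abs(chunks) < s_star, axis=1)
        pseg_std = float(np.std(win_pseg, ddof=1))

    return SubjectFit(
        subject_id=ts.subject_id,
        age=ts.age,
        sex=ts.sex,
        handedness=ts.handedness,
        t_scan=ts.t_scan,
        m2=mom.m2,
        m4=mom.m4,
        lam_hat=fit.lam_hat,
        pseg=pseg,
        pint=pint,
        included=not fit.excluded,
        exclusion_reason="negative_lambda" if fit.excluded else "none",
        pseg_std=pseg_std,
    )


def fit_cohort(subjects: Sequence[RegionTimeSeries], n_eff: int, s_star: float,
               *, age_cap: Optional[float] = 90.0,
               pseg_window: Optional[int] = 60) -> list:
    """QC-filter then fit every subject; returns a SubjectFit per input.

    QC-excluded subjects appear with their exclusion reason and NaN fit
    fields, so exclusion accounting covers the whole cohort.
    """
    passed, log = qc_filter(subjects, age_cap=age_cap)
    reasons = dict(log)
    fits = []
    for ts in subjects:
        if ts.subject_id in reasons:
            fits.append(
                SubjectFit(
                    subject_id=ts.subject_id, age=ts.age, sex=ts.sex,
                    handedness=ts.handedness, t_scan=ts.t_scan,
                    m2=float("nan"), m4=float("nan"), lam_hat=float("nan"),
                    pseg=float("nan"), pint=float("nan"), included=False,
                    exclusion_reason=reasons[ts.subject_id],
                )
            )
        else:
            fits.append(fit_subject(ts, n_eff, s_star, pseg_window=pseg_window))
            logger.info("fitted %s: lam=%.3f pseg=%.3f",
                        ts.subject_id, fits[-1].lam_hat, fits[-1].pseg)
    return fits


def age_trend(fits: Sequence[SubjectFit], *, bin_width: float = 5.0,
              on: str = "pseg") -> AgeTrendResult:
    """Aging statistics over included subjects.

    Spearman rho (age vs. Pseg, or Pint via ``on="pint"``); per-bin medians
    with SE ~ 1.2533 * SD / sqrt(n) (normal approximation); additive OLS of
    the outcome on age + sex + handedness. Bins are left-closed, right-open,
    ``bin_width`` years wide, anchored at the floor of the minimum age.
    """
    if on not in ("pseg", "pint"):
        raise ValueError("on must be 'pseg' or 'pint'")
    inc = [f for f in fits if f.included]
    if len(inc) < 3:
        raise ValueError(f"need at least 3 included subjects, got {len(inc)}")
    df = pd.DataFrame(
        {
            "subject_id": [f.subject_id for f in inc],
            "age": [f.age for f in inc],
            "sex": [f.sex for f in inc],
            "handedness": [f.handedness for f in inc],
            "y": [getattr(f, on) for f in inc],
            "pseg_std": [f.pseg_std for f in inc],
        }
    )
    rho, p = spearmanr(df["age"], df["y"])

    lo = np.floor(df["age"].min())
    edges = np.arange(lo, df["age"].max() + bin_width, bin_width)
    which = np.digitize(df["age"], edges) - 1
    bin_rows = []
    for b in sorted(set(which)):
        sub = df["y"][which == b]
        n = len(sub)
        se = _MEDIAN_SE_FACTOR * sub.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        bin_rows.append(
            {
                "bin_label": f"[{edges[b]:g},{edges[b] + bin_width:g})",
                "n": n,
                "median_pseg": float(sub.median()),
                "se_median": float(se),
            }
        )
    bins = pd.DataFrame(bin_rows)

    terms = ["age"]
    formula = "y ~ age"
    if df["sex"].nunique() > 1:
        formula += " + C(sex)"
    if df["handedness"].nunique() > 1:
        formula += " + C(handedness)"
    ols = smf.ols(formula, data=df).fit()
    regression = pd.DataFrame(
        {"term": ols.params.index, "coef": ols.params.values,
         "p_value": ols.pvalues.values}
    )

    std_df = df[["subject_id", "age", "pseg_std"]].dropna()
    return AgeTrendResult(
        spearman_rho=float(rho),
        p_value=float(p),
        n_included=len(inc),
        bins=bins,
        regression=regression,
        pseg_std_by_subject=std_df if len(std_df) else None,
    )


def fits_to_frame(fits: Sequence[SubjectFit]) -> pd.DataFrame:
    return pd.DataFrame([vars(f) for f in fits])


def write_trend_summary(result: AgeTrendResult, n_eff: int, s_star: float,
                        path) -> None:
    """JSON summary with rho, p, n, s*, n_eff."""
    payload = {
        "spearman_rho": result.spearman_rho,
        "p_value": result.p_value,
        "n_included": result.n_included,
        "n_eff": n_eff,
        "s_star": s_star,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
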