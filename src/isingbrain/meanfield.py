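"""Mean-field Ising model of brain synchrony.

The model treats the brain as ``n_eff`` exchangeable +/-1 spins whose total
magnetization n = sum_i sigma_i follows the maximum-entropy distribution with
a second-moment constraint and a binomial prior,

    P(n) = (1/Z) * C(n_eff, (n_eff + n)/2) * exp(lam * n^2 / n_eff^2),

on the parity grid n in {-n_eff, -n_eff + 2, ..., n_eff}. ``lam`` is the
coupling (the Lagrange multiplier of the constraint); its critical value is
lam_c = n_eff / 2, where the quadratic term of the log-pmf vanishes and the
synchrony density degenerates to the quartic (Landau) form

    f(s) ∝ exp(Lambda * s^2 - n_eff * s^4 / 12),   Lambda = lam - n_eff/2,

on s in [-1, 1]. The threshold s* separating segregated (|s| < s*) from
integrated (|s| >= s*) dynamics is calibrated so that Pseg = 1/2 at the
critical point; model Pseg shares the Landau-density convention with the
calibration, so the half-point holds by construction.

``n_eff`` is a hyper-parameter: atlas parcellations provide N regions, but
the data behave as if only a few tens of units are statistically independent.
It is selected per data set by minimizing the RMSE of the fourth synchrony
moment between model and cohort (the next moment the fit does not constrain).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import gammaln

from .synchrony import MomentSummary

__all__ = [
    "SynchronyPMF",
    "MeanFieldModel",
    "LambdaFit",
    "NeffScanResult",
    "pmf",
    "model_moments",
    "critical_lambda",
    "fit_lambda",
    "calibrate_s_star",
    "pseg_model",
    "select_neff",
    "default_neff_candidates",
    "write_calibration_table",
]

# bisection control for the coupling fit (residual on m2)
_FIT_TOL = 1e-10
_FIT_MAX_ITER = 200


@dataclass(frozen=True)
class SynchronyPMF:
    """Exact magnetization distribution on the parity grid of ``n_eff`` spins."""

    n_eff: int
    lam: float
    support: np.ndarray  # integers -n_eff, -n_eff+2, ..., n_eff
    probs: np.ndarray

    @property
    def synchrony_grid(self) -> np.ndarray:
        return self.support / self.n_eff


@dataclass(frozen=True)
class MeanFieldModel:
    """A fitted mean-field Ising model: (n_eff, lam) with derived quantities."""

    n_eff: int
    lam: float

    @property
    def big_lambda(self) -> float:
        """Rescaled coupling Lambda = lam - n_eff/2; zero at the critical point."""
        return self.lam - self.n_eff / 2.0

    def pmf(self) -> SynchronyPMF:
        return pmf(self.n_eff, self.lam)


@dataclass(frozen=True)
class LambdaFit:
    """Result of the maximum-entropy coupling fit.

    ``excluded`` is True when the observed second moment falls below the
    uncoupled (binomial) value 1/n_eff, which would require a negative,
    non-physical coupling; ``lam_hat`` then carries the diagnostic negative
    root.
    """

    lam_hat: float
    excluded: bool


@dataclass(frozen=True)
class NeffScanResult:
    candidates: list
    objective: np.ndarray  # RMSE of s^4 per candidate; NaN where undefined
    best: int


def pmf(n_eff: int, lam: float) -> SynchronyPMF:
    """Exact mean-field pmf, computed in log space and max-shifted."""
    n_eff = int(n_eff)
    if n_eff < 2:
        raise ValueError(f"n_eff must be >= 2, got {n_eff}")
    n = np.arange(-n_eff, n_eff + 1, 2)
    k = (n_eff + n) / 2
    logw = (
        gammaln(n_eff + 1)
        - gammaln(k + 1)
        - gammaln(n_eff - k + 1)
        + lam * n.astype(float) ** 2 / n_eff**2
    )
    logw -= logw.max()
    p = np.exp(logw)
    p /= p.sum()
    return SynchronyPMF(n_eff=n_eff, lam=float(lam), support=n, probs=p)


def model_moments(n_eff: int, lam: float) -> MomentSummary:
    """Second and fourth moments of synchrony s = n/n_eff under the model."""
    d = pmf(n_eff, lam)
    s2 = d.synchrony_grid**2
    return MomentSummary(
        m2=float(np.dot(d.probs, s2)), m4=float(np.dot(d.probs, s2 * s2))
    )


def critical_lambda(n_eff: int) -> float:
    """Coupling at which the quadratic term of the log-pmf vanishes.

    The Gaussian expansion ln C(N, (N+n)/2) ≈ const - n^2/(2N) is cancelled
    by lam * n^2 / N^2 exactly at lam = N/2, leaving the quartic critical
    density.
    """
    if n_eff < 2:
        raise ValueError(f"n_eff must be >= 2, got {n_eff}")
    return n_eff / 2.0


def fit_lambda(m2_obs: float, n_eff: int) -> LambdaFit:
    """Solve model m2(lam) = m2_obs by bisection (maximum-entropy moment match).

    The model's second moment is strictly increasing in lam, from 0 (lam ->
    -inf) through 1/n_eff at lam = 0 to 1 (lam -> +inf), so the root is
    unique. Observed m2 below the binomial value 1/n_eff requires lam < 0,
    a non-physical coupling: the subject is flagged for exclusion and the
    negative root returned for diagnostics.
    """
    if not 0.0 <= m2_obs <= 1.0:
        raise ValueError(f"m2_obs must lie in [0, 1], got {m2_obs}")

    def resid(lam: float) -> float:
        return model_moments(n_eff, lam).m2 - m2_obs

    r0 = resid(0.0)
    if abs(r0) <= _FIT_TOL:
        return LambdaFit(lam_hat=0.0, excluded=False)

    excluded = r0 > 0  # m2_obs < 1/n_eff -> negative root
    if excluded:
        lo, hi = -float(n_eff), 0.0
        while resid(lo) > 0:
            lo *= 2.0
            if lo < -1e9:
                # m2_obs ~ 0: coupling diverges to -inf
                return LambdaFit(lam_hat=-math.inf, excluded=True)
    else:
        lo, hi = 0.0, float(n_eff)
        while resid(hi) < 0:
            hi *= 2.0
            if hi > 1e9:
                return LambdaFit(lam_hat=math.inf, excluded=False)

    for _ in range(_FIT_MAX_ITER):
        mid = 0.5 * (lo + hi)
        r = resid(mid)
        if abs(r) <= _FIT_TOL:
            return LambdaFit(lam_hat=mid, excluded=excluded)
        if r < 0:
            lo = mid
        else:
            hi = mid
    return LambdaFit(lam_hat=0.5 * (lo + hi), excluded=excluded)


# ---------------------------------------------------------------------------
# Landau (quartic) continuum convention shared by calibration and model Pseg
# ---------------------------------------------------------------------------

def _landau_mass(n_eff: int, big_lambda: float, upper: float) -> float:
    """Integral of exp(Lambda s^2 - n_eff s^4 / 12) over [0, upper]."""
    f = lambda s: math.exp(big_lambda * s * s - n_eff * s**4 / 12.0)
    val, _ = quad(f, 0.0, upper, limit=200)
    return val


def pseg_model(model: MeanFieldModel, s_star: float, *,
               method: str = "continuum") -> float:
    """Model probability of the segregated state, P(|s| < s*).

    method="continuum" (default) integrates the Landau critical-expansion
    density exp(Lambda s^2 - n_eff s^4/12) over |s| < s*, normalized on
    [-1, 1] — the same convention used to calibrate s*, so Pseg = 1/2 at the
    critical point exactly. method="discrete" evaluates the truncated sum of
    the exact pmf over grid points with |n| < n_eff * s* (strict, non-integer
    bounds truncated inward).
    """
    if not 0.0 < s_star < 1.0:
        raise ValueError(f"s_star must lie in (0, 1), got {s_star}")
    if method == "continuum":
        L = model.big_lambda
        return _landau_mass(model.n_eff, L, s_star) / _landau_mass(model.n_eff, L, 1.0)
    if method == "discrete":
        d = model.pmf()
        return float(d.probs[np.abs(d.support) < model.n_eff * s_star].sum())
    raise ValueError(f"unknown method {method!r}")


def calibrate_s_star(n_eff: int, *, ndigits: Optional[int] = None) -> float:
    """Synchrony threshold at which critical-point Pseg equals 1/2.

    Solves P(|s| < s*) = 1/2 under the quartic critical density
    exp(-n_eff s^4 / 12) on |s| <= 1 (the Lambda = 0 limit of the model).
    Returned at full precision; pass ``ndigits=2`` for the reported
    two-decimal value.
    """
    if n_eff < 2:
        raise ValueError(f"n_eff must be >= 2, got {n_eff}")
    total = _landau_mass(n_eff, 0.0, 1.0)
    s_star = brentq(
        lambda m: _landau_mass(n_eff, 0.0, m) - 0.5 * total,
        1e-9, 1.0 - 1e-9, xtol=1e-13,
    )
    return round(s_star, ndigits) if ndigits is not None else float(s_star)


def default_neff_candidates(atlas_size: int) -> list:
    """Multiples of 5 from 5 up to the atlas region count (capped at 200)."""
    top = min(200, atlas_size)
    return list(range(5, top + 1, 5))


def select_neff(moment_table: Sequence[MomentSummary],
                candidates: Optional[Sequence[int]] = None,
                *, atlas_size: Optional[int] = None,
                objective: str = "cohort_rmse") -> NeffScanResult:
    """Choose the effective region count by the fourth-moment RMSE scan.

    For each candidate n_eff, every subject's coupling is fitted from its
    observed m2 (subjects requiring a negative coupling are dropped for that
    candidate) and the model's fourth moment compared with the observed one.
    objective="cohort_rmse" (default) minimizes
    sqrt(mean_subjects (m4_obs - m4_model)^2); objective="per_subject" sums
    the per-subject absolute errors. The argmin is insensitive to this
    monotone reweighting in the planted-recovery regime.
    """
    if candidates is None:
        if atlas_size is None:
            raise ValueError("provide candidates or atlas_size")
        candidates = default_neff_candidates(atlas_size)
    candidates = [int(c) for c in candidates]
    if not candidates:
        raise ValueError("empty candidate list")
    if len(moment_table) < 2:
        raise ValueError("need at least 2 subjects with valid moments")
    if objective not in ("cohort_rmse", "per_subject"):
        raise ValueError(f"unknown objective {objective!r}")

    obj = np.full(len(candidates), np.nan)
    for j, ne in enumerate(candidates):
        errs = []
        for mom in moment_table:
            fit = fit_lambda(mom.m2, ne)
            if fit.excluded or not math.isfinite(fit.lam_hat):
                continue
            m4_model = model_moments(ne, fit.lam_hat).m4
            errs.append(mom.m4 - m4_model)
        if errs:
            e = np.asarray(errs)
            if objective == "cohort_rmse":
                obj[j] = math.sqrt(float(np.mean(e * e)))
            else:
                obj[j] = float(np.abs(e).sum())
    if np.all(np.isnan(obj)):
        raise ValueError("all subjects excluded at every candidate")
    best = candidates[int(np.nanargmin(obj))]
    return NeffScanResult(candidates=candidates, objective=obj, best=best)


def write_calibration_table(n_effs: Sequence[int], path) -> None:
    """Audit table of (n_eff, lambda_c, s_star), tab-separated."""
    import pandas as pd

    rows = [
        {
            "n_eff": ne,
            "lambda_c": critical_lambda(ne),
            "s_star": calibrate_s_star(ne),
        }
        for ne in n_effs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
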