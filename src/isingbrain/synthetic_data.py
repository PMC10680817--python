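"""Synthetic cohorts with planted mean-field structure.

The generator emulates the statistical structure the analysis assumes: a
subject's brain is ``n_eff_planted`` exchangeable meta-units whose joint
magnetization follows the exact mean-field pmf at a planted coupling; each
meta-unit is copied out to several atlas region channels (optionally with
independent sign-flip noise), and the continuous "scan" is a cumulative sum
of spin-signed positive increments so that slope-sign binarization recovers
the spins exactly. Age enters through a coupling schedule lam(age), letting
cohorts carry a controllable ground-truth aging trend (or none).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .meanfield import pmf
from .synchrony import RegionTimeSeries, write_timeseries

__all__ = [
    "CohortSpec",
    "CohortBundle",
    "linear_lambda_schedule",
    "constant_lambda_schedule",
    "sample_meanfield_spins",
    "expand_to_timeseries",
    "synth_cohort",
    "write_cohort",
    "read_cohort",
]


def linear_lambda_schedule(age_young: float = 20.0, lam_young: float = 30.0,
                           age_old: float = 80.0, lam_old: float = 8.0
                           ) -> Callable[[float], float]:
    """Coupling declining linearly with age (clipped at the endpoints).

    Defaults plant a decline from lam = 30 at age 20 to lam = 8 at age 80 for
    an n_eff = 40 model: couplings sweep from near-critical (lam_c = 20) well
    into the disordered phase, producing a rising Pseg-age trend of the kind
    seen in aging cohorts.
    """
    def schedule(age: float) -> float:
        t = np.clip((age - age_young) / (age_old - age_young), 0.0, 1.0)
        return float(lam_young + t * (lam_old - lam_young))
    return schedule


def constant_lambda_schedule(lam: float) -> Callable[[float], float]:
    """Age-independent coupling (null cohort: no true aging trend)."""
    return lambda age: float(lam)


@dataclass
class CohortSpec:
    """Design of a synthetic cohort.

    Defaults follow a typical resting-state acquisition scale: a 300-region
    atlas, 40 planted effective units, 500-point scans, ages uniform on
    20-80, a linearly declining coupling schedule, and noiseless meta-unit
    expansion.
    """

    n_subjects: int
    seed: int
    n_regions: int = 300
    n_eff_planted: int = 40
    t_scan: int = 500
    age_range: tuple = (20.0, 80.0)
    lambda_schedule: Union[Callable[[float], float], None] = None
    flip_noise: float = 0.0
    subject_prefix: str = "synth"

    def __post_init__(self):
        if self.lambda_schedule is None:
            self.lambda_schedule = linear_lambda_schedule()
        if not 0.0 <= self.flip_noise <= 0.5:
            raise ValueError("flip_noise must lie in [0, 0.5]")
        if self.n_regions < self.n_eff_planted:
            raise ValueError("n_regions must be >= n_eff_planted")


@dataclass
class CohortBundle:
    subjects: list  # of RegionTimeSeries
    metadata: pd.DataFrame
    lambdas: np.ndarray = field(repr=False)


def sample_meanfield_spins(n_eff: int, lam: float, t: int,
                           seed: Union[int, np.random.Generator]) -> np.ndarray:
    """Draw t independent spin columns from the exact mean-field model.

    For each time point the magnetization n is drawn from the pmf by
    inverse-CDF, then (n_eff + n)/2 uniformly chosen units are set to +1 —
    valid because the mean-field model is exchangeable. Columns are
    independent across time (the fit uses only marginal moments).
    Returns an int8 array of shape (n_eff, t).
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = pmf(n_eff, lam)
    cdf = np.cumsum(d.probs)
    cdf[-1] = 1.0
    draws = d.support[np.searchsorted(cdf, rng.random(t))]
    k_up = (n_eff + draws) // 2
    # rank trick: per column, the k_up units with smallest random keys are +1
    ranks = np.argsort(rng.random((n_eff, t)), axis=0).argsort(axis=0)
    spins = np.where(ranks < k_up[None, :], 1, -1).astype(np.int8)
    return spins


def expand_to_timeseries(meta: np.ndarray, n_regions: int, flip_noise: float,
                         seed: Union[int, np.random.Generator],
                         subject_id: str = "synth", **demographics
                         ) -> RegionTimeSeries:
    """Copy meta-unit spins to region channels and integrate to a signal.

    Each of the n_eff meta-units drives floor(n_regions/n_eff) region
    channels; the remainder channels are attached to the first meta-units.
    Every copied spin flips sign independently with probability
    ``flip_noise``. The continuous trace is the cumulative sum of
    spin * u(t) with u(t) iid positive (uniform on [0.5, 1.5], unit mean),
    strictly monotone between flips, so slope-sign binarization recovers the
    noisy spins exactly.
    """
    if not 0.0 <= flip_noise <= 0.5:
        raise ValueError("flip_noise must lie in [0, 0.5]")
    meta = np.asarray(meta)
    n_eff, t = meta.shape
    if n_regions < n_eff:
        raise ValueError("n_regions must be >= n_eff")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    copies = np.full(n_eff, n_regions // n_eff, dtype=np.int64)
    copies[: n_regions % n_eff] += 1
    region_spins = np.repeat(meta, copies, axis=0)
    if flip_noise > 0:
        flips = rng.random(region_spins.shape) < flip_noise
        region_spins = np.where(flips, -region_spins, region_spins)

    increments = rng.uniform(0.5, 1.5, size=region_spins.shape)
    traces = np.concatenate(
        [np.zeros((n_regions, 1)), np.cumsum(region_spins * increments, axis=1)],
        axis=1,
    )
    return RegionTimeSeries(subject_id=subject_id, values=traces, **demographics)


def synth_cohort(spec: CohortSpec) -> CohortBundle:
    """Generate a cohort of subjects with age-dependent planted coupling.

    Ages are uniform over ``spec.age_range``; sex and handedness are
    randomized covariates with zero true effect (sex balanced, handedness 90%
    right, the population base rate). Deterministic for a fixed spec + seed.
    """
    rng = np.random.default_rng(spec.seed)
    ages = rng.uniform(*spec.age_range, size=spec.n_subjects)
    sexes = rng.choice(["F", "M"], size=spec.n_subjects)
    handed = rng.choice(["right", "left"], size=spec.n_subjects, p=[0.9, 0.1])

    subjects, lams, rows = [], [], []
    for i in range(spec.n_subjects):
        lam = spec.lambda_schedule(float(ages[i]))
        if lam < 0:
            raise ValueError(f"lambda_schedule returned negative coupling {lam}")
        sid = f"{spec.subject_prefix}{i:04d}"
        meta = sample_meanfield_spins(spec.n_eff_planted, lam,
                                      spec.t_scan - 1, rng)
        ts = expand_to_timeseries(
            meta, spec.n_regions, spec.flip_noise, rng,
            subject_id=sid, age=float(ages[i]), sex=str(sexes[i]),
            handedness=str(handed[i]),
        )
        subjects.append(ts)
        lams.append(lam)
        rows.append(
            {
                "subject_id": sid,
                "age": float(ages[i]),
                "sex": str(sexes[i]),
                "handedness": str(handed[i]),
                "t_scan": spec.t_scan,
            }
        )
    return CohortBundle(
        subjects=subjects,
        metadata=pd.DataFrame(rows),
        lambdas=np.asarray(lams),
    )


def write_cohort(bundle: CohortBundle, out_dir, spec: Optional[CohortSpec] = None
                 ) -> None:
    """Write per-subject matrices, the metadata table and a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ts in bundle.subjects:
        write_timeseries(ts, out / f"{ts.subject_id}.tsv")
    bundle.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False,
                           float_format="%.17g")
    if spec is not None:
        manifest = {
            "n_subjects": spec.n_subjects,
            "n_regions": spec.n_regions,
            "n_eff_planted": spec.n_eff_planted,
            "t_scan": spec.t_scan,
            "age_range": list(spec.age_range),
            "flip_noise": spec.flip_noise,
            "seed": spec.seed,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_cohort(cohort_dir) -> list:
    """Read a written cohort back as a list of RegionTimeSeries."""
    from .synchrony import read_metadata, read_timeseries

    cohort_dir = Path(cohort_dir)
    meta = read_metadata(cohort_dir / "metadata.tsv")
    subjects = []
    for row in meta.itertuples(index=False):
        ts = read_timeseries(
            cohort_dir / f"{row.subject_id}.tsv",
            subject_id=str(row.subject_id),
            age=float(row.age),
            sex=getattr(row, "sex", None),
            handedness=getattr(row, "handedness", None),
        )
        subjects.append(ts)
    return subjects
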