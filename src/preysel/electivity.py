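"""Manly-Chesson electivity: daily α, per-individual averaging, selection calls.

The Manly-Chesson index for prey type j on one feeding day is

    α_j = (r_j / p_j) / Σ_k (r_k / p_k)

with r the consumed proportions that day and p the offered proportions.
Because prey are replaced every 24 h at the starting relative abundances,
this is Chesson's constant-prey (no-depletion) case.  α sums to 1 over
prey types; under random feeding — consumption proportional to offer —
every component equals 1/m, which serves as the no-selection reference
line.  Per individual, α is computed on each day with at least one prey
consumed and averaged unweighted over those feeding days; non-feeding
days are excluded, never imputed.

Treatment-level inference treats individuals as the independent
replicates: the per-species mean of individual mean-α values gets a
two-sided confidence interval (Student t by default, bootstrap
optionally), and a species is called positively selected if the whole
interval lies above 1/m, negatively selected (avoided) if wholly below.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records_io import FeedingRecord, TreatmentSpec, ValidationError

__all__ = [
    "ElectivityVector",
    "SelectionCall",
    "manly_chesson_alpha",
    "individual_alpha",
    "treatment_selection",
    "rank_prey",
    "UndefinedDayError",
]


class UndefinedDayError(ValueError):
    """α requested for a day (or subject) with zero total consumption."""


@dataclass(frozen=True)
class ElectivityVector:
    """Per-individual electivity: mean daily α over feeding days."""

    subject: str
    species: tuple[str, ...]
    alpha: tuple[float, ...]
    basis_days: int

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha)
        if self.basis_days >= 1:
            if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
                raise ValidationError("alpha components must lie in [0, 1]")
            if abs(a.sum() - 1.0) > 1e-9:
                raise ValidationError("alpha must sum to 1")


@dataclass(frozen=True)
class SelectionCall:
    """Selection classification of one species in one treatment."""

    species: str
    mean_alpha: float
    ci_low: float
    ci_high: float
    n_individuals: int
    call: Literal["positive", "negative", "none"]
    ci_defined: bool = True


def manly_chesson_alpha(
    daily_counts: Sequence[int] | np.ndarray,
    offered_props: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Daily Manly-Chesson α for one predator-day.

    Parameters
    ----------
    daily_counts
        Prey consumed per species in one 24 h period; must sum to ≥ 1.
    offered_props
        Offered relative abundances p_j; strictly positive wherever the
        corresponding count is positive.

    Returns
    -------
    α vector summing to 1.  A species never consumed contributes
    r_j = 0 and hence α_j = 0 regardless of p_j.
    """
    x = np.asarray(daily_counts, dtype=float)
    p = np.asarray(offered_props, dtype=float)
    if x.shape != p.shape:
        raise ValueError("counts and offered proportions differ in length")
    total = x.sum()
    if total < 1:
        raise UndefinedDayError("no prey consumed: daily alpha undefined")
    if np.any((x > 0) & (p <= 0)):
        raise ValidationError("positive consumption of a species offered at proportion 0")
    r = x / total
    ratio = np.divide(r, p, out=np.zeros_like(r), where=p > 0)
    return ratio / ratio.sum()


def individual_alpha(
    records: Sequence[FeedingRecord],
    spec: TreatmentSpec,
    *,
    method: Literal["daily_mean", "pooled"] = "daily_mean",
) -> ElectivityVector:
    """Averaged electivity for one predator.

    ``daily_mean`` (default) computes α on each feeding day and takes
    the unweighted arithmetic mean; ``pooled`` sums counts over all days
    first and computes a single α (the two agree closely in practice).
    """
    recs = [r for r in records if r.treatment_id == spec.treatment_id]
    subjects = {r.predator_id for r in recs}
    if len(subjects) != 1:
        raise ValueError(f"expected records for exactly one predator, got {sorted(subjects)}")
    subject = subjects.pop()
    p = spec.offered_props
    feeding = [r for r in recs if r.total >= 1]
    if not feeding:
        raise UndefinedDayError(f"predator {subject} has no feeding days")
    if method == "pooled":
        totals = np.sum([r.counts for r in feeding], axis=0)
        alpha = manly_chesson_alpha(totals, p)
    elif method == "daily_mean":
        alpha = np.mean([manly_chesson_alpha(r.counts, p) for r in feeding], axis=0)
    else:
        raise ValueError(f"unknown averaging method {method!r}")
    return ElectivityVector(
        subject=subject,
        species=spec.species,
        alpha=tuple(float(a) for a in alpha),
        basis_days=len(feeding),
    )


def _t_interval(values: np.ndarray, level: float) -> tuple[float, float]:
    n = len(values)
    mean = float(values.mean())
    if n < 2:
        return mean, mean
    se = float(values.std(ddof=1)) / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + level / 2, df=n - 1)
    return mean - tcrit * se, mean + tcrit * se


def _bootstrap_interval(
    values: np.ndarray, level: float, replicates: int, rng: np.random.Generator
) -> tuple[float, float]:
    idx = rng.integers(0, len(values), size=(replicates, len(values)))
    means = values[idx].mean(axis=1)
    lo, hi = np.quantile(means, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


def treatment_selection(
    alphas: Sequence[ElectivityVector],
    *,
    level: float = 0.95,
    method: Literal["t", "bootstrap"] = "t",
    bootstrap_replicates: int = 10000,
    seed: int | None = None,
) -> list[SelectionCall]:
    """Classify each species' selection from per-individual mean α.

    The CI on the across-individual mean is compared with the random
    feeding line 1/m: entirely above → ``positive``, entirely below →
    ``negative``, otherwise ``none``.  With a single individual no CI
    exists; the call is ``none`` with ``ci_defined=False``.
    """
    if not alphas:
        raise ValueError("no electivity vectors supplied")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    species = alphas[0].species
    if any(v.species != species for v in alphas):
        raise ValueError("electivity vectors disagree on species ordering")
    mat = np.array([v.alpha for v in alphas])  # individuals × species
    n = mat.shape[0]
    m = len(species)
    line = 1.0 / m
    rng = np.random.default_rng(seed)
    calls: list[SelectionCall] = []
    for j, sp in enumerate(species):
        vals = mat[:, j]
        mean = float(vals.mean())
        if n < 2:
            calls.append(SelectionCall(sp, mean, mean, mean, n, "none", ci_defined=False))
            continue
        if method == "t":
            lo, hi = _t_interval(vals, level)
        elif method == "bootstrap":
            lo, hi = _bootstrap_interval(vals, level, bootstrap_replicates, rng)
        else:
            raise ValueError(f"unknown CI method {method!r}")
        call: Literal["positive", "negative", "none"]
        if lo > line:
            call = "positive"
        elif hi < line:
            call = "negative"
        else:
            call = "none"
        calls.append(SelectionCall(sp, mean, lo, hi, n, call))
    return calls


def rank_prey(alpha: Sequence[float] | np.ndarray) -> list[int]:
    """Descending ranks of an α vector; tied values share the best rank.

    ``(0.5, 0.3, 0.1, 0.1)`` ranks as ``[1, 2, 3, 3]``; a uniform vector
    is a single tie group ``[1, 1, 1, 1]``.
    """
    a = np.asarray(alpha, dtype=float)
    return [int(r) for r in stats.rankdata(-a, method="min")]


def selection_table(calls: Sequence[SelectionCall], treatment_id: str) -> pd.DataFrame:
    """Tabular form of treatment-level selection calls."""
    return pd.DataFrame(
        {
            "treatment_id": treatment_id,
            "species": [c.species for c in calls],
            "mean_alpha": [c.mean_alpha for c in calls],
            "ci_low": [c.ci_low for c in calls],
            "ci_high": [c.ci_high for c in calls],
            "n_individuals": [c.n_individuals for c in calls],
            "call": [c.call for c in calls],
            "ci_defined": [c.ci_defined for c in calls],
        }
    )


def individual_table(vectors: Sequence[ElectivityVector], treatment_id: str) -> pd.DataFrame:
    """One row per (predator, species) with the mean individual α."""
    rows = []
    for v in vectors:
        for sp, a in zip(v.species, v.alpha):
            rows.append(
                {
                    "treatment_id": treatment_id,
                    "predator_id": v.subject,
                    "species": sp,
                    "mean_alpha": a,
                    "basis_days": v.basis_days,
                }
            )
    return pd.DataFrame(rows)
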