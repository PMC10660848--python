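"""Sleep-cycle invariant (SCI): per-night products and constancy testing.

The SCI is the product of an NREM episode's duration and the intensity
(REM density) of the REM episode that follows it.  Because NREM duration
tracks the oscillation period 2 pi / delta_eps while REM intensity tracks
the released gap delta_eps, the product is predicted constant across
cycles.  The observed first NREM episode is curtailed to ~3/4 of a period
by the onset position, so its duration is multiplied by 4/3 before the
product is formed (the ``correct_first`` flag, on by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .fitting import CycleSeries

__all__ = [
    "FIRST_CYCLE_CORRECTION",
    "ConstancyResult",
    "SCIResult",
    "sci_per_night",
    "sci_group",
    "sci_constancy_test",
    "sci_constancy_anova",
    "hybrid_sci",
]

#: observed cycle-1 NREM duration is ~3/4 of the full period
FIRST_CYCLE_CORRECTION = 4.0 / 3.0


@dataclass(frozen=True)
class ConstancyResult:
    """Chi-square test of per-cycle means against their weighted grand mean.

    High p is consistent with a constant product across cycles.  When no
    SEMs are available the test falls back to unit weights
    (``weighted=False``).
    """

    statistic: float
    dof: int
    p_value: float
    grand_mean: float
    weighted: bool = True


@dataclass
class SCIResult:
    """Per-cycle SCI products with group statistics and the constancy test."""

    products: np.ndarray
    products_rel: np.ndarray
    sem: Optional[np.ndarray]
    grand_mean: float
    constancy: ConstancyResult
    notes: list = field(default_factory=list)


def sci_per_night(nrem_min, rem_density, correct_first: bool = True) -> np.ndarray:
    """Per-cycle products NREM duration x following-REM density for one night.

    ``rem_density[i]`` must belong to the REM episode following NREM episode
    ``i``.  With ``correct_first`` the cycle-1 duration is multiplied by 4/3
    before the product is formed.
    """
    t = np.asarray(nrem_min, dtype=float).copy()
    d = np.asarray(rem_density, dtype=float)
    if t.shape != d.shape:
        raise ValueError(
            f"misaligned series: {t.shape} NREM values vs {d.shape} densities"
        )
    if t.size == 0:
        raise ValueError("empty series")
    if correct_first:
        t[0] *= FIRST_CYCLE_CORRECTION
    return t * d


def sci_constancy_test(means, sems=None) -> ConstancyResult:
    """Chi-square of per-cycle means against the SEM-weighted grand mean.

    ``chi2 = sum ((m_i - m_bar)/sem_i)^2`` with ``m_bar`` the
    inverse-variance-weighted mean, ``dof = cycles - 1``, one-sided
    upper-tail p.  Unit weights (flagged) when SEMs are missing.
    """
    m = np.asarray(means, dtype=float)
    if m.size < 3:
        raise ValueError("need at least 3 cycles for a constancy test")
    weighted = sems is not None
    if weighted:
        s = np.asarray(sems, dtype=float)
        if s.shape != m.shape or np.any(s <= 0):
            raise ValueError("sems must be positive and match means in length")
    else:
        s = np.ones_like(m)
    w = 1.0 / s**2
    grand = float(np.sum(w * m) / np.sum(w))
    chi2 = float(np.sum(((m - grand) / s) ** 2))
    dof = m.size - 1
    return ConstancyResult(statistic=chi2, dof=dof,
                           p_value=float(stats.chi2.sf(chi2, dof)),
                           grand_mean=grand, weighted=weighted)


def sci_constancy_anova(products_by_cycle) -> ConstancyResult:
    """One-way ANOVA across cycles with nights as replicates (alternative test).

    ``products_by_cycle`` is a sequence of per-night product arrays, one per
    cycle (unbalanced groups allowed).
    """
    groups = [np.asarray(g, dtype=float) for g in products_by_cycle]
    if len(groups) < 3:
        raise ValueError("need at least 3 cycles")
    f, p = stats.f_oneway(*groups)
    dof = len(groups) - 1
    grand = float(np.mean(np.concatenate(groups)))
    return ConstancyResult(statistic=float(f), dof=dof, p_value=float(p),
                           grand_mean=grand, weighted=False)


def sci_group(nrem_by_night, density_by_night,
              correct_first: bool = True) -> SCIResult:
    """Group-level SCI from night-level series.

    Inputs are sequences (one entry per night) of per-cycle arrays; nights
    may contribute different numbers of cycles (per-cycle n is carried
    through the SEMs).
    """
    prods: list[np.ndarray] = []
    for t, d in zip(nrem_by_night, density_by_night, strict=True):
        prods.append(sci_per_night(t, d, correct_first=correct_first))
    n_cycles = max(len(p) for p in prods)
    by_cycle = [
        np.array([p[k] for p in prods if len(p) > k and np.isfinite(p[k])])
        for k in range(n_cycles)
    ]
    means = np.array([g.mean() for g in by_cycle])
    counts = np.array([len(g) for g in by_cycle])
    sem = np.array([
        g.std(ddof=1) / np.sqrt(len(g)) if len(g) > 1 else np.nan
        for g in by_cycle
    ])
    notes = []
    if np.any(~np.isfinite(sem)) or np.any(sem == 0):
        constancy = sci_constancy_test(means)
        sem_out = None
        notes.append("SEMs unavailable or degenerate: unit-weight constancy test")
    else:
        constancy = sci_constancy_test(means, sem)
        sem_out = sem
    result = SCIResult(
        products=means,
        products_rel=means / means[0],
        sem=sem_out,
        grand_mean=constancy.grand_mean,
        constancy=constancy,
        notes=notes,
    )
    result.notes.append(f"nights per cycle: {counts.tolist()}")
    return result


def hybrid_sci(nrem: CycleSeries, rem_density: CycleSeries,
               correct_first: bool = True) -> SCIResult:
    """SCI from an NREM-duration series and a REM-density series of
    different origin (e.g. two independent studies).

    Both series are normalized to cycle 1 (the 4/3 correction is applied to
    the NREM cycle-1 value *before* normalization), multiplied over their
    overlapping cycle range and tested for constancy.
    """
    k = min(len(nrem), len(rem_density))
    if k < 3:
        raise ValueError("need at least 3 overlapping cycles")
    t = nrem.values[:k].copy()
    if correct_first:
        t[0] *= FIRST_CYCLE_CORRECTION
    t_rel = t / t[0]
    d_rel = rem_density.values[:k] / rem_density.values[0]
    prod = t_rel * d_rel
    sem = None
    if nrem.sem is not None and rem_density.sem is not None:
        rel_t = nrem.sem[:k] / nrem.values[:k]
        rel_d = rem_density.sem[:k] / rem_density.values[:k]
        sem = prod * np.sqrt(rel_t**2 + rel_d**2)
        sem = np.where(sem > 0, sem, np.nan)
    notes = []
    if sem is not None and np.all(np.isfinite(sem)):
        constancy = sci_constancy_test(prod, sem)
    else:
        constancy = sci_constancy_test(prod)
        sem = None
        notes.append("SEMs unavailable or degenerate: unit-weight constancy test")
    return SCIResult(products=prod, products_rel=prod / prod[0], sem=sem,
                     grand_mean=constancy.grand_mean, constancy=constancy,
                     notes=notes)
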