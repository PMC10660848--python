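"""Chi-square estimation of wave-model parameters from per-cycle group data.

Conventions: goodness of fit is a one-sided upper-tail chi-square test with
``dof = n_indep - 1 - p_fitted``; SEM weights are used when available, unit
weights otherwise; the first cycle is excluded from duration fits by default
because its observed duration is curtailed by the onset position (a
4/3-corrected inclusion mode is provided).

A note on identifiability: with the time scale free, the NREM-duration curve
``a * 4 pi sigma^2 / (2 sigma - j_in + n - 1)`` depends on (sigma, j_in) only
through ``c = 2 sigma - j_in`` — durations alone sit on an exact chi-square
ridge.  Supplying the normalized NREM-intensity series (parameter-free given
sigma and j_in, and not scale-invariant in energy because the well depth is
fixed at 1) breaks the ridge and identifies both parameters.  Duration-only
fits are flagged ``sigma_jin_degenerate`` and tie-break to the smallest j_in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import morse, model
from .morse import MorseWell

__all__ = [
    "CycleSeries",
    "FitResult",
    "chi2_objective",
    "fit_nrem_durations",
    "fit_rem_durations",
    "predict_intensities",
    "goodness_of_fit",
    "r_squared",
]

MEASURES = (
    "nrem_duration",
    "rem_duration",
    "nrem_intensity",
    "rem_intensity",
    "rem_density",
    "sci",
)

#: default search bounds; cover ladders with up to ~120 bound levels
SIGMA_BOUNDS = (0.75, 60.0)
GAMMA_BOUNDS = (1e-4, 1.0)


@dataclass
class CycleSeries:
    """Per-cycle group values of one sleep measure, with uncertainty.

    ``values[i]`` belongs to cycle ``cycles[i]``; cycle indices must be
    consecutive from 1.  ``sem`` (same units, > 0) and ``n_nights`` are
    optional.  ``normalized`` marks series scaled to cycle 1 (value(1)=1).
    """

    values: np.ndarray
    sem: Optional[np.ndarray] = None
    n_nights: Optional[np.ndarray] = None
    measure: str = "nrem_duration"
    normalized: bool = False
    cycles: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.cycles is None:
            self.cycles = np.arange(1, len(self.values) + 1)
        self.cycles = np.asarray(self.cycles, dtype=int)
        if not np.array_equal(self.cycles, np.arange(1, len(self.values) + 1)):
            raise ValueError("cycle indices must be consecutive from 1")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if self.sem.shape != self.values.shape:
                raise ValueError("sem must match values in length")
            if np.any(self.sem <= 0):
                raise ValueError("sem must be > 0 where provided")
        if self.n_nights is not None:
            self.n_nights = np.asarray(self.n_nights, dtype=int)
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}; one of {MEASURES}")
        if self.normalized and not math.isclose(self.values[0], 1.0,
                                                rel_tol=1e-9):
            raise ValueError("normalized series must have value 1 at cycle 1")

    def __len__(self) -> int:
        return len(self.values)

    def weights(self) -> np.ndarray:
        """1/sem^2 when SEMs are present, unit weights otherwise."""
        if self.sem is None:
            return np.ones_like(self.values)
        return 1.0 / self.sem**2

    def normalize_to_first(self) -> "CycleSeries":
        v1 = self.values[0]
        sem = None if self.sem is None else self.sem / v1
        return CycleSeries(self.values / v1, sem=sem, n_nights=self.n_nights,
                           measure=self.measure, normalized=True)

    def to_frame(self) -> pd.DataFrame:
        d = {"n": self.cycles, "value": self.values}
        if self.sem is not None:
            d["sem"] = self.sem
        if self.n_nights is not None:
            d["n_nights"] = self.n_nights
        return pd.DataFrame(d)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, measure: str = "nrem_duration",
                   normalized: bool = False) -> "CycleSeries":
        df = df.sort_values("n")
        return cls(
            df["value"].to_numpy(),
            sem=df["sem"].to_numpy() if "sem" in df else None,
            n_nights=df["n_nights"].to_numpy() if "n_nights" in df else None,
            measure=measure,
            normalized=normalized,
            cycles=df["n"].to_numpy(),
        )


@dataclass
class FitResult:
    """Parameter estimates with chi-square goodness of fit."""

    estimates: dict
    chi2: float
    dof: Optional[int]
    p_value: Optional[float]
    r2: float
    options: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            **self.estimates,
            "chi2": self.chi2,
            "dof": self.dof,
            "p": self.p_value,
            "r2": self.r2,
            "options": self.options,
            "flags": list(self.flags),
        }


def chi2_objective(observed: CycleSeries, predicted: CycleSeries,
                   exclude_first: bool = False) -> float:
    """Sum over cycles of ((obs - pred)/sem)^2 (unit weights without SEMs)."""
    common = np.intersect1d(observed.cycles, predicted.cycles)
    if exclude_first:
        common = common[common != 1]
    if common.size == 0:
        raise ValueError("no overlapping cycles between observed and predicted")
    io = np.searchsorted(observed.cycles, common)
    ip = np.searchsorted(predicted.cycles, common)
    resid = observed.values[io] - predicted.values[ip]
    return float(np.sum(observed.weights()[io] * resid**2))


def goodness_of_fit(chi2: float, n_indep: int, p_fitted: int) -> tuple[int, float]:
    """(dof, upper-tail p) with dof = n_indep - 1 - p_fitted.

    The "- 1" accounts for the cycle-1 normalization of the plotted series;
    for unnormalized duration fits pass the number of included cycles as
    ``n_indep`` (the same arithmetic then reads n - 1 - p with n = cycles).
    """
    dof = n_indep - 1 - p_fitted
    if dof < 1:
        raise ValueError(
            f"dof = {n_indep} - 1 - {p_fitted} = {dof} < 1: "
            "drop parameters or add cycles to report a p-value"
        )
    return dof, float(stats.chi2.sf(chi2, dof))


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot about the observed mean."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: observations have zero variance")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


def predict_intensities(sigma: float, j_in: int,
                        n_cycles: int) -> tuple[CycleSeries, CycleSeries]:
    """Parameter-free normalized NREM- and REM-intensity series.

    Both equal 1 at cycle 1; the REM series is exactly linear with slope
    ``1/(2 sigma - j_in)``.  These carry no adjustable parameters
    (p_fitted = 0 in the dof accounting).
    """
    params = model.SleepModelParams(sigma=sigma, j_in=j_in, eps_res=-0.5,
                                    gamma=1.0)
    nrem = [model.nrem_intensity_rel(params, n) for n in range(1, n_cycles + 1)]
    rem = [model.rem_intensity_rel(params, n) for n in range(1, n_cycles + 1)]
    return (
        CycleSeries(np.array(nrem), measure="nrem_intensity", normalized=True),
        CycleSeries(np.array(rem), measure="rem_intensity", normalized=True),
    )


def _wls_scale(y: np.ndarray, m: np.ndarray, w: np.ndarray) -> float:
    """Closed-form weighted least-squares scale minimizing sum w (y - a m)^2."""
    denom = float(np.sum(w * m * m))
    if denom == 0.0:
        return 0.0
    return float(np.sum(w * y * m)) / denom


def _nrem_shape(sigma: float, j_in: int, cycles: np.ndarray,
                first_cycle_correction: bool) -> np.ndarray:
    # dimensionless periods along the ladder, optionally 3/4 on cycle 1
    shape = 4.0 * math.pi * sigma**2 / (2.0 * sigma - j_in + cycles - 1.0)
    if first_cycle_correction:
        shape = np.where(cycles == 1, model.FIRST_CYCLE_FRACTION * shape, shape)
    return shape


def _intensity_chi2(sigma: float, j_in: int, intensity: CycleSeries) -> float:
    pred, _ = predict_intensities(sigma, j_in, int(intensity.cycles.max()))
    return chi2_objective(intensity, pred)


def fit_nrem_durations(
    observed: CycleSeries,
    intensity: Optional[CycleSeries] = None,
    exclude_first: bool = True,
    first_cycle_correction: bool = False,
    sigma_bounds: tuple[float, float] = SIGMA_BOUNDS,
) -> FitResult:
    """Estimate (sigma, j_in, a_nr) from per-cycle NREM durations.

    Exhaustive grid over integer ``j_in`` crossed with a bounded 1-D search
    over sigma; the time scale ``a_nr`` is a closed-form weighted
    least-squares scale at each candidate.  ``intensity`` (a normalized
    NREM-intensity series) is folded into the objective when given — see the
    module note on identifiability.  Ties in chi-square report the smallest
    j_in.  Deterministic given bounds and grid.
    """
    cycles = observed.cycles
    mask = cycles != 1 if exclude_first else np.ones_like(cycles, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("need at least two included cycles to fit durations")
    y = observed.values[mask]
    w = observed.weights()[mask]
    cyc = cycles[mask]
    n_obs_cycles = int(cycles.max())

    def duration_chi2(sigma: float, j_in: int) -> tuple[float, float]:
        shape = _nrem_shape(sigma, j_in, cyc, first_cycle_correction)
        a = _wls_scale(y, shape, w)
        return float(np.sum(w * (y - a * shape) ** 2)), a

    def total_chi2(sigma: float, j_in: int) -> float:
        c2, _ = duration_chi2(sigma, j_in)
        if intensity is not None:
            c2 += _intensity_chi2(sigma, j_in, intensity)
        return c2

    lo, hi = sigma_bounds
    j_in_max = math.floor(2.0 * hi - 0.5)
    best = None
    for j_in in range(n_obs_cycles, j_in_max + 1):
        # ladder must exist: j_in <= jmax(sigma) i.e. sigma >= (j_in + 1/2)/2
        s_lo = max(lo, (j_in + 0.5) / 2.0 + 1e-9)
        if s_lo >= hi:
            break
        res = optimize.minimize_scalar(
            total_chi2, bounds=(s_lo, hi), args=(j_in,), method="bounded",
            options={"xatol": 1e-10},
        )
        if best is None or res.fun < best[0] * (1.0 - 1e-9) - 1e-12:
            best = (float(res.fun), j_in, float(res.x), s_lo)

    chi2_total, j_in_hat, sigma_hat, s_lo = best
    chi2_dur, a_nr = duration_chi2(sigma_hat, j_in_hat)
    shape = _nrem_shape(sigma_hat, j_in_hat, cyc, first_cycle_correction)
    flags = []
    try:
        r2 = r_squared(y, a_nr * shape)
    except ValueError:
        r2 = float("nan")
        flags.append("r2_undefined")

    if intensity is None:
        flags.append("sigma_jin_degenerate")
    if sigma_hat - s_lo < 1e-4 * (hi - lo) or hi - sigma_hat < 1e-4 * (hi - lo):
        flags.append("boundary")

    p_fitted = 3  # sigma, j_in, a_nr
    n_indep = int(mask.sum())
    try:
        dof, p = goodness_of_fit(chi2_dur, n_indep, p_fitted)
    except ValueError:
        dof, p = None, None
        flags.append("too_few_cycles_for_p")
    return FitResult(
        estimates={"sigma": sigma_hat, "j_in": j_in_hat, "a_nr": a_nr},
        chi2=chi2_dur,
        dof=dof,
        p_value=p,
        r2=r2,
        options={
            "exclude_first": exclude_first,
            "first_cycle_correction": first_cycle_correction,
            "sigma_bounds": list(sigma_bounds),
            "weights": "sem" if observed.sem is not None else "unit",
            "intensity_informed": intensity is not None,
            "chi2_total": chi2_total,
            "p_fitted": p_fitted,
        },
        flags=flags,
    )


def fit_rem_durations(
    observed: CycleSeries,
    sigma: float,
    j_in: int,
    exclude_first: bool = False,
    gamma_bounds: tuple[float, float] = GAMMA_BOUNDS,
    n_starts: int = 24,
    seed: int = 0,
) -> FitResult:
    """Estimate (eps_res, gamma, a_rem) from per-cycle REM durations.

    (sigma, j_in) are fixed, normally from :func:`fit_nrem_durations`.
    Bounded multi-start Nelder-Mead over (eps_res, gamma) with a closed-form
    weighted least-squares scale; the start grid spans the ladder energies
    and is jittered with a recorded seed.  A fit whose resonance lies below
    the lowest ladder energy reached is flagged ``threshold_not_reached``
    (monotone-increasing REM series: the night ended above the homeostatic
    threshold).
    """
    well = MorseWell(sigma)
    cycles = observed.cycles
    mask = cycles != 1 if exclude_first else np.ones_like(cycles, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("need at least three included cycles to fit resonance")
    y = observed.values[mask]
    w = observed.weights()[mask]
    levels = np.array([
        morse.energy_level(well, j_in - int(n) + 1) for n in cycles[mask]
    ])

    g_lo, g_hi = gamma_bounds

    def chi2_of(theta: np.ndarray) -> float:
        eps_res, log_gamma = theta
        gamma = math.exp(log_gamma)
        if not (-1.0 < eps_res < 0.0) or not (g_lo <= gamma <= g_hi):
            return 1e12
        half = 0.5 * gamma
        tau = (half / math.pi) / ((levels - eps_res) ** 2 + half * half)
        a = _wls_scale(y, tau, w)
        return float(np.sum(w * (y - a * tau) ** 2))

    rng = np.random.default_rng(seed)
    e_span = np.linspace(max(levels.min() * 1.5, -0.95), levels.max() * 0.5, 6)
    g_span = np.exp(np.linspace(math.log(g_lo * 10), math.log(g_hi), 4))
    starts = [(e, math.log(g)) for e in e_span for g in g_span]
    rng.shuffle(starts)
    starts = starts[:n_starts]
    best = None
    for start in starts:
        res = optimize.minimize(chi2_of, np.asarray(start),
                                method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    eps_hat, gamma_hat = float(best.x[0]), float(math.exp(best.x[1]))
    half = 0.5 * gamma_hat
    tau = (half / math.pi) / ((levels - eps_hat) ** 2 + half * half)
    a_rem = _wls_scale(y, tau, w)
    chi2 = float(np.sum(w * (y - a_rem * tau) ** 2))
    r2 = r_squared(y, a_rem * tau)

    flags = []
    if eps_hat < levels.min():
        flags.append("threshold_not_reached")
    p_fitted = 3  # eps_res, gamma, a_rem
    n_indep = int(mask.sum())
    try:
        dof, p = goodness_of_fit(chi2, n_indep, p_fitted)
    except ValueError:
        dof, p = None, None
        flags.append("too_few_cycles_for_p")
    return FitResult(
        estimates={"eps_res": eps_hat, "gamma": gamma_hat, "a_rem": a_rem},
        chi2=chi2,
        dof=dof,
        p_value=p,
        r2=r2,
        options={
            "sigma": sigma,
            "j_in": j_in,
            "exclude_first": exclude_first,
            "gamma_bounds": list(gamma_bounds),
            "n_starts": len(starts),
            "seed": seed,
            "weights": "sem" if observed.sem is not None else "unit",
            "p_fitted": p_fitted,
        },
        flags=flags,
    )
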