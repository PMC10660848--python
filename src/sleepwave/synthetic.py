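"""Synthetic group sleep data with the wave model's statistical structure.

Night-level per-cycle tables are the model means (periods, Lorentzian
delays, intensity ladders) under multiplicative log-normal observation
noise — one unit-mean factor per night and measure, emulating night-to-night
variation in overall sleep pressure — with the first NREM episode curtailed
by a jittered onset fraction (mean 3/4) and REM eye movements drawn as
Poisson counts at the model's density.  Epoch-quantized hypnograms
consistent with the per-cycle tables let the whole pipeline — segmentation,
fitting, SCI — run end to end without external recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from . import model
from .model import SleepModelParams, RelaxationComplete
from .fitting import CycleSeries
from .hypnogram import Hypnogram

__all__ = [
    "GeneratorConfig",
    "default_params",
    "default_config",
    "generate_cycle_tables",
    "generate_hypnogram",
    "generate_night_hypnograms",
    "semiquantitative_transform",
]


def default_params() -> SleepModelParams:
    """Canonical regular-sleep parameters used by the generator.

    sigma=10, j_in=16 gives a 5-cycle ladder with 2*sigma - j_in = 4 levels
    above onset (NREM ratios 1 : 0.80 : 0.67 : 0.57 : 0.50); the resonance
    sits at the cycle-3 level energy so REM duration is bell-shaped with its
    peak mid-night; scales give ~91 min first NREM, ~25 min peak REM,
    45 min cycle-1 SWS and 4 eye movements/min cycle-1 REM density.
    """
    sigma = 10.0
    eps_res = -((1.0 - (14 + 0.5) / (2 * sigma)) ** 2)  # level-14 energy
    return SleepModelParams(sigma=sigma, j_in=16, eps_res=eps_res, gamma=0.05,
                            a_nr=0.29, a_rem=2.0, i_nr1=45.0, i_r1=4.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for synthetic group generation.

    Observation noise is multiplicative log-normal per night and measure
    (durations 8% CV, SWS 10% CV): each night draws one unit-mean factor
    per measure, shared across its cycles — a night-level scale effect.
    The first-cycle fraction is a truncated normal around 3/4 (sd 0.08 on
    (0.5, 1)) standing in for the variable onset position; REM eye
    movements are Poisson at rate ``i_r1 * I_R(n)/I_R(1)`` events/min
    (switchable off for noise-free pipeline-identity checks).
    """

    params: SleepModelParams = field(default_factory=default_params)
    n_nights: int = 40
    n_cycles: int = 5
    cv_duration: float = 0.08
    cv_sws: float = 0.10
    first_frac_mean: float = 0.75
    first_frac_sd: float = 0.08
    first_frac_bounds: tuple[float, float] = (0.5, 1.0)
    poisson_em: bool = True
    epoch_len_s: float = 30.0
    n1_leadin_epochs: int = 0
    w_tail_min: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_duration < 0 or self.cv_sws < 0 or self.first_frac_sd < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.n_nights < 1 or self.n_cycles < 1:
            raise ValueError("n_nights and n_cycles must be >= 1")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)

    def metadata(self) -> dict:
        d = asdict(self)
        d["params"] = asdict(self.params)
        return d


def default_config(seed: int = 0, **kwargs) -> GeneratorConfig:
    return GeneratorConfig(seed=seed, **kwargs)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    s2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * s2, sigma=math.sqrt(s2), size=size)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    if sd == 0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return x
    raise RuntimeError("truncated-normal sampling failed (bounds too tight)")


def generate_cycle_tables(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict[str, CycleSeries]]:
    """Per-night and group-aggregated per-cycle tables.

    Returns ``(per_night, group)`` where ``per_night`` has one row per
    (night, cycle) with columns ``night, n, t_nrem_min, t_rem_min, sws_min,
    rem_density, first_frac`` and ``group`` maps measure name to a
    :class:`~sleepwave.fitting.CycleSeries` of mean +/- SEM across nights.
    Deterministic given the seed.  Nights are shortened with a notice
    (frame ``attrs``) if the relaxation ladder exhausts before ``n_cycles``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    p = cfg.params
    n_feasible = min(cfg.n_cycles, p.j_in)  # j(n) >= 1
    truncated = n_feasible < cfg.n_cycles

    mean_nrem = np.array([model.nrem_duration(p, n) for n in range(1, n_feasible + 1)])
    mean_rem = np.array([model.rem_duration(p, n) for n in range(1, n_feasible + 1)])
    i_nr1 = p.i_nr1 if p.i_nr1 is not None else 45.0
    i_r1 = p.i_r1 if p.i_r1 is not None else 4.0
    mean_sws = i_nr1 * np.array(
        [model.nrem_intensity_rel(p, n) for n in range(1, n_feasible + 1)])
    dens_rate = i_r1 * np.array(
        [model.rem_intensity_rel(p, n) for n in range(1, n_feasible + 1)])

    rows = []
    for night in range(cfg.n_nights):
        frac = _truncnorm(rng, cfg.first_frac_mean, cfg.first_frac_sd,
                          *cfg.first_frac_bounds)
        # one shared factor per measure and night: night-level scale noise
        t_nrem = mean_nrem * _lognormal_factor(rng, cfg.cv_duration, ())
        t_nrem[0] *= frac
        t_rem = mean_rem * _lognormal_factor(rng, cfg.cv_duration, ())
        sws = mean_sws * _lognormal_factor(rng, cfg.cv_sws, ())
        sws = np.minimum(sws, t_nrem)  # SWS cannot exceed its episode
        if cfg.poisson_em:
            counts = rng.poisson(dens_rate * t_rem)
            density = counts / t_rem
        else:
            density = dens_rate.copy()
        for k in range(n_feasible):
            rows.append(dict(night=night, n=k + 1, t_nrem_min=t_nrem[k],
                             t_rem_min=t_rem[k], sws_min=sws[k],
                             rem_density=density[k], first_frac=frac))
    per_night = pd.DataFrame(rows)
    per_night.attrs["seed"] = cfg.seed
    per_night.attrs["relaxation_complete"] = truncated
    if truncated:
        per_night.attrs["notice"] = (
            f"ladder exhausted after {n_feasible} of {cfg.n_cycles} cycles"
        )

    group: dict[str, CycleSeries] = {}
    col_for = {
        "nrem_duration": "t_nrem_min",
        "rem_duration": "t_rem_min",
        "nrem_intensity": "sws_min",
        "rem_density": "rem_density",
    }
    for measure, col in col_for.items():
        g = per_night.groupby("n")[col]
        mean = g.mean().to_numpy()
        n = g.count().to_numpy()
        sd = g.std(ddof=1).to_numpy()
        with np.errstate(invalid="ignore"):
            sem = sd / np.sqrt(n)
        ok = np.all(np.isfinite(sem)) and np.all(sem > 0)
        group[measure] = CycleSeries(mean, sem=sem if ok else None,
                                     n_nights=n, measure=measure)
    return per_night, group


def generate_hypnogram(night_table: pd.DataFrame, cfg: GeneratorConfig,
                       rng: np.random.Generator | None = None,
                       night_id: str = "night-0") -> Hypnogram:
    """Epoch-quantized hypnogram for one night's per-cycle table.

    Each NREM episode opens with two N2 epochs (the scoring anchor),
    carries its SWS minutes as an early block, and is padded with N2;
    REM episodes carry per-epoch Poisson eye-movement counts at the
    night's density; a wake tail closes the night.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    per_min = 60.0 / cfg.epoch_len_s
    stages: list[str] = []
    counts: list[int] = []

    def push(stage: str, n: int, em_rate: float = 0.0) -> None:
        stages.extend([stage] * n)
        if em_rate > 0:
            counts.extend(rng.poisson(em_rate / per_min, size=n).tolist())
        else:
            counts.extend([0] * n)

    for row in night_table.sort_values("n").itertuples():
        nrem_ep = int(round(row.t_nrem_min * per_min))
        rem_ep = int(round(row.t_rem_min * per_min))
        if nrem_ep < 2 or rem_ep < 2:
            raise ValueError(
                f"cycle {row.n}: episode shorter than 2 epochs "
                f"(NREM {nrem_ep}, REM {rem_ep}); adjust the configuration"
            )
        sws_ep = min(int(round(row.sws_min * per_min)), nrem_ep - 2)
        if cfg.n1_leadin_epochs:
            push("N1", cfg.n1_leadin_epochs)
        push("N2", 2)
        push("SWS", sws_ep)
        push("N2", nrem_ep - 2 - sws_ep)
        push("REM", rem_ep, em_rate=float(row.rem_density))
    push("W", int(round(cfg.w_tail_min * per_min)))
    return Hypnogram(stages=np.array(stages), night_id=night_id,
                     epoch_len_s=cfg.epoch_len_s,
                     em_counts=np.array(counts, dtype=int))


def generate_night_hypnograms(
    cfg: GeneratorConfig,
) -> tuple[pd.DataFrame, list[Hypnogram]]:
    """Per-night tables plus one hypnogram per night, from a single seed."""
    rng = np.random.default_rng(cfg.seed)
    per_night, _ = generate_cycle_tables(cfg, rng)
    nights = []
    for night, tbl in per_night.groupby("night"):
        nights.append(
            generate_hypnogram(tbl, cfg, rng, night_id=f"night-{night}")
        )
    return per_night, nights


def semiquantitative_transform(values, n_bins: int = 3,
                               saturation: float | None = None) -> np.ndarray:
    """Degrade a density series to a saturating equal-width bin score.

    Emulates semi-quantitative REM-density scoring (a small ordinal scale
    that tops out at high intensity): values are binned into ``n_bins``
    equal-width bins between the series minimum and ``saturation`` (default
    60% of the observed range above the minimum) and replaced by bin
    midpoints; anything above ``saturation`` lands in the top bin.  Monotone
    but non-linear — applied to REM densities it obscures the sleep-cycle
    invariant.
    """
    v = np.asarray(values, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if np.any(v <= 0):
        raise ValueError("densities must be positive")
    lo = float(v.min())
    if saturation is None:
        saturation = lo + 0.6 * (float(v.max()) - lo)
    if saturation <= lo:
        raise ValueError("saturation must exceed the series minimum")
    width = (saturation - lo) / n_bins
    k = np.clip(np.floor((v - lo) / width), 0, n_bins - 1)
    return lo + (k + 0.5) * width
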