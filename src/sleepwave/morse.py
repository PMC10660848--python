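"""Unit-depth Morse well: spectrum, classical kinematics, two-state mixing.

The sleep state is modelled as a probability wave confined by a Morse
potential ``U(x) = exp(-2x/sigma) - 2 exp(-x/sigma)`` over the regulating
parameter of state stability *x*.  The depth is fixed at ``U0 = 1`` (all
energies are dimensionless, in units of the well depth), so the whole
spectrum is controlled by the single width parameter ``sigma``:

    eps_j = -(1 - (j + 1/2) / (2 sigma))**2,   j = 0 .. jmax,
    jmax  = floor(2 sigma - 1/2).

The semiclassical period of wavepacket oscillation at level *j* is
``T_j = 2 pi / delta_eps(j)`` with gap ``delta_eps(j) = eps_j - eps_{j-1}``.
Classical-trajectory quantities (quadrature period, first-passage times)
use the mass convention ``m = 2``, the unique choice consistent with the
level density ``N = 2 sigma`` of the spectrum above; under it the exact
classical Morse period is ``2 pi sigma / sqrt(|eps|)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

__all__ = [
    "MorseWell",
    "MixingResult",
    "energy_level",
    "num_levels",
    "energy_gap",
    "period",
    "turning_points",
    "amplitude",
    "trajectory_period_quadrature",
    "first_passage_fraction",
    "two_state_mixing",
]

#: classical mass convention consistent with the level density N = 2*sigma
CLASSICAL_MASS = 2.0

_MIN_SIGMA_BOUND = 0.25  # below this the well holds no bound level


@dataclass(frozen=True)
class MorseWell:
    """Morse well of width ``sigma`` and unit depth.

    Parameters
    ----------
    sigma : float
        Dimensionless width of the well, ``sigma > 0``.  The number of
        bound levels is ``floor(2 sigma - 1/2) + 1`` (requires
        ``sigma >= 0.25`` for at least one level).
    """

    sigma: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0 and math.isfinite(self.sigma)):
            raise ValueError(f"sigma must be positive and finite, got {self.sigma}")

    @property
    def n_param(self) -> float:
        """Level-density parameter N = 2*sigma."""
        return 2.0 * self.sigma

    @property
    def j_max(self) -> int:
        """Index of the highest bound level, floor(2*sigma - 1/2)."""
        if self.sigma < _MIN_SIGMA_BOUND:
            raise ValueError(
                f"sigma={self.sigma} holds no bound level (requires sigma >= 0.25)"
            )
        return math.floor(self.n_param - 0.5)

    def potential(self, x):
        """U(x) = exp(-2x/sigma) - 2 exp(-x/sigma); minimum -1 at x = 0."""
        u = np.exp(-np.asarray(x, dtype=float) / self.sigma)
        return u * u - 2.0 * u


def _energy_at_index(sigma: float, j) -> float:
    # continuous extension of the spectrum; used for the resonance-level
    # inversion where j is generally non-integer
    return -((1.0 - (np.asarray(j, dtype=float) + 0.5) / (2.0 * sigma)) ** 2)


def energy_level(well: MorseWell, j: int) -> float:
    """Bound-level energy eps_j = -(1 - (j+1/2)/(2 sigma))**2.

    Strictly increasing in ``j`` and contained in (-1, 0).
    """
    jmax = well.j_max
    if not float(j).is_integer() or j < 0 or j > jmax:
        raise ValueError(f"level index {j} outside [0, jmax={jmax}]")
    return float(_energy_at_index(well.sigma, int(j)))


def num_levels(well: MorseWell) -> int:
    """Number of bound levels, jmax + 1."""
    return well.j_max + 1


def energy_gap(well: MorseWell, j: int) -> float:
    """Gap eps_j - eps_{j-1}; equals (2 sigma - j)/(2 sigma^2) exactly."""
    if j < 1:
        raise ValueError("energy_gap requires j >= 1 (no level below j=0)")
    return energy_level(well, j) - energy_level(well, j - 1)


def period(well: MorseWell, j: int) -> float:
    """Semiclassical oscillation period T_j = 2 pi / (eps_j - eps_{j-1})."""
    return 2.0 * math.pi / energy_gap(well, j)


def _check_bound_energy(eps: float) -> None:
    if not (-1.0 < eps < 0.0):
        raise ValueError(f"energy {eps} outside the bound range (-1, 0)")


def turning_points(well: MorseWell, eps: float) -> tuple[float, float]:
    """Classical turning points of U(x) = eps, ``x_inner < 0 < x_outer``.

    With ``s = sqrt(1 - |eps|)``: ``x_inner = -sigma ln(1+s)`` and
    ``x_outer = -sigma ln(1-s)``.
    """
    _check_bound_energy(eps)
    s = math.sqrt(1.0 - abs(eps))
    x_inner = -well.sigma * math.log1p(s)
    x_outer = -well.sigma * math.log1p(-s)
    return x_inner, x_outer


def amplitude(well: MorseWell, eps: float) -> float:
    """Oscillation amplitude L(eps): distance between the turning points.

    Closed form ``sigma ln[(1+s)/(1-s)]`` with ``s = sqrt(1-|eps|)``;
    this is the wave-intensity length scale (intensity ~ L**2).
    """
    if eps == -1.0:
        return 0.0
    x_inner, x_outer = turning_points(well, eps)
    return x_outer - x_inner


def _segment_time(well: MorseWell, eps: float, a: float, b: float) -> float:
    """Travel time from x=a to x=b (a < b) at energy eps, mass m=2.

    t = integral_a^b dx * sqrt(m / (2 (eps - U(x)))).  The integrable
    inverse-square-root singularities that occur when a or b is a turning
    point are removed by the substitution x = a + (b - a) sin^2(psi).
    """
    if b <= a:
        return 0.0
    span = b - a
    sqrt_half_m = math.sqrt(CLASSICAL_MASS / 2.0)

    def integrand(psi: float) -> float:
        sn, cs = math.sin(psi), math.cos(psi)
        x = a + span * sn * sn
        denom = eps - float(well.potential(x))
        if denom <= 0.0:
            # clipped to zero measure at the endpoints; quad never hits them
            return 0.0
        return sqrt_half_m * 2.0 * span * sn * cs / math.sqrt(denom)

    value, err = quad(integrand, 0.0, 0.5 * math.pi, limit=200,
                      epsabs=1e-11, epsrel=1e-10)
    if not math.isfinite(value) or (value > 0 and err > 1e-6 * max(value, 1.0)):
        raise RuntimeError(
            f"non-convergent trajectory quadrature on [{a}, {b}] at eps={eps}: "
            f"value={value}, abserr={err}"
        )
    return value


def trajectory_period_quadrature(well: MorseWell, eps: float) -> float:
    """Full classical oscillation period at energy eps, by quadrature.

    Independent numerical oracle for the semiclassical period: agrees with
    the closed form ``2 pi sigma / sqrt(|eps|)`` (mass m = 2) and, at the
    half-integer energy eps_{j-1/2}, with ``period(well, j)``.
    """
    _check_bound_energy(eps)
    x_inner, x_outer = turning_points(well, eps)
    return 2.0 * _segment_time(well, eps, x_inner, x_outer)


def first_passage_fraction(
    well: MorseWell, eps: float, x0: float, direction: str = "outer"
) -> float:
    """Fraction of the full period until first arrival at the inner wall.

    Starting from ``x0`` and moving toward the stated wall (``"inner"`` or
    ``"outer"``), the travel time to the inner turning point divided by the
    full period.  For sleep onset near the well minimum moving outward in a
    near-harmonic well this is ~3/4: the first oscillation is curtailed by
    about a quarter of the whole period.
    """
    _check_bound_energy(eps)
    if direction not in ("inner", "outer"):
        raise ValueError(f"direction must be 'inner' or 'outer', got {direction!r}")
    x_inner, x_outer = turning_points(well, eps)
    tol = 1e-12 * max(1.0, abs(x_outer - x_inner))
    if x0 < x_inner - tol or x0 > x_outer + tol:
        raise ValueError(
            f"x0={x0} outside the classically allowed region "
            f"[{x_inner}, {x_outer}] at eps={eps}"
        )
    x0 = min(max(x0, x_inner), x_outer)
    half = _segment_time(well, eps, x_inner, x_outer)
    if direction == "inner":
        t = _segment_time(well, eps, x_inner, x0)
    else:
        t = _segment_time(well, eps, x0, x_outer) + half
    return t / (2.0 * half)


@dataclass(frozen=True)
class MixingResult:
    """Two-state coherent mixing of a sleep and a wake stationary wave.

    ``e_a <= e_b`` are the perturbed eigen-energies, ``theta`` the mixing
    angle, ``p_s = cos^2(theta/2)`` / ``p_w = sin^2(theta/2)`` the sleep and
    wake fractions in the lower eigenstate, and ``beta = |V / delta_eps|``
    the perturbation-strength parameter (``inf`` at exact resonance).
    """

    e_a: float
    e_b: float
    theta: float
    p_s: float
    p_w: float
    beta: float


def two_state_mixing(eps_s: float, eps_w: float, v: float) -> MixingResult:
    """Closed-form avoided crossing of one sleep and one wake level.

    E_{a,b} = (eps_s + eps_w)/2 -/+ sqrt(delta^2/4 + V^2) with
    delta = eps_s - eps_w, and cos(theta) = 1/sqrt(1 + (2V/delta)^2).
    Diagonal couplings are taken as zero.  At resonance (delta -> 0 with
    V != 0) the superposition carries equal sleep/wake fractions.
    """
    delta = eps_s - eps_w
    mean = 0.5 * (eps_s + eps_w)
    root = math.hypot(0.5 * delta, v)
    e_a, e_b = mean - root, mean + root
    if delta == 0.0:
        theta = 0.5 * math.pi if v != 0.0 else 0.0
        beta = math.inf
    else:
        theta = math.acos(1.0 / math.sqrt(1.0 + (2.0 * v / delta) ** 2))
        beta = abs(v / delta)
    p_s = math.cos(0.5 * theta) ** 2
    return MixingResult(e_a=e_a, e_b=e_b, theta=theta, p_s=p_s, p_w=1.0 - p_s,
                        beta=beta)
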