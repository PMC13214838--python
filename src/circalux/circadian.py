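"""Light-driven circadian pacemaker: Process L + van der Pol limit cycle.

The pacemaker is the classic human circadian limit-cycle oscillator in its
"simpler model" form: a van der Pol oscillator in the variables
``(x, x_c)`` with intrinsic period ``tau_c``, forced by a photic drive
``B`` produced by a photoreceptor activation/saturation stage (Process L).

Process L converts illuminance ``I`` into an activation rate

    alpha(I) = alpha_0 * (I / I_0)**p        [1/min]

and tracks the fraction ``n`` of activated (light-adapted) photoreceptor
elements,

    dn/dt = 60 * (alpha(I) * (1 - n) - beta * n)   [1/h],

so that the drive onto the clock,

    B = G * alpha(I) * (1 - n) * (1 - kappa*x) * (1 - kappa*x_c),

is strongest at light onset and adapts as ``n`` saturates.  The
``(1 - kappa*x)(1 - kappa*x_c)`` factor makes identical light produce
phase-dependent effects, shaping the phase response curve; ``kappa`` is
the PRC-shape parameter swept in this study.  The oscillator itself is

    dx/dt   = (pi/12) * (x_c + B)
    dx_c/dt = (pi/12) * ( mu_vdp*(x_c - (4/3)x_c^3)
                          - x*((24/(0.99669*tau_c))^2 + k_light*B) ),

whose dark free-run period equals ``tau_c`` (the 0.99669 factor corrects
for the period lengthening introduced by the stiffness term).

The minimum of ``x`` marks core body temperature minimum (CBTmin); dim
light melatonin onset (DLMO) is taken 7 h before CBTmin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np

__all__ = [
    "CircadianParams",
    "CircadianState",
    "DLMO_TO_CBTMIN_H",
    "photic_activation",
    "process_l_derivative",
    "light_drive",
    "oscillator_derivatives",
    "cbt_min_times",
    "dlmo_times",
    "average_amplitude",
]

#: CBTmin is assumed to occur this many hours after DLMO.
DLMO_TO_CBTMIN_H = 7.0


@dataclass(frozen=True)
class CircadianParams:
    """Circadian model parameters.

    The three phenotype parameters swept in this study are ``p`` (photic
    sensitivity exponent, [0.5, 0.7]), ``kappa`` (PRC shape, [0.4, 0.7])
    and ``tau_c`` (intrinsic period in hours, [23.8, 24.4]).  The
    remaining constants are the reference limit-cycle model's fixed
    values:

    ==================  =========  ==========================================
    constant            value      meaning
    ==================  =========  ==========================================
    ``alpha_0``         0.05       photoreceptor activation scale, 1/min
    ``beta``            0.0075     photoreceptor recovery rate, 1/min
    ``i_0``             9500.0     half-scale illuminance, lux
    ``big_g``           33.75      photic drive gain, dimensionless
    ``mu_vdp``          0.23       van der Pol stiffness
    ``k_light``         0.55       light effect on angular frequency
    ``period_corr``     0.99669    stiffness period-correction factor
    ==================  =========  ==========================================
    """

    p: float = 0.5
    kappa: float = 0.4
    tau_c: float = 24.2
    alpha_0: float = 0.05
    beta: float = 0.0075
    i_0: float = 9500.0
    big_g: float = 33.75
    mu_vdp: float = 0.23
    k_light: float = 0.55
    period_corr: float = 0.99669

    def __post_init__(self) -> None:
        if self.tau_c <= 0:
            raise ValueError("tau_c must be positive")
        for name in ("alpha_0", "beta", "i_0", "big_g", "mu_vdp", "k_light", "period_corr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def with_(self, **kw) -> "CircadianParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    def export_constants(self, path: str | Path) -> None:
        """Write the full constants table as JSON."""
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


@dataclass
class CircadianState:
    """Oscillator variables ``(x, x_c)`` and photoreceptor saturation
    fraction ``n`` (dimensionless, in [0, 1])."""

    x: float = -1.0
    x_c: float = 0.0
    n: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.n <= 1.0:
            raise ValueError("n must lie in [0, 1]")


def photic_activation(I: float, params: CircadianParams) -> float:
    """Photoreceptor activation rate alpha(I) in 1/min.

    Zero in darkness, equal to ``alpha_0`` at ``I = i_0``, and strictly
    increasing with curvature set by the sensitivity exponent ``p``.
    """
    if I < 0:
        raise ValueError("illuminance must be non-negative")
    if I == 0:
        return 0.0
    return params.alpha_0 * (I / params.i_0) ** params.p


def process_l_derivative(state: CircadianState, I: float, params: CircadianParams) -> float:
    """dn/dt in 1/h: activation of the unsaturated fraction in light,
    first-order recovery in darkness."""
    alpha = photic_activation(I, params)
    return 60.0 * (alpha * (1.0 - state.n) - params.beta * state.n)


def process_l_fixed_point(I: float, params: CircadianParams) -> float:
    """Steady-state saturation n* = alpha / (alpha + beta) in constant light."""
    alpha = photic_activation(I, params)
    return alpha / (alpha + params.beta) if alpha > 0 else 0.0


def light_drive(state: CircadianState, I: float, params: CircadianParams) -> float:
    """Photic drive B onto the oscillator.

    Proportional to the activation rate and the available (unsaturated)
    photoreceptor fraction, modulated by oscillator state through
    ``kappa`` so the same light produces phase-dependent shifts.
    """
    alpha = photic_activation(I, params)
    return (
        params.big_g
        * alpha
        * (1.0 - state.n)
        * (1.0 - params.kappa * state.x)
        * (1.0 - params.kappa * state.x_c)
    )


def oscillator_derivatives(state: CircadianState, B: float, params: CircadianParams) -> tuple[float, float]:
    """(dx/dt, dx_c/dt) in 1/h for the driven van der Pol oscillator."""
    omega_sq = (24.0 / (params.period_corr * params.tau_c)) ** 2
    dx = (np.pi / 12.0) * (state.x_c + B)
    dxc = (np.pi / 12.0) * (
        params.mu_vdp * (state.x_c - (4.0 / 3.0) * state.x_c**3)
        - state.x * (omega_sq + params.k_light * B)
    )
    return dx, dxc


# ---------------------------------------------------------------------------
# phase / amplitude marker extraction
# ---------------------------------------------------------------------------

def cbt_min_times(t: np.ndarray, x: np.ndarray, min_separation_h: float = 16.0) -> np.ndarray:
    """Times of the cyclic minima of ``x`` (the CBTmin marker series).

    Local minima on the sampling grid are refined by three-point quadratic
    interpolation; ties break to the earliest time.  Successive minima
    closer than ``min_separation_h`` are collapsed to the deeper one, so
    one marker is returned per circadian cycle.  An empty array is
    returned if the trajectory is too short to contain a cycle minimum.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.shape != x.shape or t.ndim != 1:
        raise ValueError("t and x must be matching 1-D arrays")
    if len(t) < 3:
        return np.empty(0)
    interior = np.flatnonzero((x[1:-1] < x[:-2]) & (x[1:-1] <= x[2:])) + 1
    times: list[float] = []
    depths: list[float] = []
    for i in interior:
        t0, t1, t2 = t[i - 1], t[i], t[i + 1]
        y0, y1, y2 = x[i - 1], x[i], x[i + 1]
        # quadratic through three (possibly unevenly spaced) points
        denom = (t0 - t1) * (t0 - t2) * (t1 - t2)
        a = (t2 * (y1 - y0) + t1 * (y0 - y2) + t0 * (y2 - y1)) / denom
        b = (t2**2 * (y0 - y1) + t1**2 * (y2 - y0) + t0**2 * (y1 - y2)) / denom
        if a > 0:
            tm = min(max(-b / (2.0 * a), t0), t2)
        else:
            tm = t1
        ym = y1  # grid value ranks duplicate minima within a cycle
        if times and tm - times[-1] < min_separation_h:
            if ym < depths[-1]:
                times[-1], depths[-1] = tm, ym
        else:
            times.append(tm)
            depths.append(ym)
    return np.asarray(times)


def dlmo_times(cbt_min: np.ndarray) -> np.ndarray:
    """Dim light melatonin onset series: DLMO = CBTmin - 7 h."""
    return np.asarray(cbt_min, dtype=float) - DLMO_TO_CBTMIN_H


def average_amplitude(t: np.ndarray, x: np.ndarray, x_c: np.ndarray, window: tuple[float, float] | None = None) -> float:
    """Time-average of the instantaneous amplitude r(t) = sqrt(x^2+x_c^2).

    Averaged by trapezoid quadrature over ``window`` (defaults to the last
    24 h of the trajectory).
    """
    t = np.asarray(t, dtype=float)
    r = np.hypot(np.asarray(x, dtype=float), np.asarray(x_c, dtype=float))
    if window is None:
        window = (t[-1] - 24.0, t[-1])
    lo, hi = window
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9 or hi <= lo:
        raise ValueError("window must lie inside the trajectory")
    mask = (t >= lo - 1e-12) & (t <= hi + 1e-12)
    tt, rr = t[mask], r[mask]
    return float(np.trapezoid(rr, tt) / (tt[-1] - tt[0]))
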