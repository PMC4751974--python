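"""Two-state thermal denaturation of dimeric coiled coils.

Model
-----
A dimeric coiled coil unfolds as ``D <=> 2 M`` with no populated
intermediate.  Writing Pt for the total peptide concentration (monomer
units, mol/L) and f for the fraction of chains in the folded dimer, the
unfolding equilibrium constant is

    K_unf(T) = [M]^2 / [D] = 2 * Pt * (1 - f)^2 / f .

With a temperature-independent heat capacity change of zero (the default
here), the Gibbs-Helmholtz expression for the unfolding free energy pinned
to the midpoint Tm — the temperature where f = 1/2, at which
K_unf = Pt and hence dG_unf(Tm) = -R * Tm * ln(Pt) — reduces to

    dG_unf(T) = dH_unf * (1 - T / Tm) - R * T * ln(Pt)      [T in kelvin].

Solving the quadratic in f at each temperature gives the folded-fraction
curve; the observable (mean residue ellipticity at 222 nm) interpolates
between linear folded and unfolded baselines:

    y(T) = f * (bf + mf * T) + (1 - f) * (bu + mu * T).

Because the equilibrium is bimolecular, the apparent midpoint rises with
concentration: the same dH/dS evaluated at doubled Pt crosses f = 1/2 at a
higher temperature.

Fitting uses least squares over (Tm, dH, bf, mf, bu, mu) with fixed,
documented start values: Tm at the steepest signal change, a folding
enthalpy of -50 kcal/mol, and baselines from straight-line fits to the
curve's flanks.  Non-convergence (including degenerate flat curves, whose
midpoint is unidentifiable) is flagged on the result, never silent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

__all__ = [
    "R_KCAL",
    "Baselines",
    "MeltCurve",
    "MeltFitResult",
    "ExchangeResult",
    "folded_fraction",
    "simulate_melt",
    "fit_two_state",
    "exchange_excess",
]

#: Gas constant, kcal / (mol K).
R_KCAL = 1.987204e-3

_T0 = 273.15


@dataclass(frozen=True)
class Baselines:
    """Linear folded/unfolded baselines: intercept + slope * T(degC)."""

    folded_intercept: float = -33000.0
    folded_slope: float = 60.0
    unfolded_intercept: float = -3000.0
    unfolded_slope: float = -10.0


@dataclass(frozen=True)
class MeltCurve:
    """A thermal melt: temperature grid (deg C), CD signal at 222 nm, and
    total peptide concentration Pt (mol/L)."""

    temperature: np.ndarray
    signal: np.ndarray
    pt: float

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "signal", y)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("temperature and signal must be 1-D arrays of equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("signal must be finite")
        if not 0 < self.pt:
            raise ValueError("total peptide concentration must be positive")


@dataclass(frozen=True)
class MeltFitResult:
    """Fitted midpoint, folding enthalpy, baselines and diagnostics."""

    tm: float
    enthalpy: float
    baselines: Baselines
    rss: float
    converged: bool
    message: str = ""


def folded_fraction(
    temperature_c: np.ndarray | float,
    tm_c: float,
    enthalpy: float,
    pt: float,
    pt_eval: float | None = None,
) -> np.ndarray:
    """Fraction folded of the two-state dimer at the given temperatures.

    ``tm_c`` is the midpoint at the reference concentration ``pt``;
    ``enthalpy`` is the folding enthalpy (kcal/mol, negative).  Passing
    ``pt_eval`` evaluates the same thermodynamics at another concentration
    (the apparent midpoint shifts up with concentration for a dimer).
    """
    if enthalpy >= 0:
        raise ValueError("folding enthalpy must be negative (non-physical otherwise)")
    dh_unf = -float(enthalpy)
    t = np.asarray(temperature_c, dtype=float) + _T0
    tm = tm_c + _T0
    p_eval = pt if pt_eval is None else pt_eval
    # K_unf(T) = Pt_ref * exp(-dH_unf (1 - T/Tm) / (R T))
    k_unf = pt * np.exp(-dh_unf * (1.0 - t / tm) / (R_KCAL * t))
    # 2 Pt f^2 - (4 Pt + K) f + 2 Pt = 0, physical root in [0, 1]
    b = 4.0 * p_eval + k_unf
    f = (b - np.sqrt(b * b - 16.0 * p_eval * p_eval)) / (4.0 * p_eval)
    return f


def simulate_melt(
    tm: float,
    enthalpy: float,
    pt: float = 150e-6,
    baselines: Baselines = Baselines(),
    noise_sd: float = 0.0,
    seed: int = 0,
    temperatures: np.ndarray | None = None,
) -> MeltCurve:
    """Synthetic melt curve with linear baselines and Gaussian noise.

    Defaults emulate a CD melt stepped in 1 degC increments from -8 to
    95 degC at 150 uM total peptide.  ``noise_sd`` is in signal units; the
    seed fixes the noise stream, so identical calls give identical curves.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = (
        np.arange(-8.0, 96.0, 1.0)
        if temperatures is None
        else np.asarray(temperatures, dtype=float)
    )
    if not (t.min() <= tm <= t.max()):
        raise ValueError("tm must lie within the temperature grid")
    f = folded_fraction(t, tm, enthalpy, pt)
    y = f * (baselines.folded_intercept + baselines.folded_slope * t) + (1 - f) * (
        baselines.unfolded_intercept + baselines.unfolded_slope * t
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return MeltCurve(temperature=t, signal=y, pt=pt)


def _model(t, tm, dh, bf, mf, bu, mu, pt):
    f = folded_fraction(t, tm, dh, pt)
    return f * (bf + mf * t) + (1 - f) * (bu + mu * t)


def _flank_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(t, y, 1)
    return intercept, slope


def fit_two_state(curve: MeltCurve, enthalpy_start: float = -50.0) -> MeltFitResult:
    """Least-squares fit of the two-state dimer model to a melt curve.

    Requires >= 20 points so both baselines are sampled.  Start values are
    fixed for reproducibility: the midpoint guess is the temperature of
    steepest signal change (5-point smoothed gradient), the enthalpy guess
    -50 kcal/mol, and baseline guesses come from the outer 15% of points.
    """
    t, y = curve.temperature, curve.signal
    if len(t) < 20:
        raise ValueError("need at least 20 points spanning both baselines")
    grad = np.convolve(np.gradient(y, t), np.ones(5) / 5, mode="same")
    tm0 = float(t[np.argmax(np.abs(grad))])
    tm0 = float(np.clip(tm0, t[2], t[-3]))
    k = max(3, len(t) * 15 // 100)
    bf0, mf0 = _flank_line(t[:k], y[:k])
    bu0, mu0 = _flank_line(t[-k:], y[-k:])
    p0 = (tm0, enthalpy_start, bf0, mf0, bu0, mu0)
    bounds = (
        [t[0], -np.inf, -np.inf, -np.inf, -np.inf, -np.inf],
        [t[-1], -1e-6, np.inf, np.inf, np.inf, np.inf],
    )

    def f(tt, tm, dh, bf, mf, bu, mu):
        return _model(tt, tm, dh, bf, mf, bu, mu, curve.pt)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, pcov = curve_fit(f, t, y, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        return MeltFitResult(
            tm=tm0,
            enthalpy=enthalpy_start,
            baselines=Baselines(bf0, mf0, bu0, mu0),
            rss=float(np.sum((y - f(t, *p0)) ** 2)),
            converged=False,
            message=f"fit did not converge: {exc}",
        )
    tm, dh, bf, mf, bu, mu = popt
    rss = float(np.sum((y - f(t, *popt)) ** 2))
    tm_var = pcov[0, 0]
    # the midpoint is identifiable only if the folded/unfolded baseline gap
    # at Tm clears the residual noise: a flat curve fits perfectly with zero
    # amplitude and an arbitrary Tm
    amplitude = abs((bf + mf * tm) - (bu + mu * tm))
    rms = float(np.sqrt(rss / len(t)))
    converged = bool(
        np.isfinite(tm_var)
        and np.sqrt(max(tm_var, 0.0)) < (t[-1] - t[0])
        and amplitude > 5.0 * rms
        and amplitude > 0.0
    )
    message = "" if converged else "midpoint unidentifiable (flat or degenerate curve)"
    return MeltFitResult(
        tm=float(tm),
        enthalpy=float(dh),
        baselines=Baselines(float(bf), float(mf), float(bu), float(mu)),
        rss=rss,
        converged=converged,
        message=message,
    )


@dataclass(frozen=True)
class ExchangeResult:
    """Pointwise mixture-minus-average spectrum and the 222 nm summary.

    ``excess_helicity_222`` = average(222) − mixture(222): positive when the
    mixture is more negative (more helical) than the average of its
    components, the signature of partner exchange.
    """

    wavelength: np.ndarray
    difference: np.ndarray
    excess_helicity_222: float


def exchange_excess(
    wavelength: np.ndarray,
    spectrumA: np.ndarray,
    spectrumB: np.ndarray,
    spectrum_mixed: np.ndarray,
) -> ExchangeResult:
    """Dimer-exchange comparison of a mixture against its component average.

    All spectra must share the wavelength grid (nm); the grid must cover
    222 nm for the scalar summary.
    """
    w = np.asarray(wavelength, dtype=float)
    arrs = [np.asarray(s, dtype=float) for s in (spectrumA, spectrumB, spectrum_mixed)]
    for s in arrs:
        if s.shape != w.shape:
            raise ValueError("spectra and wavelength grid have mismatched shapes")
    a, b, mixed = arrs
    avg = (a + b) / 2.0
    diff = mixed - avg
    order = np.argsort(w)
    if not (w.min() <= 222.0 <= w.max()):
        raise ValueError("wavelength grid does not cover 222 nm")
    excess = -float(np.interp(222.0, w[order], diff[order]))
    return ExchangeResult(wavelength=w, difference=diff, excess_helicity_222=excess)
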