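"""Electroanalytical computations for the e-MIP sensor workflow.

Covers the four desk computations of the sensor characterization:

* square-wave voltammetry (SWV) peak extraction with a linear baseline
  through the flanking minima;
* calibration lines with ICH-style detection/quantification limits
  (LOD = 3.3·s/slope, LOQ = 10·s/slope, with s the intercept standard
  error by default or a supplied blank standard deviation);
* electrochemical impedance spectra and the Randles-type equivalent
  circuit R_s + (R_ct ∥ CPE) fitted by modulus-weighted complex
  nonlinear least squares;
* polymer film thickness h = q·M/(ρ·A·n·F) from the integrated
  electropolymerization charge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .constants import FARADAY


class ElectroError(ValueError):
    pass


class PeakNotDetected(ElectroError):
    """No interior peak in the requested potential window."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Voltammogram:
    """One potential sweep: potentials in V (strictly monotone), currents
    in A; ``technique`` is ``"SWV"`` or ``"CV"`` (CV requires a scan
    rate, V s⁻¹)."""

    potential: np.ndarray
    current: np.ndarray
    technique: str = "SWV"
    scan_rate: float | None = None

    def __post_init__(self) -> None:
        self.potential = np.asarray(self.potential, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.potential.shape != self.current.shape:
            raise ElectroError("potential and current must have equal length")
        if self.potential.size < 10:
            raise ElectroError("a voltammogram needs at least 10 points")
        dv = np.diff(self.potential)
        if not (np.all(dv > 0) or np.all(dv < 0)):
            raise ElectroError("potential must be strictly monotone")
        if self.technique not in ("SWV", "CV"):
            raise ElectroError("technique must be 'SWV' or 'CV'")


@dataclass
class CalibrationResult:
    slope: float                  # A per mol L⁻¹
    intercept: float              # A
    slope_se: float
    intercept_se: float
    r_squared: float
    n: int
    lod: float                    # mol L⁻¹
    loq: float                    # mol L⁻¹

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ElectroError("r_squared must lie in [0, 1]")
        if self.lod >= self.loq:
            raise ElectroError("LOD must be below LOQ")


@dataclass
class EISSpectrum:
    """Frequency-resolved complex impedance, frequencies descending (Hz)."""

    frequency: np.ndarray
    z_real: np.ndarray
    z_imag: np.ndarray

    def __post_init__(self) -> None:
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.z_real = np.asarray(self.z_real, dtype=float)
        self.z_imag = np.asarray(self.z_imag, dtype=float)
        if not (self.frequency.shape == self.z_real.shape
                == self.z_imag.shape):
            raise ElectroError("spectrum arrays must have equal length")
        if self.frequency.size < 5:
            raise ElectroError("an EIS spectrum needs at least 5 points")
        if np.any(self.frequency <= 0):
            raise ElectroError("frequencies must be positive")
        if not np.all(np.diff(self.frequency) < 0):
            raise ElectroError("frequencies must be strictly descending")

    @property
    def z(self) -> np.ndarray:
        return self.z_real + 1j * self.z_imag


@dataclass
class RandlesModel:
    """R_s + (R_ct ∥ CPE) equivalent circuit parameters."""

    r_s: float                    # Ω
    r_ct: float                   # Ω
    cpe_q: float                  # S·sⁿ
    cpe_n: float                  # (0, 1]

    def __post_init__(self) -> None:
        if self.r_s <= 0 or self.r_ct <= 0:
            raise ElectroError("resistances must be > 0")
        if self.cpe_q <= 0:
            raise ElectroError("cpe_q must be > 0")
        if not 0.0 < self.cpe_n <= 1.0:
            raise ElectroError("cpe_n must lie in (0, 1]")


@dataclass
class RandlesFit:
    model: RandlesModel
    stderr: dict[str, float]
    residual_norm: float
    pinned: list[str]
    converged: bool


@dataclass
class FilmThicknessInput:
    """Inputs of the film-thickness relation h = q·M/(ρ·A·n·F)."""

    q: float                      # C
    M: float                      # g mol⁻¹
    rho: float                    # g cm⁻³
    A: float                      # cm²
    n_electrons: int
    F: float = FARADAY            # C mol⁻¹

    def __post_init__(self) -> None:
        for name in ("q", "M", "rho", "A", "n_electrons", "F"):
            if getattr(self, name) <= 0:
                raise ElectroError(f"{name} must be strictly positive")


# ---------------------------------------------------------------------------
# SWV peak detection
# ---------------------------------------------------------------------------

def detect_swv_peak(v: Voltammogram, window: tuple[float, float]
                    ) -> tuple[float, float]:
    """Find (Ep, ip) inside a potential window.

    A linear baseline is drawn through the current minima flanking the
    raw in-window maximum; ip is the maximum baseline-corrected current
    and Ep the corresponding potential refined by a 3-point parabolic
    interpolation.  Raises :class:`PeakNotDetected` when no interior
    positive peak exists (flat traces, monotone ramps).
    """
    lo, hi = sorted(window)
    e = v.potential
    if lo < e.min() - 1e-12 or hi > e.max() + 1e-12:
        raise ElectroError("window must lie inside the sweep")
    order = np.argsort(e)
    e, i = e[order], v.current[order]
    mask = (e >= lo) & (e <= hi)
    if mask.sum() < 3:
        raise ElectroError("window contains fewer than 3 samples")
    ew, iw = e[mask], i[mask]
    k = int(np.argmax(iw))
    if k == 0 or k == len(iw) - 1:
        raise PeakNotDetected("maximum sits on the window edge")
    left = int(np.argmin(iw[: k + 1]))
    right = k + int(np.argmin(iw[k:]))
    if right == left:
        raise PeakNotDetected("no flanking minima around the maximum")
    slope = (iw[right] - iw[left]) / (ew[right] - ew[left])
    baseline = iw[left] + slope * (ew - ew[left])
    corrected = iw - baseline
    kp = int(np.argmax(corrected))
    if kp == 0 or kp == len(iw) - 1 or corrected[kp] <= 0:
        raise PeakNotDetected("no interior baseline-corrected maximum")
    ip = float(corrected[kp])
    y0, y1, y2 = corrected[kp - 1: kp + 2]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        ep = float(ew[kp])
    else:
        offset = 0.5 * (y0 - y2) / denom
        step = 0.5 * (ew[kp + 1] - ew[kp - 1])
        ep = float(ew[kp] + offset * step)
    return ep, ip


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def fit_calibration(concentrations: Sequence[float],
                    peak_currents: Sequence[float],
                    lod_rule: str = "intercept_se",
                    s_blank: float | None = None) -> CalibrationResult:
    """Ordinary least squares calibration line with LOD/LOQ.

    ``lod_rule`` selects the noise estimate s in LOD = 3.3·s/|slope|:
    ``"intercept_se"`` (default) uses the fitted intercept standard
    error; ``"blank_sd"`` uses the supplied ``s_blank``.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(peak_currents, dtype=float)
    if x.shape != y.shape:
        raise ElectroError("concentration and current arrays differ in length")
    if np.unique(x).size < 3:
        raise ElectroError("need at least 3 distinct concentrations")
    res = stats.linregress(x, y)
    if res.slope == 0:
        raise ElectroError("zero calibration slope")
    if lod_rule == "intercept_se":
        s = res.intercept_stderr
    elif lod_rule == "blank_sd":
        if s_blank is None or s_blank < 0:
            raise ElectroError("blank_sd rule requires a nonnegative s_blank")
        s = s_blank
    else:
        raise ElectroError(f"unknown lod_rule {lod_rule!r}")
    # guard the degenerate noiseless case so LOD < LOQ stays well defined
    s = max(float(s), np.finfo(float).tiny)
    lod = 3.3 * s / abs(res.slope)
    loq = 10.0 * s / abs(res.slope)
    r2 = min(float(res.rvalue) ** 2, 1.0)
    return CalibrationResult(
        slope=float(res.slope), intercept=float(res.intercept),
        slope_se=float(res.stderr), intercept_se=float(res.intercept_stderr),
        r_squared=r2, n=x.size, lod=lod, loq=loq)


def monomer_template_ratio(monomer_conc: float, template_conc: float
                           ) -> tuple[int, int]:
    """Reduced integer monomer:template ratio (same concentration units)."""
    if monomer_conc <= 0 or template_conc <= 0:
        raise ElectroError("concentrations must be positive")
    frac = Fraction(monomer_conc / template_conc).limit_denominator(1000)
    return frac.numerator, frac.denominator


# ---------------------------------------------------------------------------
# EIS: Randles circuit
# ---------------------------------------------------------------------------

def randles_impedance(model: RandlesModel,
                      frequencies: np.ndarray) -> np.ndarray:
    """Complex impedance Z(ω) = R_s + R_ct / (1 + R_ct·Q·(jω)ⁿ)."""
    omega = 2.0 * np.pi * np.asarray(frequencies, dtype=float)
    jw_n = omega ** model.cpe_n * np.exp(1j * model.cpe_n * np.pi / 2.0)
    return model.r_s + model.r_ct / (1.0 + model.r_ct * model.cpe_q * jw_n)


def simulate_randles(model: RandlesModel,
                     frequencies: Sequence[float]) -> EISSpectrum:
    """Noise-free spectrum of a Randles-type circuit on given frequencies."""
    f = np.sort(np.asarray(frequencies, dtype=float))[::-1]
    z = randles_impedance(model, f)
    return EISSpectrum(frequency=f, z_real=z.real, z_imag=z.imag)


_PARAM_NAMES = ("r_s", "r_ct", "cpe_q", "cpe_n")
_LOWER = np.array([1e-6, 1e-6, 1e-15, 0.05])
_UPPER = np.array([1e9, 1e12, 1e3, 1.0])


def _initial_guess(spectrum: EISSpectrum) -> np.ndarray:
    r_s = max(float(spectrum.z_real.min()), 1e-3)
    r_ct = max(float(spectrum.z_real.max() - spectrum.z_real.min()), 1e-3)
    k = int(np.argmax(-spectrum.z_imag))
    omega_apex = 2.0 * np.pi * spectrum.frequency[k]
    q = 1.0 / max(r_ct * omega_apex, 1e-12)
    return np.array([r_s, r_ct, q, 0.9])


def fit_randles(spectrum: EISSpectrum,
                initial: RandlesModel | None = None) -> RandlesFit:
    """Complex nonlinear least squares fit of the Randles-type circuit.

    Minimizes Σ|Z_obs − Z_model|²/|Z_obs|² (modulus weighting, the
    standard choice for spectra spanning decades of |Z|).  Requires at
    least 8 points covering ≥ 3 frequency decades.  Parameters within
    1e-6 relative of a bound are flagged in ``pinned``.
    """
    if spectrum.frequency.size < 8:
        raise ElectroError("EIS fit needs at least 8 frequency points")
    decades = math.log10(spectrum.frequency.max()
                         / spectrum.frequency.min())
    if decades < 3.0:
        raise ElectroError("EIS fit needs a span of at least 3 decades")
    z_obs = spectrum.z
    w = 1.0 / np.abs(z_obs)
    if initial is not None:
        x0 = np.array([initial.r_s, initial.r_ct, initial.cpe_q,
                       initial.cpe_n])
    else:
        x0 = _initial_guess(spectrum)
    x0 = np.clip(x0, _LOWER * 1.01, _UPPER * 0.99)

    def residuals(x: np.ndarray) -> np.ndarray:
        model = RandlesModel(*x)
        z = randles_impedance(model, spectrum.frequency)
        diff = (z - z_obs) * w
        return np.concatenate([diff.real, diff.imag])

    result = optimize.least_squares(residuals, x0, bounds=(_LOWER, _UPPER),
                                    xtol=1e-14, ftol=1e-14, gtol=1e-14)
    x = result.x
    dof = max(2 * spectrum.frequency.size - 4, 1)
    s2 = 2.0 * result.cost / dof
    jtj = result.jac.T @ result.jac
    try:
        cov = np.linalg.inv(jtj) * s2
        stderr = {name: float(math.sqrt(max(cov[i, i], 0.0)))
                  for i, name in enumerate(_PARAM_NAMES)}
    except np.linalg.LinAlgError:
        stderr = {name: math.nan for name in _PARAM_NAMES}
    pinned = [name for i, name in enumerate(_PARAM_NAMES)
              if x[i] <= _LOWER[i] * (1 + 1e-6)
              or x[i] >= _UPPER[i] * (1 - 1e-6)]
    return RandlesFit(
        model=RandlesModel(*x),
        stderr=stderr,
        residual_norm=float(math.sqrt(2.0 * result.cost)),
        pinned=pinned,
        converged=bool(result.success))


# ---------------------------------------------------------------------------
# film thickness and polymerization charge
# ---------------------------------------------------------------------------

def film_thickness(inp: FilmThicknessInput) -> float:
    """Polymer film thickness in nm from h = q·M/(ρ·A·n·F).

    With q in C, M in g mol⁻¹, ρ in g cm⁻³, A in cm² and F in C mol⁻¹
    the bare quotient is in cm; the return value converts to nm.
    """
    h_cm = inp.q * inp.M / (inp.rho * inp.A * inp.n_electrons * inp.F)
    return h_cm * 1e7


def charge_for_thickness(h_nm: float, M: float, rho: float, A: float,
                         n_electrons: int, F: float = FARADAY) -> float:
    """Inverse of :func:`film_thickness`: the charge giving thickness h."""
    if h_nm <= 0:
        raise ElectroError("thickness must be positive")
    return h_nm * 1e-7 * rho * A * n_electrons * F / M


def integrate_polymerization_charge(cycles: Voltammogram |
                                    Sequence[Voltammogram],
                                    window: tuple[float, float],
                                    baseline: str = "endpoints") -> float:
    """Charge from the anodic polymerization peaks, q = ∫ i dE / ν.

    Each supplied CV cycle is integrated by the trapezoidal rule over the
    potential window after subtracting a linear baseline through the
    in-window endpoint currents (``baseline="none"`` disables the
    correction); the per-cycle charges are summed.
    """
    if isinstance(cycles, Voltammogram):
        cycles = [cycles]
    if baseline not in ("endpoints", "none"):
        raise ElectroError("baseline must be 'endpoints' or 'none'")
    lo, hi = sorted(window)
    q_total = 0.0
    for cv in cycles:
        if cv.scan_rate is None or cv.scan_rate == 0:
            raise ElectroError("charge integration requires a nonzero "
                               "scan_rate")
        order = np.argsort(cv.potential)
        e, i = cv.potential[order], cv.current[order]
        mask = (e >= lo) & (e <= hi)
        if mask.sum() < 2:
            raise ElectroError("window contains fewer than 2 samples")
        ew, iw = e[mask], i[mask]
        if baseline == "endpoints" and ew[-1] > ew[0]:
            slope = (iw[-1] - iw[0]) / (ew[-1] - ew[0])
            iw = iw - (iw[0] + slope * (ew - ew[0]))
        q_total += float(np.trapezoid(iw, ew)) / abs(cv.scan_rate)
    return q_total
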