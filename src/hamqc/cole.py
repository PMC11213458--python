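"""Cole relaxation model for tissue impedance spectra and the Py statistic.

Muscle tissue measured over the radio-frequency band shows a single broad
relaxation (the beta-dispersion) driven by cell-membrane capacitance.  The
empirical Cole model describes it with four parameters::

    Z(f) = Rinf + (R0 - Rinf) / (1 + (j * 2*pi*f * tau)**alpha)

where ``R0`` and ``Rinf`` are the low- and high-frequency resistance limits
(Ohm), ``tau`` the characteristic time constant (s) and ``alpha`` in (0, 1]
a shape parameter (alpha = 1 is the ideal Debye single-relaxation limit).
The normalized impedance drop across the dispersion,

    Py = (R0 - Rinf) / R0 * 100,

is high (roughly 85-95) in intact fresh meat and collapses when cell
membranes are damaged, which makes it a quality statistic for structural
meat defects.

This module evaluates the model, fits it to measured spectra by bounded
complex nonlinear least squares with proportional weighting, and aggregates
replicate readings into a per-sample Py.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    DegenerateSpectrumError,
    InputError,
    NonConvergenceError,
    ParameterDomainError,
)

MUSCLES = ("AD", "SM")

#: Measurement grid used throughout: 40 log-spaced points, 10 Hz to 1 MHz.
DEFAULT_GRID_POINTS = 40
DEFAULT_GRID_FMIN = 10.0
DEFAULT_GRID_FMAX = 1.0e6

ALPHA_MIN = 0.05  # below this the dispersion is numerically flat
ALPHA_MAX = 1.0  # Debye limit, inclusive


def default_frequency_grid(
    n_points: int = DEFAULT_GRID_POINTS,
    f_min: float = DEFAULT_GRID_FMIN,
    f_max: float = DEFAULT_GRID_FMAX,
) -> np.ndarray:
    """Log-spaced frequency grid in Hz (defaults to the 40-point 10 Hz-1 MHz band)."""
    return np.logspace(np.log10(f_min), np.log10(f_max), n_points)


@dataclass(frozen=True)
class ColeParameters:
    """Cole model parameters.

    Attributes
    ----------
    r0 : float
        Zero-frequency resistance limit, Ohm.  Must exceed ``rinf``.
    rinf : float
        Infinite-frequency resistance limit, Ohm, >= 0.
    tau : float
        Characteristic time constant, seconds, > 0.
    alpha : float
        Dispersion shape parameter in (0, 1].
    """

    r0: float
    rinf: float
    tau: float
    alpha: float

    def __post_init__(self):
        if not (self.rinf >= 0.0):
            raise ParameterDomainError(f"rinf must be >= 0, got {self.rinf}")
        if not (self.r0 > self.rinf):
            raise ParameterDomainError(
                f"r0 must exceed rinf, got r0={self.r0}, rinf={self.rinf}"
            )
        if not (self.tau > 0.0):
            raise ParameterDomainError(f"tau must be > 0, got {self.tau}")
        if not (0.0 < self.alpha <= 1.0):
            raise ParameterDomainError(f"alpha must be in (0, 1], got {self.alpha}")

    @property
    def py(self) -> float:
        return compute_py(self)

    @property
    def fc(self) -> float:
        return characteristic_frequency(self)


@dataclass
class ImpedanceSpectrum:
    """One impedance reading: a frequency grid and complex impedances.

    ``muscle`` is one of ``{"AD", "SM"}`` (adductor / semimembranosus) and
    ``replicate`` numbers repeated readings at the same site (>= 1).
    """

    sample_id: str
    muscle: str
    replicate: int
    frequencies: np.ndarray
    impedance: np.ndarray

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.impedance = np.asarray(self.impedance, dtype=complex)
        if self.muscle not in MUSCLES:
            raise InputError(f"muscle must be one of {MUSCLES}, got {self.muscle!r}")
        if int(self.replicate) < 1:
            raise InputError(f"replicate must be >= 1, got {self.replicate}")
        if self.frequencies.ndim != 1 or self.impedance.ndim != 1:
            raise InputError("frequencies and impedance must be 1-D")
        if len(self.frequencies) != len(self.impedance):
            raise InputError(
                f"length mismatch: {len(self.frequencies)} frequencies vs "
                f"{len(self.impedance)} impedance values"
            )
        if len(self.frequencies) < 5:
            raise InputError(
                f"need at least 5 points to fit 4 parameters, got {len(self.frequencies)}"
            )
        if np.any(self.frequencies <= 0):
            raise InputError("frequencies must all be > 0")
        if np.any(np.diff(self.frequencies) <= 0):
            raise InputError("frequencies must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frequencies)


@dataclass
class ColeFitResult:
    """Result of fitting one spectrum.

    ``residual_norm`` is the weighted sum of squared complex residuals
    (dimensionless under proportional weighting); ``py`` is recomputable
    from ``params``.
    """

    params: ColeParameters
    residual_norm: float
    converged: bool
    n_points: int
    py: float = field(init=False)

    def __post_init__(self):
        self.py = compute_py(self.params)

    def to_dict(self) -> dict:
        return {
            "r0_ohm": self.params.r0,
            "rinf_ohm": self.params.rinf,
            "tau_s": self.params.tau,
            "alpha": self.params.alpha,
            "py": self.py,
            "fc_hz": self.params.fc,
            "residual_norm": self.residual_norm,
            "converged": self.converged,
            "n_points": self.n_points,
        }


def evaluate_cole(params: ColeParameters, frequencies) -> np.ndarray:
    """Evaluate the Cole impedance model at the given frequencies (Hz).

    Returns complex impedances in Ohm.  The real part lies in
    (``rinf``, ``r0``) and the imaginary part is <= 0 (capacitive).
    """
    f = np.asarray(frequencies, dtype=float)
    if np.any(f <= 0):
        raise InputError("frequencies must all be > 0")
    omega = 2.0 * np.pi * f
    return params.rinf + (params.r0 - params.rinf) / (
        1.0 + (1j * omega * params.tau) ** params.alpha
    )


def compute_py(params_or_r0, rinf: float | None = None) -> float:
    """Py = (R0 - Rinf) / R0 * 100, the normalized beta-dispersion drop.

    Accepts either a :class:`ColeParameters` or the pair ``(r0, rinf)``.
    Scale-invariant in (R0, Rinf); value in [0, 100).
    """
    if rinf is None:
        p = params_or_r0
        r0, rinf = p.r0, p.rinf
    else:
        r0 = float(params_or_r0)
        rinf = float(rinf)
        if r0 <= 0:
            raise ParameterDomainError(f"r0 must be > 0, got {r0}")
        if rinf < 0 or rinf >= r0:
            raise ParameterDomainError(
                f"need r0 > rinf >= 0, got r0={r0}, rinf={rinf}"
            )
    return (r0 - rinf) / r0 * 100.0


def characteristic_frequency(params_or_tau) -> float:
    """f_c = 1 / (2*pi*tau): the frequency where -Im(Z) peaks (exactly so for alpha=1)."""
    tau = params_or_tau.tau if isinstance(params_or_tau, ColeParameters) else float(params_or_tau)
    if tau <= 0:
        raise ParameterDomainError(f"tau must be > 0, got {tau}")
    return 1.0 / (2.0 * math.pi * tau)


def initial_guess(spectrum: ImpedanceSpectrum) -> ColeParameters:
    """Data-driven starting point for :func:`fit_cole`.

    R0 from |Z| at the lowest frequency; tau from the frequency where
    |Im Z| peaks; alpha fixed at 0.8.  The raw high-frequency |Z| endpoint
    overestimates Rinf whenever the dispersion tail extends beyond the
    measured band, so Rinf gets a one-step correction that subtracts the
    model-predicted residual dispersion at the top frequency.
    """
    absz = np.abs(spectrum.impedance)
    zmax = float(absz.max())
    if zmax <= 0 or (zmax - float(absz.min())) / zmax < 1e-6:
        raise DegenerateSpectrumError(
            f"spectrum {spectrum.sample_id}/{spectrum.muscle} is flat (|Z| constant): "
            "no dispersion to fit"
        )
    r0 = float(absz[0])
    rinf_raw = max(float(absz[-1]), 0.0)

    im = np.abs(spectrum.impedance.imag)
    f_peak = float(spectrum.frequencies[int(np.argmax(im))])
    tau = 1.0 / (2.0 * math.pi * f_peak)
    alpha = 0.8

    # Correct the Rinf endpoint for unfinished dispersion at f_max.
    if r0 > rinf_raw:
        w_top = 2.0 * math.pi * float(spectrum.frequencies[-1])
        tail = (r0 - rinf_raw) / (1.0 + (1j * w_top * tau) ** alpha)
        rinf = max(0.0, float(spectrum.impedance[-1].real - tail.real))
    else:
        rinf = rinf_raw
    if r0 <= rinf:
        r0 = rinf * 1.05 + 1e-6
    return ColeParameters(r0=r0, rinf=rinf, tau=tau, alpha=alpha)


def _cole_eval_raw(rinf, dr, ltau, alpha, omega):
    return rinf + dr / (1.0 + (1j * omega * np.exp(ltau)) ** alpha)


def fit_cole(
    spectrum: ImpedanceSpectrum,
    init: ColeParameters | None = None,
    *,
    ftol: float = 1e-10,
    max_nfev: int = 2000,
    n_restarts: int = 3,
) -> ColeFitResult:
    """Fit the Cole model to a spectrum by weighted complex least squares.

    Minimizes ``sum_f |Z_meas(f) - Z_model(f)|^2 / |Z_meas(f)|^2``
    (proportional weighting; |Z| spans a wide range over the band and
    unweighted residuals would be dominated by the low-frequency end).
    The optimizer works on ``(Rinf, R0-Rinf, log tau, alpha)`` with bounds
    from the parameter invariants; tau in log-space avoids scale
    pathologies.  Up to ``n_restarts`` jittered restarts on failure; a
    final failure raises :class:`NonConvergenceError` carrying the best
    result found.
    """
    if init is None:
        init = initial_guess(spectrum)
    z = spectrum.impedance
    omega = 2.0 * np.pi * spectrum.frequencies
    weight = 1.0 / np.abs(z)

    def residuals(theta):
        zm = _cole_eval_raw(theta[0], theta[1], theta[2], theta[3], omega)
        d = (z - zm) * weight
        return np.concatenate([d.real, d.imag])

    lo = np.array([0.0, 1e-9, math.log(1e-12), ALPHA_MIN])
    hi = np.array([np.inf, np.inf, math.log(1e4), ALPHA_MAX])
    theta0 = np.array(
        [init.rinf, init.r0 - init.rinf, math.log(init.tau), init.alpha]
    )
    theta0 = np.clip(theta0, lo, hi if np.all(np.isfinite(hi)) else theta0)
    theta0 = np.minimum(np.maximum(theta0, lo), np.where(np.isfinite(hi), hi, theta0))

    rng = np.random.default_rng(0)  # deterministic restart jitter
    best = None
    for attempt in range(1 + n_restarts):
        if attempt == 0:
            start = theta0
        else:
            jitter = rng.normal(0.0, 0.3, size=4)
            start = theta0 + np.array(
                [
                    theta0[0] * jitter[0] * 0.5,
                    theta0[1] * jitter[1] * 0.5,
                    jitter[2],
                    jitter[3] * 0.2,
                ]
            )
            start = np.minimum(np.maximum(start, lo), np.where(np.isfinite(hi), hi, start))
        try:
            res = least_squares(
                residuals,
                start,
                bounds=(lo, hi),
                method="trf",
                ftol=ftol,
                xtol=ftol,
                gtol=ftol,
                max_nfev=max_nfev,
            )
        except (ValueError, FloatingPointError):
            continue
        if best is None or res.cost < best.cost:
            best = res
        if res.success:
            best = res if res.cost <= best.cost else best
            if best.success:
                break

    if best is None:
        raise NonConvergenceError(
            f"Cole fit failed for {spectrum.sample_id}/{spectrum.muscle}"
            f"/rep{spectrum.replicate}: optimizer raised on every start"
        )

    rinf, dr, ltau, alpha = best.x
    params = ColeParameters(
        r0=rinf + dr, rinf=rinf, tau=math.exp(ltau), alpha=min(alpha, ALPHA_MAX)
    )
    result = ColeFitResult(
        params=params,
        residual_norm=2.0 * float(best.cost),
        converged=bool(best.success),
        n_points=len(spectrum),
    )
    if not best.success:
        raise NonConvergenceError(
            f"Cole fit did not converge for {spectrum.sample_id}/{spectrum.muscle}"
            f"/rep{spectrum.replicate} after {n_restarts} restarts",
            best=result,
        )
    return result


@dataclass
class ReplicateAggregate:
    """Mean Py over replicate readings at one sample/muscle site."""

    sample_id: str
    muscle: str
    py: float
    n_replicates: int
    spread: float  # max - min replicate Py
    flagged: bool  # spread exceeded the threshold


def aggregate_replicates(
    fits: list, sample_id: str | None = None, muscle: str | None = None,
    spread_threshold: float = 5.0,
) -> ReplicateAggregate:
    """Average replicate Py values for one sample/muscle.

    Accepts :class:`ColeFitResult` objects optionally tagged with
    ``sample_id``/``muscle`` (pass explicitly when fits do not carry them).
    Raises :class:`InputError` on an empty list.  Flags the aggregate when
    the replicate Py range exceeds ``spread_threshold`` (default 5 Py
    units), indicating a dubious repeat measurement.
    """
    if not fits:
        raise InputError("aggregate_replicates needs at least one fit")
    ids = {getattr(f, "sample_id", sample_id) for f in fits}
    muscles = {getattr(f, "muscle", muscle) for f in fits}
    if len(ids) > 1:
        raise InputError(f"mixed sample_ids in replicate set: {sorted(map(str, ids))}")
    if len(muscles) > 1:
        raise InputError(f"mixed muscles in replicate set: {sorted(map(str, muscles))}")
    pys = np.array([f.py for f in fits], dtype=float)
    spread = float(pys.max() - pys.min())
    return ReplicateAggregate(
        sample_id=str(ids.pop() if ids else sample_id),
        muscle=str(muscles.pop() if muscles else muscle),
        py=float(pys.mean()),
        n_replicates=len(pys),
        spread=spread,
        flagged=spread > spread_threshold,
    )
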