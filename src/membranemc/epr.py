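"""EPR spin-probe parameter calculators and a synthetic spectrum generator.

Two spectroscopic observables interpret the membrane simulations:

* the rotational correlation time ``tau`` of a 16-DOXYL-type nitroxide probe,
  estimated from the first-derivative triplet in the fast-motion regime,

      tau = C * dB0 * ( sqrt(I0/I+1) + sqrt(I0/I-1) - 2 )   [s]

  with ``C = 5.95e-10 s/mT``, ``dB0`` the peak-to-peak width of the central
  line in mT, and ``I0, I+1, I-1`` the peak-to-peak amplitudes of the
  central, low-field, and high-field lines;

* the TEMPO partition coefficient ``F = H / (H + P)`` where ``H`` and ``P``
  are the lipid- and aqueous-phase components of the composite high-field
  line.

No experimental spectra ship with the package; a generator synthesizes
first-derivative Lorentzian triplets (and TEMPO-style composites) with known
ground truth, which the amplitude-measurement routine must recover.
Nitroxide line ordering follows the usual convention: the low-field line is
the m = +1 component, the high-field line is m = -1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateBaselineError,
    DetectionError,
    ParseError,
)

#: fast-motion calibration constant, seconds per mT
TAU_CALIBRATION_S_PER_MT = 5.95e-10

#: peak-to-peak amplitude of the unit shape -2u/(1+u^2)^2 (extrema at u = +-1/sqrt(3))
_SHAPE_PP = 3.0 * math.sqrt(3.0) / 4.0


@dataclass
class EprSpectrum:
    """First-derivative EPR spectrum on a uniform field axis (mT)."""

    field_mT: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.field_mT) <= 0):
            raise ConfigurationError("field axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ConfigurationError("spectrum intensity must be finite")


@dataclass
class SpectralParams:
    """Measured line parameters of a spectrum (unused fields remain None)."""

    I0: float | None = None
    Ip1: float | None = None
    Im1: float | None = None
    delta_B0: float | None = None  # mT
    H: float | None = None
    P: float | None = None
    tau: float | None = None  # s
    F: float | None = None


# ----------------------------------------------------------------------
# Formula operations
# ----------------------------------------------------------------------

def rotational_correlation_time(
    delta_B0: float,
    I0: float,
    Ip1: float,
    Im1: float,
    calibration: float = TAU_CALIBRATION_S_PER_MT,
) -> float:
    """Fast-motion nitroxide rotational correlation time, seconds.

    ``delta_B0`` is the central-line peak-to-peak width in mT; the amplitudes
    enter only through the ratios I0/I+1 and I0/I-1, so the estimate is
    invariant under joint rescaling.
    """
    if delta_B0 <= 0:
        raise ValueError(f"delta_B0 must be positive, got {delta_B0}")
    for name, v in (("I0", I0), ("Ip1", Ip1), ("Im1", Im1)):
        if v <= 0:
            raise ValueError(f"line amplitude {name} must be positive, got {v}")
    return calibration * delta_B0 * (math.sqrt(I0 / Ip1) + math.sqrt(I0 / Im1) - 2.0)


def partition_coefficient(H: float, P: float) -> float:
    """TEMPO partition coefficient F = H / (H + P), in [0, 1]."""
    if H < 0 or P < 0:
        raise ValueError(f"signal components must be non-negative, got H={H}, P={P}")
    if H + P == 0:
        raise DegenerateBaselineError("H + P = 0: no signal to partition")
    return H / (H + P)


def normalize_to_baseline(values) -> np.ndarray:
    """Divide a dose series by its zero-concentration (first) value."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty series")
    if arr[0] == 0:
        raise DegenerateBaselineError("baseline (first) value is zero")
    return arr / arr[0]


# ----------------------------------------------------------------------
# Synthetic spectra
# ----------------------------------------------------------------------

def _deriv_lorentzian(x: np.ndarray, center: float, width_pp: float, amp_pp: float) -> np.ndarray:
    """First-derivative Lorentzian with given peak-to-peak width and amplitude."""
    gamma = width_pp * math.sqrt(3.0) / 2.0  # absorption HWHM
    u = (x - center) / gamma
    return (amp_pp / _SHAPE_PP) * (-2.0 * u / (1.0 + u * u) ** 2)


def synth_triplet_spectrum(
    I0: float,
    Ip1: float,
    Im1: float,
    delta_B0: float,
    hyperfine_splitting: float,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    n_points: int = 4096,
    span_factor: float = 2.0,
) -> EprSpectrum:
    """Nitroxide triplet: lines at -A (I+1), 0 (I0), +A (I-1) relative to center.

    All widths share ``delta_B0``; optional Gaussian noise of standard
    deviation ``noise_sd`` is added pointwise.  Lines must be resolved
    (``hyperfine_splitting > 3 * delta_B0``).
    """
    if delta_B0 <= 0 or hyperfine_splitting <= 0:
        raise ConfigurationError("width and splitting must be positive")
    if hyperfine_splitting <= 3.0 * delta_B0:
        raise ConfigurationError(
            f"unresolved lines: splitting {hyperfine_splitting} mT must exceed "
            f"3 x width {delta_B0} mT"
        )
    A = hyperfine_splitting
    x = np.linspace(-span_factor * A, span_factor * A, n_points)
    y = (
        _deriv_lorentzian(x, -A, delta_B0, Ip1)
        + _deriv_lorentzian(x, 0.0, delta_B0, I0)
        + _deriv_lorentzian(x, +A, delta_B0, Im1)
    )
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng()
        y = y + rng.normal(0.0, noise_sd, size=n_points)
    meta = {
        "probe": "doxyl",
        "I0": I0,
        "Ip1": Ip1,
        "Im1": Im1,
        "delta_B0": delta_B0,
        "splitting": A,
        "noise_sd": noise_sd,
    }
    return EprSpectrum(field_mT=x, intensity=y, metadata=meta)


def synth_tempo_spectrum(
    H: float,
    P: float,
    splitting_lipid: float = 1.35,
    splitting_water: float = 1.75,
    width: float = 0.05,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    n_points: int = 8192,
) -> EprSpectrum:
    """TEMPO-style spectrum: two overlaid triplets with distinct splittings.

    The lipid-phase component (amplitude scale ``H``, splitting
    ``splitting_lipid``) and the aqueous component (``P``,
    ``splitting_water``) nearly coincide at low and central field but separate
    in the high-field line, whose two sub-components carry the H and P
    amplitudes read off for the partition coefficient.
    """
    if width <= 0 or splitting_lipid <= 0 or splitting_water <= splitting_lipid:
        raise ConfigurationError("require width > 0 and splitting_water > splitting_lipid > 0")
    # first-derivative Lorentzian tails fall off only like (gap/width)^-3,
    # so peak-to-peak reading to ~1% needs a generous separation
    if (splitting_water - splitting_lipid) <= 6.0 * width:
        raise ConfigurationError(
            "high-field sub-lines unresolved: splitting difference "
            f"{splitting_water - splitting_lipid} mT must exceed 6 x width {width} mT"
        )
    if H < 0 or P < 0:
        raise ConfigurationError("component amplitudes must be non-negative")
    span = 1.6 * splitting_water
    x = np.linspace(-span, span, n_points)
    y = np.zeros_like(x)
    for amp, A in ((H, splitting_lipid), (P, splitting_water)):
        if amp > 0:
            y += (
                _deriv_lorentzian(x, -A, width, amp)
                + _deriv_lorentzian(x, 0.0, width, amp)
                + _deriv_lorentzian(x, +A, width, amp)
            )
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng()
        y = y + rng.normal(0.0, noise_sd, size=n_points)
    meta = {
        "probe": "tempo",
        "H": H,
        "P": P,
        "splitting_lipid": splitting_lipid,
        "splitting_water": splitting_water,
        "width": width,
        "noise_sd": noise_sd,
    }
    return EprSpectrum(field_mT=x, intensity=y, metadata=meta)


# ----------------------------------------------------------------------
# Amplitude measurement
# ----------------------------------------------------------------------

def _refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Parabolic sub-grid interpolation of an extremum at sample ``i``."""
    if i <= 0 or i >= len(y) - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    dx = x[1] - x[0]
    return float(x[i] + delta * dx), float(y1 - 0.25 * (y0 - y2) * delta)


def _measure_line(spec: EprSpectrum, center: float, half_width: float, label: str):
    """Peak-to-peak amplitude and width of one first-derivative line."""
    x, y = spec.field_mT, spec.intensity
    mask = (x >= center - half_width) & (x <= center + half_width)
    idx = np.nonzero(mask)[0]
    if len(idx) < 5:
        raise DetectionError(f"window {label!r} ([{center - half_width}, {center + half_width}] mT) "
                             "contains too few samples")
    imax = idx[np.argmax(y[idx])]
    imin = idx[np.argmin(y[idx])]
    if imax in (idx[0], idx[-1]) or imin in (idx[0], idx[-1]):
        raise DetectionError(f"no interior extremum in window {label!r}")
    x_max, y_max = _refine(x, y, imax)
    x_min, y_min = _refine(x, y, imin)
    if not x_max < x_min:
        raise DetectionError(
            f"window {label!r}: extrema not in first-derivative order (max before min)"
        )
    amp = y_max - y_min
    if amp <= 0:
        raise DetectionError(f"window {label!r}: non-positive peak-to-peak amplitude")
    return amp, x_min - x_max


def measure_amplitudes(spectrum: EprSpectrum, probe_kind: str | None = None) -> SpectralParams:
    """Read line amplitudes (and widths) off a spectrum by windowed extremum search.

    For a ``doxyl`` triplet the three windows are centered at -A, 0, +A with
    half-width A/2 and the result carries I+1, I0, I-1, the central width
    delta_B0, and the derived tau.  For a ``tempo`` composite the central line
    and the two high-field sub-lines are measured, giving H, P and F.  Window
    geometry comes from the generator metadata (``splitting`` keys).
    """
    kind = probe_kind or spectrum.metadata.get("probe")
    if kind not in ("doxyl", "tempo"):
        raise ConfigurationError(f"unknown probe kind: {kind!r}")
    out = SpectralParams()
    if kind == "doxyl":
        A = spectrum.metadata.get("splitting")
        if A is None:
            raise ConfigurationError("spectrum metadata lacks 'splitting'; cannot place windows")
        hw = A / 2.0
        out.Ip1, _ = _measure_line(spectrum, -A, hw, "low-field")
        out.I0, out.delta_B0 = _measure_line(spectrum, 0.0, hw, "central")
        out.Im1, _ = _measure_line(spectrum, +A, hw, "high-field")
        out.tau = rotational_correlation_time(out.delta_B0, out.I0, out.Ip1, out.Im1)
    else:
        a_lip = spectrum.metadata.get("splitting_lipid")
        a_wat = spectrum.metadata.get("splitting_water")
        if a_lip is None or a_wat is None:
            raise ConfigurationError(
                "spectrum metadata lacks component splittings; cannot place windows"
            )
        gap = a_wat - a_lip
        hw = gap / 2.0
        try:
            out.H, _ = _measure_line(spectrum, a_lip, hw, "high-field lipid")
        except DetectionError:
            out.H = 0.0
        try:
            out.P, _ = _measure_line(spectrum, a_wat, hw, "high-field water")
        except DetectionError:
            out.P = 0.0
        if out.H == 0.0 and out.P == 0.0:
            raise DetectionError("no high-field component found in either window")
        out.F = partition_coefficient(out.H, out.P)
    return out


# ----------------------------------------------------------------------
# Two-column text I/O
# ----------------------------------------------------------------------

def save_spectrum(spectrum: EprSpectrum, path: str) -> None:
    """Write field/intensity columns with '#'-prefixed metadata headers."""
    with open(path, "w") as fh:
        for key, value in spectrum.metadata.items():
            fh.write(f"# {key} = {value!r}\n")
        fh.write("# field_mT intensity\n")
        for xv, yv in zip(spectrum.field_mT, spectrum.intensity):
            fh.write(f"{float(xv):.17g} {float(yv):.17g}\n")


def load_spectrum(path: str) -> EprSpectrum:
    """Read a two-column spectrum; '#' lines may carry key = value metadata."""
    meta: dict = {}
    xs, ys = [], []
    with open(path) as fh:
        for lineno, ln in enumerate(fh, 1):
            ln = ln.strip()
            if not ln:
                continue
            if ln.startswith("#"):
                body = ln[1:].strip()
                if "=" in body:
                    key, _, raw = body.partition("=")
                    raw = raw.strip()
                    try:
                        import ast

                        meta[key.strip()] = ast.literal_eval(raw)
                    except (ValueError, SyntaxError):
                        meta[key.strip()] = raw
                continue
            parts = ln.split()
            if len(parts) != 2:
                raise ParseError(f"{path!r}:{lineno}: expected two columns, got {ln!r}")
            try:
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(f"{path!r}:{lineno}: {exc}") from exc
    if not xs:
        raise ParseError(f"{path!r}: no data rows")
    return EprSpectrum(field_mT=np.array(xs), intensity=np.array(ys), metadata=meta)
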