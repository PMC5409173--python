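"""Closed-form diffusion-weighted signal models.

Three signal representations for multi-b-value breast DWI:

* mono-exponential (ADC) decay ``S = S0 exp(-b D_app)``;
* intravoxel incoherent motion (IVIM) bi-exponential mixture
  ``S = S0 [f exp(-b D*) + (1 - f) exp(-b D)]``;
* fractional-order-calculus (FROC) generalisation
  ``S = S0 exp(-D mu^{2(beta-1)} (gamma G delta)^{2 beta}
  (Delta - (2 beta - 1)/(2 beta + 1) delta))``
  with fractional order ``beta`` (heterogeneity-related, dimensionless)
  and spatial constant ``mu`` (um).

Internal unit system: time ms, length um, magnetic field mT, hence
diffusivities in um^2/ms.  b-values cross the public interface in the
conventional s/mm^2 (1000 s/mm^2 == 1 ms/um^2) and are converted at the
boundary.  Gradient amplitudes G (mT/um) are a convention derived from
the nominal b-values through the rectangular-pulse relation
``b = (gamma G delta)^2 (Delta - delta/3)`` — the ``beta = 1`` limit of
the FROC exponent — not measured hardware values.  This construction
makes the ``beta = 1`` collapse of the FROC model onto the
mono-exponential exact by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "GYROMAGNETIC_RATIO_PROTON",
    "S_MM2_PER_MS_UM2",
    "AcquisitionScheme",
    "MonoParams",
    "FROCParams",
    "IVIMParams",
    "b_value_from_gradient",
    "gradient_for_b",
    "mono_signal",
    "froc_signal",
    "ivim_signal",
]

#: Proton gyromagnetic ratio in rad ms^-1 mT^-1 (= 267.513e6 rad s^-1 T^-1).
GYROMAGNETIC_RATIO_PROTON = 267.513

#: Unit conversion: 1 ms/um^2 equals 1000 s/mm^2.
S_MM2_PER_MS_UM2 = 1000.0


def b_value_from_gradient(G, delta, Delta, gamma=GYROMAGNETIC_RATIO_PROTON):
    """b-value (s/mm^2) of a rectangular gradient pair.

    ``b = (gamma G delta)^2 (Delta - delta/3)`` with G in mT/um, timings
    in ms; the result is converted to s/mm^2.  Strictly increasing and
    quadratic in G.
    """
    G = np.asarray(G, dtype=float)
    _check_timing(delta, Delta)
    if np.any(G < 0):
        raise InvalidParameterError("gradient amplitude G must be >= 0")
    b_ms_um2 = (gamma * G * delta) ** 2 * (Delta - delta / 3.0)
    out = b_ms_um2 * S_MM2_PER_MS_UM2
    return float(out) if out.ndim == 0 else out


def gradient_for_b(b, delta, Delta, gamma=GYROMAGNETIC_RATIO_PROTON):
    """Gradient amplitude G (mT/um) producing a nominal b-value (s/mm^2).

    Inverse of :func:`b_value_from_gradient`; the round trip is exact to
    floating-point precision (G scales as sqrt(b)).
    """
    b = np.asarray(b, dtype=float)
    _check_timing(delta, Delta)
    if np.any(b < 0):
        raise InvalidParameterError("b-value must be >= 0")
    b_ms_um2 = b / S_MM2_PER_MS_UM2
    G = np.sqrt(b_ms_um2 / (Delta - delta / 3.0)) / (gamma * delta)
    return float(G) if G.ndim == 0 else G


def _check_timing(delta: float, Delta: float) -> None:
    if not delta > 0:
        raise InvalidParameterError(f"delta must be > 0, got {delta}")
    if not Delta >= delta:
        raise InvalidParameterError(
            f"Delta must be >= delta, got Delta={Delta}, delta={delta}"
        )


@dataclass(frozen=True)
class AcquisitionScheme:
    """Diffusion encoding: b-values plus pulse-sequence timing.

    Parameters
    ----------
    b_values
        Diffusion weightings in s/mm^2, non-negative and strictly
        increasing; a leading 0 is permitted (and required by most fits).
    delta
        Diffusion gradient pulse width (ms).
    Delta
        Gradient lobe separation (ms); must be >= ``delta``.
    gamma
        Gyromagnetic ratio (rad ms^-1 mT^-1); proton by default.

    The per-b gradient amplitudes (mT/um) are derived from the b-values
    via :func:`gradient_for_b` and round-trip to them within 1e-9
    relative.
    """

    b_values: tuple[float, ...]
    delta: float
    Delta: float
    gamma: float = GYROMAGNETIC_RATIO_PROTON
    gradient_amplitudes: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        if b.ndim != 1 or b.size == 0:
            raise InvalidParameterError("b_values must be a non-empty 1-D sequence")
        if np.any(b < 0):
            raise InvalidParameterError("b_values must be non-negative")
        if np.any(np.diff(b) <= 0):
            raise InvalidParameterError("b_values must be strictly increasing")
        _check_timing(self.delta, self.Delta)
        object.__setattr__(self, "b_values", tuple(float(x) for x in b))
        g = gradient_for_b(b, self.delta, self.Delta, self.gamma)
        object.__setattr__(self, "gradient_amplitudes", tuple(np.atleast_1d(g)))

    @classmethod
    def breast_protocol(cls) -> "AcquisitionScheme":
        """The four-point breast protocol: b = 0, 100, 750, 1500 s/mm^2,
        delta = 14.1 ms, Delta = 35.1 ms."""
        return cls(b_values=(0.0, 100.0, 750.0, 1500.0), delta=14.1, Delta=35.1)

    @property
    def n_b(self) -> int:
        return len(self.b_values)

    @property
    def b_array(self) -> np.ndarray:
        """b-values as an array, s/mm^2."""
        return np.asarray(self.b_values, dtype=float)

    @property
    def b_ms_um2(self) -> np.ndarray:
        """b-values in the internal ms/um^2 unit."""
        return self.b_array / S_MM2_PER_MS_UM2

    @property
    def q(self) -> np.ndarray:
        """Per-b wave-number-like factor ``gamma G delta`` (rad/um)."""
        return self.gamma * np.asarray(self.gradient_amplitudes) * self.delta


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(msg)


@dataclass(frozen=True)
class MonoParams:
    """Mono-exponential (ADC) parameters: amplitude S0 (a.u.) and apparent
    diffusion coefficient D_app (um^2/ms)."""

    S0: float
    D_app: float

    def __post_init__(self) -> None:
        _require(self.S0 >= 0, f"S0 must be >= 0, got {self.S0}")
        _require(self.D_app > 0, f"D_app must be > 0, got {self.D_app}")


@dataclass(frozen=True)
class FROCParams:
    """FROC parameters: S0 (a.u.), diffusion coefficient D (um^2/ms),
    fractional order beta in (0, 1], spatial constant mu (um)."""

    S0: float
    D: float
    beta: float
    mu: float

    def __post_init__(self) -> None:
        _require(self.S0 >= 0, f"S0 must be >= 0, got {self.S0}")
        _require(self.D > 0, f"D must be > 0, got {self.D}")
        # beta > 1 is rejected rather than extrapolated: the timing factor
        # (Delta - (2b-1)/(2b+1) delta) loses its meaning there and the
        # literature reports beta <= 1 only.
        _require(0 < self.beta <= 1, f"beta must be in (0, 1], got {self.beta}")
        _require(self.mu > 0, f"mu must be > 0, got {self.mu}")


@dataclass(frozen=True)
class IVIMParams:
    """IVIM parameters: S0 (a.u.), perfusion fraction f in [0, 1],
    pseudo-diffusion D* and tissue diffusion D (um^2/ms), D* >= D."""

    S0: float
    f: float
    D_star: float
    D: float

    def __post_init__(self) -> None:
        _require(self.S0 >= 0, f"S0 must be >= 0, got {self.S0}")
        _require(0 <= self.f <= 1, f"f must be in [0, 1], got {self.f}")
        _require(self.D > 0, f"D must be > 0, got {self.D}")
        _require(
            self.D_star >= self.D,
            f"D_star must be >= D, got D_star={self.D_star}, D={self.D}",
        )


def mono_signal(params: MonoParams, scheme: AcquisitionScheme) -> np.ndarray:
    """Mono-exponential decay ``S(b) = S0 exp(-b D_app)``, one value per b."""
    return params.S0 * np.exp(-scheme.b_ms_um2 * params.D_app)


def froc_exponent(
    D: float, beta: float, mu: float, scheme: AcquisitionScheme
) -> np.ndarray:
    """The (negative) FROC exponent per b-value:
    ``-D mu^{2(beta-1)} (gamma G delta)^{2 beta}
    (Delta - (2 beta - 1)/(2 beta + 1) delta)``.

    Exposed separately because the product ``D mu^{2(beta-1)}`` — not D
    and mu individually — is what a fixed-(delta, Delta) acquisition
    determines; diagnostics use it to quantify the D–mu coupling.
    """
    timing = scheme.Delta - (2.0 * beta - 1.0) / (2.0 * beta + 1.0) * scheme.delta
    return -D * mu ** (2.0 * (beta - 1.0)) * scheme.q ** (2.0 * beta) * timing


def froc_signal(params: FROCParams, scheme: AcquisitionScheme) -> np.ndarray:
    """FROC signal, one value per b.

    Returns exactly S0 at G = 0 and is strictly decreasing in G for
    fixed positive parameters.  A non-finite result (overflow for
    extreme beta/mu combinations) raises
    :class:`~frocdwi.errors.InvalidParameterError` rather than
    propagating NaN/inf.
    """
    with np.errstate(over="ignore", invalid="ignore"):
        s = params.S0 * np.exp(
            froc_exponent(params.D, params.beta, params.mu, scheme)
        )
    if not np.all(np.isfinite(s)):
        raise InvalidParameterError(
            f"froc_signal produced a non-finite value for params={params}"
        )
    return s


def ivim_signal(params: IVIMParams, scheme: AcquisitionScheme) -> np.ndarray:
    """IVIM bi-exponential mixture, one value per b.

    Degenerates to :func:`mono_signal` with D at f = 0 and with D* at
    f = 1; the mixture weights sum to 1 so S(0) = S0 for any f.
    """
    b = scheme.b_ms_um2
    return params.S0 * (
        params.f * np.exp(-b * params.D_star)
        + (1.0 - params.f) * np.exp(-b * params.D)
    )
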