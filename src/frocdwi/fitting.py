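"""Voxel-wise model fitting.

Estimates MonoParams, FROCParams and IVIMParams from a multi-b signal
vector, and maps thereof from 4-D volumes.  All fits are deterministic
(no randomised starts): repeated calls on identical input return
bit-identical output.

The FROC fit reproduces a staged initialisation ladder:

1. the initial D is the mono-exponential (ADC) estimate from b <= 750
   s/mm^2;
2. the initial beta is 0.5;
3. the initial mu comes from a bounded 1-D least-squares fit with D and
   beta frozen at their initial values;
4. a bounded trust-region Levenberg–Marquardt fit of (D, beta, mu) on
   the diffusion-weighted b-values (b > 0) with S0 frozen to the
   measured signal at b = 0.

With a single (delta, Delta) timing, D and mu enter the FROC exponent
only through the product ``D mu^{2(beta-1)}``: the data determine that
product and beta, while the split between D and mu is inherited from the
initial values.  Diagnostics therefore always record the starting point,
and :func:`initialization_sensitivity` quantifies the coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar

from .errors import FitDomainError, InsufficientDataError
from .signal_models import (
    AcquisitionScheme,
    FROCParams,
    IVIMParams,
    MonoParams,
)

__all__ = [
    "FIT_BOUNDS",
    "FitDiagnostics",
    "ParameterMaps",
    "SensitivityResult",
    "fit_mono",
    "fit_froc",
    "fit_ivim",
    "fit_parameter_maps",
    "initialization_sensitivity",
    "MAP_KEYS",
]

#: Fit bounds (internal units: um^2/ms for diffusivities, um for mu).
#: They enclose all values reported for breast tissue with wide margins.
FIT_BOUNDS = {
    "D": (1e-3, 10.0),
    "beta": (0.01, 1.0),
    "mu": (0.1, 50.0),
    "f": (0.0, 1.0),
    "D_star": (1e-3, 500.0),
}

_FTOL = _XTOL = _GTOL = 1e-10
_MAX_NFEV = 500

#: Map layer names produced per model by :func:`fit_parameter_maps`.
MAP_KEYS = {
    "mono": ("d_app",),
    "froc": ("d_froc", "beta_froc", "mu_froc"),
    "ivim": ("f_ivim", "d_star_ivim", "d_ivim"),
}


@dataclass(frozen=True)
class FitDiagnostics:
    """Per-fit bookkeeping.

    ``initial_values`` records the full starting point of the nonlinear
    stage — required downstream because the D–mu split of a FROC fit is
    inherited from it.  ``flags`` carries free-form quality markers such
    as ``"not_converged"``, ``"beta_at_bound"`` or
    ``"d_star_low_confidence"``.
    """

    converged: bool
    residual_norm: float
    n_iterations: int
    initial_values: Mapping[str, float]
    flags: tuple[str, ...] = ()


def _positive(signal: np.ndarray, where: str) -> None:
    if np.any(~np.isfinite(signal)) or np.any(signal <= 0):
        raise FitDomainError(f"non-positive or non-finite signal in {where}")


def fit_mono(
    signal: np.ndarray,
    scheme: AcquisitionScheme,
    b_max: float = 750.0,
) -> MonoParams:
    """Apparent diffusion coefficient by log-linear least squares.

    Uses only b-values <= ``b_max`` (s/mm^2) — by default b <= 750, so a
    b = 1500 channel never influences D_app.  The estimator is ordinary
    least squares of log(S) on b, which is exact on noiseless
    mono-exponential data.
    """
    signal = np.asarray(signal, dtype=float)
    b = scheme.b_array
    if signal.shape != b.shape:
        raise InsufficientDataError(
            f"signal length {signal.size} != number of b-values {b.size}"
        )
    use = b <= b_max
    if use.sum() < 2:
        raise InsufficientDataError(
            f"need at least two b-values <= {b_max} s/mm^2, got {int(use.sum())}"
        )
    _positive(signal[use], f"mono fit (b <= {b_max})")
    x = scheme.b_ms_um2[use]
    y = np.log(signal[use])
    xm, ym = x.mean(), y.mean()
    slope = np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2)
    intercept = ym - slope * xm
    d_app = -slope
    if not d_app > 0:
        raise FitDomainError(
            f"mono fit produced non-positive D_app = {d_app:.4g} um^2/ms"
        )
    return MonoParams(S0=float(np.exp(intercept)), D_app=float(d_app))


def _weighted_channels(
    signal: np.ndarray, scheme: AcquisitionScheme
) -> tuple[float, np.ndarray, np.ndarray]:
    """Split a signal vector into (S0, weighted b in ms/um^2, weighted
    signal); requires a b = 0 channel and positive signal everywhere."""
    signal = np.asarray(signal, dtype=float)
    b = scheme.b_array
    if signal.shape != b.shape:
        raise InsufficientDataError(
            f"signal length {signal.size} != number of b-values {b.size}"
        )
    if b[0] != 0.0:
        raise InsufficientDataError("scheme lacks a b = 0 channel")
    _positive(signal, "nonlinear fit")
    return float(signal[0]), scheme.b_ms_um2[1:], signal[1:]


def _froc_decay(b_ms: np.ndarray, d: float, beta: float, mu: float,
                delta: float, Delta: float) -> np.ndarray:
    """FROC decay factor written in terms of the nominal b-value:
    ``(gamma G delta)^{2 beta} = (b / (Delta - delta/3))^beta``."""
    timing = Delta - (2.0 * beta - 1.0) / (2.0 * beta + 1.0) * delta
    q2beta = (b_ms / (Delta - delta / 3.0)) ** beta
    return np.exp(-d * mu ** (2.0 * (beta - 1.0)) * q2beta * timing)


def _froc_exponent_and_jac(
    x: np.ndarray, b_ms: np.ndarray, delta: float, Delta: float
) -> tuple[np.ndarray, np.ndarray]:
    """FROC exponent K_i (so the model is s0*exp(-K)) and dK/d(d, beta, mu)."""
    d, beta, mu = x
    timing = Delta - (2.0 * beta - 1.0) / (2.0 * beta + 1.0) * delta
    lb = np.log(b_ms / (Delta - delta / 3.0))
    K = d * mu ** (2.0 * (beta - 1.0)) * np.exp(beta * lb) * timing
    dT = -delta * 4.0 / (2.0 * beta + 1.0) ** 2
    dK = np.empty((b_ms.size, 3))
    dK[:, 0] = K / d
    dK[:, 1] = K * (2.0 * np.log(mu) + lb + dT / timing)
    dK[:, 2] = K * 2.0 * (beta - 1.0) / mu
    return K, dK


def fit_froc(
    signal: np.ndarray,
    scheme: AcquisitionScheme,
    d_init: float | None = None,
    mu_init: float | None = None,
    beta_init: float = 0.5,
) -> tuple[FROCParams, FitDiagnostics]:
    """FROC fit with the staged initialisation ladder.

    ``d_init`` / ``mu_init`` override stages 1 and 3 (used by
    :func:`initialization_sensitivity`); by default stage 1 is the
    b <= 750 mono fit and stage 3 a bounded 1-D least-squares fit of mu
    alone.  S0 is not fitted but frozen to the signal at b = 0; the
    nonlinear stage uses only the diffusion-weighted (b > 0) channels.
    """
    s0, b_w, y_w = _weighted_channels(signal, scheme)
    if b_w.size < 3:
        raise InsufficientDataError(
            f"FROC fit needs >= 3 diffusion-weighted b-values, got {b_w.size}"
        )
    delta, Delta = scheme.delta, scheme.Delta
    lo = np.array([FIT_BOUNDS["D"][0], FIT_BOUNDS["beta"][0], FIT_BOUNDS["mu"][0]])
    hi = np.array([FIT_BOUNDS["D"][1], FIT_BOUNDS["beta"][1], FIT_BOUNDS["mu"][1]])

    if d_init is None:
        d_init = fit_mono(signal, scheme).D_app
    d_init = float(np.clip(d_init, lo[0], hi[0]))
    beta_init = float(np.clip(beta_init, lo[1], hi[1]))

    if mu_init is None:
        # bounded 1-D least squares over mu with (D_init, beta_init) frozen
        def sse_mu(m: float) -> float:
            r = s0 * _froc_decay(b_w, d_init, beta_init, m, delta, Delta) - y_w
            return float(r @ r)

        res_mu = minimize_scalar(
            sse_mu, bounds=(lo[2], hi[2]), method="bounded",
            options={"xatol": 1e-10, "maxiter": _MAX_NFEV},
        )
        mu_init = float(res_mu.x)
    mu_init = float(np.clip(mu_init, lo[2], hi[2]))

    def residuals(x: np.ndarray) -> np.ndarray:
        K, _ = _froc_exponent_and_jac(x, b_w, delta, Delta)
        return s0 * np.exp(-K) - y_w

    def jacobian(x: np.ndarray) -> np.ndarray:
        K, dK = _froc_exponent_and_jac(x, b_w, delta, Delta)
        return -(s0 * np.exp(-K))[:, None] * dK

    res = least_squares(
        residuals,
        x0=[d_init, beta_init, mu_init],
        jac=jacobian,
        bounds=(lo, hi),
        method="trf",
        x_scale=[1.0, 1.0, 10.0],
        ftol=_FTOL, xtol=_XTOL, gtol=_GTOL, max_nfev=_MAX_NFEV,
    )
    d, beta, mu = (float(v) for v in np.clip(res.x, lo, hi))
    flags = []
    converged = bool(res.status > 0)
    if not converged:
        flags.append("not_converged")
    if beta >= hi[1] - 1e-12 or beta <= lo[1] + 1e-12:
        flags.append("beta_at_bound")
    params = FROCParams(S0=s0, D=d, beta=beta, mu=mu)
    diag = FitDiagnostics(
        converged=converged,
        residual_norm=float(2.0 * res.cost),
        n_iterations=int(res.nfev),
        initial_values={"D": d_init, "beta": beta_init, "mu": mu_init},
        flags=tuple(flags),
    )
    return params, diag


def fit_ivim(
    signal: np.ndarray,
    scheme: AcquisitionScheme,
) -> tuple[IVIMParams, FitDiagnostics]:
    """IVIM fit on all b-values with deterministic segmented initialisation.

    S0 is frozen to the signal at b = 0 (mirroring the FROC convention).
    The constraint D* >= D is enforced structurally by fitting the
    excess ``D* - D >= 0``.  Initial values: D from the high-b
    (b >= 750) mono slope; f from the gap between S0 and the high-b fit
    extrapolated to b = 0, clipped to [0.01, 0.5]; D* = 10 D.  D* is
    returned but flagged low-confidence: with a single low-b channel it
    is poorly determined.
    """
    s0, b_w, y_w = _weighted_channels(signal, scheme)
    if b_w.size < 3:
        raise InsufficientDataError(
            f"IVIM fit needs >= 3 diffusion-weighted b-values, got {b_w.size}"
        )
    b_all = scheme.b_ms_um2
    y_all = np.asarray(signal, dtype=float)

    high = b_w >= 750.0 / 1000.0
    if high.sum() < 2:
        raise InsufficientDataError("IVIM initialisation needs >= 2 b-values >= 750")
    xh, yh = b_w[high], np.log(y_w[high])
    slope = (yh[-1] - yh[0]) / (xh[-1] - xh[0]) if high.sum() == 2 else (
        np.polyfit(xh, yh, 1)[0]
    )
    d0 = float(np.clip(-slope, FIT_BOUNDS["D"][0], FIT_BOUNDS["D"][1]))
    s0_ext = float(np.exp(yh[0] + d0 * xh[0]))
    f0 = float(np.clip(1.0 - s0_ext / s0, 0.01, 0.5))
    exc0 = 9.0 * d0  # D*_init = 10 * D_init

    lo = np.array([FIT_BOUNDS["f"][0], FIT_BOUNDS["D"][0], 0.0])
    hi = np.array([
        FIT_BOUNDS["f"][1],
        FIT_BOUNDS["D"][1],
        FIT_BOUNDS["D_star"][1] - FIT_BOUNDS["D"][0],
    ])
    exc0 = float(np.clip(exc0, lo[2], hi[2]))

    def residuals(x: np.ndarray) -> np.ndarray:
        f, d, exc = x
        return s0 * (
            f * np.exp(-b_all * (d + exc)) + (1.0 - f) * np.exp(-b_all * d)
        ) - y_all

    def jacobian(x: np.ndarray) -> np.ndarray:
        f, d, exc = x
        e_fast = np.exp(-b_all * (d + exc))
        e_slow = np.exp(-b_all * d)
        jac = np.empty((b_all.size, 3))
        jac[:, 0] = s0 * (e_fast - e_slow)
        jac[:, 1] = -s0 * b_all * (f * e_fast + (1.0 - f) * e_slow)
        jac[:, 2] = -s0 * b_all * f * e_fast
        return jac

    res = least_squares(
        residuals,
        x0=[f0, d0, exc0],
        jac=jacobian,
        bounds=(lo, hi),
        method="trf",
        x_scale=[0.1, 1.0, 10.0],
        ftol=_FTOL, xtol=_XTOL, gtol=_GTOL, max_nfev=_MAX_NFEV,
    )
    f, d, exc = (float(v) for v in np.clip(res.x, lo, hi))
    flags = ["d_star_low_confidence"]
    converged = bool(res.status > 0)
    if not converged:
        flags.append("not_converged")
    params = IVIMParams(S0=s0, f=f, D_star=d + exc, D=d)
    diag = FitDiagnostics(
        converged=converged,
        residual_norm=float(2.0 * res.cost),
        n_iterations=int(res.nfev),
        initial_values={"f": f0, "D_star": d0 + exc0, "D": d0},
        flags=tuple(flags),
    )
    return params, diag


@dataclass
class ParameterMaps:
    """Spatial per-voxel parameter images for one model.

    ``maps`` holds one 3-D float array per parameter (NaN outside the
    valid mask — never silently zero-filled); ``valid`` marks voxels
    with a successful fit; ``diagnostics`` carries per-voxel layers
    (converged flag, residual norm, iteration count).
    """

    model: str
    maps: dict[str, np.ndarray]
    valid: np.ndarray
    diagnostics: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.maps.items():
            if arr.shape != self.valid.shape:
                raise ValueError(f"map {name!r} shape {arr.shape} != mask shape")


def _scalar_fit(model: str) -> Callable:
    if model == "mono":
        def f(sig, scheme):
            p = fit_mono(sig, scheme)
            return {"d_app": p.D_app}, True, {}
    elif model == "froc":
        def f(sig, scheme):
            p, d = fit_froc(sig, scheme)
            return (
                {"d_froc": p.D, "beta_froc": p.beta, "mu_froc": p.mu},
                d.converged,
                {"residual_norm": d.residual_norm, "n_iterations": d.n_iterations},
            )
    elif model == "ivim":
        def f(sig, scheme):
            p, d = fit_ivim(sig, scheme)
            return (
                {"f_ivim": p.f, "d_star_ivim": p.D_star, "d_ivim": p.D},
                d.converged,
                {"residual_norm": d.residual_norm, "n_iterations": d.n_iterations},
            )
    else:
        raise ValueError(f"unknown model {model!r}; expected mono, froc or ivim")
    return f


def fit_parameter_maps(
    volume: np.ndarray,
    mask: np.ndarray,
    model: str,
    scheme: AcquisitionScheme,
) -> ParameterMaps:
    """Fit one model voxel-by-voxel over a 4-D volume.

    Every masked voxel is fitted independently (the result does not
    depend on traversal order); voxels outside the mask, and voxels
    whose fit raises, are flagged invalid rather than aborting the
    volume.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if volume.ndim != 4:
        raise ValueError(f"volume must be 4-D, got shape {volume.shape}")
    if volume.shape[:3] != mask.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume grid {volume.shape[:3]}"
        )
    if volume.shape[3] != scheme.n_b:
        raise ValueError(
            f"volume has {volume.shape[3]} channels but scheme has {scheme.n_b}"
        )
    fitter = _scalar_fit(model)
    keys = MAP_KEYS[model]
    shape = mask.shape
    maps = {k: np.full(shape, np.nan) for k in keys}
    valid = np.zeros(shape, dtype=bool)
    diag = {
        "converged": np.zeros(shape, dtype=bool),
        "residual_norm": np.full(shape, np.nan),
        "n_iterations": np.zeros(shape, dtype=int),
    }
    for idx in np.argwhere(mask):
        i, j, k = (int(v) for v in idx)
        sig = volume[i, j, k, :]
        try:
            values, converged, extra = fitter(sig, scheme)
        except (FitDomainError, InsufficientDataError):
            continue
        for name, v in values.items():
            maps[name][i, j, k] = v
        valid[i, j, k] = True
        diag["converged"][i, j, k] = converged
        diag["residual_norm"][i, j, k] = extra.get("residual_norm", 0.0)
        diag["n_iterations"][i, j, k] = extra.get("n_iterations", 0)
    return ParameterMaps(model=model, maps=maps, valid=valid, diagnostics=diag)


@dataclass
class SensitivityResult:
    """Result of :func:`initialization_sensitivity`: one fitted row per
    starting point, plus the max-minus-min spread per parameter."""

    table: pd.DataFrame
    spread: dict[str, float]


def initialization_sensitivity(
    signal: np.ndarray,
    scheme: AcquisitionScheme,
    d_inits: Iterable[float],
    mu_inits: Iterable[float],
) -> SensitivityResult:
    """Refit FROC from a grid of (D_init, mu_init) starting points.

    Quantifies the D–mu coupling: with a single gradient timing the
    data pin down only beta and the product ``D mu^{2(beta-1)}``, so the
    individual D and mu land wherever the starting point sends them.
    The returned table carries the fitted (D, beta, mu), the invariant
    product, and the residual norm per start; ``spread`` summarises
    max - min over the grid for each quantity.
    """
    d_inits = list(d_inits)
    mu_inits = list(mu_inits)
    if not d_inits or not mu_inits:
        raise ValueError("init grids must be non-empty")
    rows = []
    for d0 in d_inits:
        for m0 in mu_inits:
            params, diag = fit_froc(signal, scheme, d_init=d0, mu_init=m0)
            rows.append(
                {
                    "d_init": float(d0),
                    "mu_init": float(m0),
                    "d_froc": params.D,
                    "beta_froc": params.beta,
                    "mu_froc": params.mu,
                    "coupling_product": params.D
                    * params.mu ** (2.0 * (params.beta - 1.0)),
                    "residual_norm": diag.residual_norm,
                    "converged": diag.converged,
                }
            )
    table = pd.DataFrame(rows)
    spread = {
        col: float(table[col].max() - table[col].min())
        for col in ("d_froc", "beta_froc", "mu_froc", "coupling_product")
    }
    return SensitivityResult(table=table, spread=spread)
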