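"""Synthetic breast-DWI phantom cohorts.

Generates seeded 4-D diffusion-weighted volumes and lesion cohorts with
the statistical structure the analysis pipeline assumes, so every stage
is testable without clinical data.  The generative model:

* Per-lesion parameters are drawn from class-conditional (benign vs
  malignant) two-parameter laws calibrated to published per-lesion
  group statistics: log-normal for the diffusion coefficient D
  (um^2/ms, medians 0.97 malignant / 1.20 benign) and the spatial
  constant mu (um, 8.34 / 8.91), logit-normal for the fractional order
  beta (0.69 / 0.75) and the perfusion fraction f.  Median and one
  quartile identify each law exactly; because the printed quartiles are
  asymmetric, a ``skew`` flag selects whether the upper, lower, or
  averaged quartile sets the spread (default: averaged).
* The f law is only weakly informative by design (calibration target
  AUC ~ 0.54); per-class D* laws are not published, so both classes
  share a broad log-normal (median 30 um^2/ms) — documented
  approximate.
* Each lesion is rendered as a world-mm sphere (axis-aligned ellipsoid
  in voxels) of a per-class truncated-normal diameter, on a 2.5 x 2.5 x
  3 mm grid.  Voxel signals follow the IVIM mixture whose tissue term
  is the FROC decay, with 5% relative within-lesion parameter jitter;
  background voxels carry a distinct high-diffusivity fibroglandular
  signal.  Rician noise is added at a configurable SNR (default 50 at
  b = 0).

Everything is exactly reproducible from (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .cohort import BENIGN, MALIGNANT, LesionRecord
from .errors import ConfigurationError, InvalidParameterError
from .fitting import fit_froc, fit_ivim, fit_mono
from .signal_models import AcquisitionScheme

__all__ = [
    "QuantileSpec",
    "ClassParamModel",
    "PhantomSpec",
    "GroundTruth",
    "SimulatedCohort",
    "MALIGNANT_MODEL",
    "BENIGN_MODEL",
    "DIAMETER_PRESETS",
    "add_rician_noise",
    "sample_lesion_params",
    "simulate_cohort",
    "simulate_cohort_summaries",
]

_Z75 = 0.6744897501960817  # standard normal 75% quantile


@dataclass(frozen=True)
class QuantileSpec:
    """A distribution summarised by its median and quartiles."""

    median: float
    q25: float
    q75: float

    def __post_init__(self) -> None:
        if not (self.q25 <= self.median <= self.q75):
            raise ConfigurationError(
                f"infeasible quartiles: q25={self.q25}, median={self.median}, "
                f"q75={self.q75}"
            )


def _latent_sigma(qs: QuantileSpec, transform, skew: str) -> float:
    """Latent-normal sigma from the median and one quartile.

    ``skew`` selects the calibrating quartile: 'upper' (q75), 'lower'
    (q25) or 'mean' (average of both implied sigmas).
    """
    up = (transform(qs.q75) - transform(qs.median)) / _Z75
    lo = (transform(qs.median) - transform(qs.q25)) / _Z75
    if skew == "upper":
        return up
    if skew == "lower":
        return lo
    if skew == "mean":
        return 0.5 * (up + lo)
    raise ConfigurationError(f"skew must be 'upper', 'lower' or 'mean', got {skew!r}")


def _degenerate(qs: QuantileSpec) -> bool:
    return qs.q25 == qs.median == qs.q75


def _sample_lognormal(qs: QuantileSpec, skew: str, rng, size=None):
    if _degenerate(qs):
        return qs.median if size is None else np.full(size, qs.median)
    return np.exp(math.log(qs.median) + _latent_sigma(qs, math.log, skew)
                  * rng.standard_normal(size))


def _sample_logitnormal(qs: QuantileSpec, skew: str, rng, size=None):
    if _degenerate(qs):
        return qs.median if size is None else np.full(size, qs.median)
    return expit(logit(qs.median) + _latent_sigma(qs, logit, skew)
                 * rng.standard_normal(size))


# Perfusion-fraction law: published group quartiles do not exist, only a
# weak diagnostic signal (AUC ~ 0.54).  A shared latent sigma of 0.35
# around a benign median of 0.055 with the malignant latent mean shifted
# by sqrt(2) * sigma * Phi^-1(0.54) reproduces that population AUC.
_F_SIGMA = 0.35
_F_BENIGN_MEDIAN = 0.055
_F_TARGET_AUC = 0.54
_f_benign_latent = float(logit(_F_BENIGN_MEDIAN))
_f_malignant_latent = _f_benign_latent + math.sqrt(2.0) * _F_SIGMA * float(
    stats.norm.ppf(_F_TARGET_AUC)
)


def _f_quantiles(latent_mean: float) -> QuantileSpec:
    return QuantileSpec(
        median=float(expit(latent_mean)),
        q25=float(expit(latent_mean - _Z75 * _F_SIGMA)),
        q75=float(expit(latent_mean + _Z75 * _F_SIGMA)),
    )


@dataclass(frozen=True)
class ClassParamModel:
    """Per-class lesion-level parameter laws.

    ``d``, ``mu`` are log-normal; ``beta``, ``f`` logit-normal — each
    identified by median plus quartile(s).  ``d_star_median`` /
    ``d_star_sigma`` define a log-normal pseudo-diffusion law (not
    calibrated to published values; none exist)."""

    d: QuantileSpec
    beta: QuantileSpec
    mu: QuantileSpec
    f: QuantileSpec
    d_star_median: float = 30.0
    d_star_sigma: float = 0.3


#: Malignant-lesion defaults: D 0.97 (0.87–1.01) um^2/ms, beta 0.69
#: (0.60–0.77), mu 8.34 (7.74–9.05) um.
MALIGNANT_MODEL = ClassParamModel(
    d=QuantileSpec(0.97, 0.87, 1.01),
    beta=QuantileSpec(0.69, 0.60, 0.77),
    mu=QuantileSpec(8.34, 7.74, 9.05),
    f=_f_quantiles(_f_malignant_latent),
)

#: Benign-lesion defaults: D 1.20 (1.06–1.47) um^2/ms, beta 0.75
#: (0.64–0.78), mu 8.91 (7.30–10.30) um.
BENIGN_MODEL = ClassParamModel(
    d=QuantileSpec(1.20, 1.06, 1.47),
    beta=QuantileSpec(0.75, 0.64, 0.78),
    mu=QuantileSpec(8.91, 7.30, 10.30),
    f=_f_quantiles(_f_benign_latent),
)

#: Lesion-diameter models (mm): mean/SD per class plus truncation range.
#: Two presets because the source statistics are self-inconsistent
#: between the running text and the demographics table; 'table2' is the
#: default.
DIAMETER_PRESETS = {
    "table2": {
        BENIGN: (11.54, 4.03, 4.9, 21.7),
        MALIGNANT: (12.56, 5.17, 6.3, 21.3),
    },
    "text": {
        BENIGN: (11.54, 5.16, 4.9, 21.7),
        MALIGNANT: (12.54, 4.03, 6.3, 21.3),
    },
}


@dataclass(frozen=True)
class PhantomSpec:
    """Generative description of one synthetic cohort.

    Defaults reproduce the study conditions: 29 malignant + 22 benign
    lesions, the four-point b-scheme with delta = 14.1 ms / Delta = 35.1
    ms, 2.5 x 2.5 x 3 mm voxels, SNR 50 at b = 0, 5% within-lesion
    parameter jitter.
    """

    n_malignant: int = 29
    n_benign: int = 22
    scheme: AcquisitionScheme = field(
        default_factory=AcquisitionScheme.breast_protocol
    )
    voxel_size: tuple[float, float, float] = (2.5, 2.5, 3.0)
    #: Optional explicit grid; by default the grid is sized so that one
    #: cell per lesion fits the largest admissible diameter.
    grid_shape: tuple[int, int, int] | None = None
    s0_lesion: float = 1000.0
    s0_background: float = 300.0
    background_adc: float = 2.0
    snr: float = 50.0
    within_lesion_cv: float = 0.05
    diameter_preset: str = "table2"
    skew: str = "mean"
    malignant_model: ClassParamModel = MALIGNANT_MODEL
    benign_model: ClassParamModel = BENIGN_MODEL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_malignant < 0 or self.n_benign < 0:
            raise ConfigurationError("lesion counts must be >= 0")
        if not self.snr > 0:
            raise ConfigurationError(f"snr must be > 0 (inf = noiseless), got {self.snr}")
        if self.within_lesion_cv < 0:
            raise ConfigurationError("within_lesion_cv must be >= 0")
        if self.diameter_preset not in DIAMETER_PRESETS:
            raise ConfigurationError(
                f"unknown diameter preset {self.diameter_preset!r}; "
                f"choose from {sorted(DIAMETER_PRESETS)}"
            )
        _latent_sigma(self.malignant_model.d, math.log, self.skew)  # validates skew

    @property
    def noise_sigma(self) -> float:
        """Rician sigma in signal units (0 when snr is infinite)."""
        return 0.0 if math.isinf(self.snr) else self.s0_lesion / self.snr

    def class_model(self, label: str) -> ClassParamModel:
        return self.malignant_model if label == MALIGNANT else self.benign_model


def add_rician_noise(signal, sigma: float, rng: np.random.Generator):
    """Magnitude-MRI (Rician) noise: |signal + complex Gaussian(0, sigma)|.

    The two quadrature channels receive independent N(0, sigma) noise,
    giving E[M^2] = S^2 + 2 sigma^2 exactly.  sigma = 0 returns the
    input unchanged.
    """
    signal = np.asarray(signal, dtype=float)
    if sigma < 0:
        raise InvalidParameterError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return signal.copy()
    re = signal + sigma * rng.standard_normal(signal.shape)
    im = sigma * rng.standard_normal(signal.shape)
    return np.hypot(re, im)


def sample_lesion_params(
    label: str, spec: PhantomSpec, rng: np.random.Generator
) -> dict[str, float]:
    """Draw one lesion's (d, beta, mu, f, d_star) from its class laws.

    Draws are clipped to the fitting bounds (the calibrated laws put
    negligible mass outside them).
    """
    model = spec.class_model(label)
    d = float(np.clip(_sample_lognormal(model.d, spec.skew, rng), 1e-3, 10.0))
    beta = float(np.clip(_sample_logitnormal(model.beta, spec.skew, rng), 0.01, 1.0))
    mu = float(np.clip(_sample_lognormal(model.mu, spec.skew, rng), 0.1, 50.0))
    f = float(np.clip(_sample_logitnormal(model.f, spec.skew, rng), 0.0, 1.0))
    d_star = float(
        np.exp(math.log(model.d_star_median)
               + model.d_star_sigma * rng.standard_normal())
    )
    return {"d": d, "beta": beta, "mu": mu, "f": f, "d_star": max(d_star, d)}


def _sample_diameter(label: str, spec: PhantomSpec, rng: np.random.Generator) -> float:
    mean, sd, lo, hi = DIAMETER_PRESETS[spec.diameter_preset][label]
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _froc_decay_b(b_ms, d, beta, mu, delta, Delta):
    timing = Delta - (2.0 * beta - 1.0) / (2.0 * beta + 1.0) * delta
    return np.exp(
        -d * mu ** (2.0 * (beta - 1.0))
        * (b_ms / (Delta - delta / 3.0)) ** beta * timing
    )


def _voxel_signals(
    truth: dict[str, float],
    n_vox: int,
    spec: PhantomSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Noise-free signals (n_vox x n_b) for one lesion with within-lesion
    jitter, plus the per-voxel true parameters."""
    cv = spec.within_lesion_cv
    jit = lambda: np.exp(cv * rng.standard_normal(n_vox))  # noqa: E731
    d = truth["d"] * jit()
    beta = np.minimum(truth["beta"] * jit(), 1.0)
    mu = truth["mu"] * jit()
    f = np.clip(truth["f"] * jit(), 0.0, 1.0)
    d_star = np.maximum(truth["d_star"] * jit(), d)
    sch = spec.scheme
    b = sch.b_ms_um2[None, :]
    decay = _froc_decay_b(
        b, d[:, None], beta[:, None], mu[:, None], sch.delta, sch.Delta
    )
    sig = spec.s0_lesion * (
        f[:, None] * np.exp(-b * d_star[:, None]) + (1.0 - f[:, None]) * decay
    )
    return sig, {"d": d, "beta": beta, "mu": mu, "f": f, "d_star": d_star}


@dataclass
class GroundTruth:
    """Reproducible truth of one simulated cohort: per-lesion parameters,
    per-voxel true maps (NaN outside lesions), and the noise-free
    volume."""

    lesion_params: pd.DataFrame
    true_maps: dict[str, np.ndarray]
    noisefree: np.ndarray
    seed: int


@dataclass
class SimulatedCohort:
    """Simulation output in the same shapes the fitting pipeline consumes."""

    volume: np.ndarray
    roi_labels: np.ndarray
    lesion_table: pd.DataFrame
    scheme: AcquisitionScheme
    truth: GroundTruth
    noise_sigma: float
    voxel_size: tuple[float, float, float]


def _lesion_labels(spec: PhantomSpec) -> list[str]:
    return [MALIGNANT] * spec.n_malignant + [BENIGN] * spec.n_benign


def simulate_cohort(spec: PhantomSpec, seed: int | None = None) -> SimulatedCohort:
    """Render a full cohort volume: one spherical lesion per grid cell on
    a background of high-diffusivity fibroglandular tissue, plus Rician
    noise.  Bit-identical for identical (spec, seed)."""
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    labels = _lesion_labels(spec)
    n = len(labels)
    if n == 0:
        raise ConfigurationError("cohort must contain at least one lesion")
    vx, vy, vz = spec.voxel_size
    ncols = int(math.ceil(math.sqrt(n)))
    nrows = int(math.ceil(n / ncols))
    if spec.grid_shape is None:
        max_diam = max(
            hi for (_, _, _, hi) in DIAMETER_PRESETS[spec.diameter_preset].values()
        )
        cell_x = int(math.ceil(max_diam / vx)) + 2
        cell_y = cell_x
        cell_z = int(math.ceil(max_diam / vz)) + 2
        shape = (ncols * cell_x, nrows * cell_y, cell_z)
    else:
        shape = tuple(int(s) for s in spec.grid_shape)
        cell_x, cell_y, cell_z = shape[0] // ncols, shape[1] // nrows, shape[2]
        if min(cell_x, cell_y, cell_z) < 1:
            raise ConfigurationError(
                f"grid_shape {shape} too small for {n} lesion cells"
            )

    sch = spec.scheme
    b = sch.b_ms_um2
    background = spec.s0_background * np.exp(-b * spec.background_adc)
    noisefree = np.broadcast_to(background, shape + (sch.n_b,)).copy()
    roi = np.zeros(shape, dtype=np.int32)
    truth_maps = {
        k: np.full(shape, np.nan) for k in ("d", "beta", "mu", "f", "d_star")
    }

    ii, jj, kk = np.indices(shape)
    rows = []
    for lesion_id, label in enumerate(labels, start=1):
        truth = sample_lesion_params(label, spec, rng)
        diam = _sample_diameter(label, spec, rng)
        cell = lesion_id - 1
        cx = (cell % ncols) * cell_x + cell_x / 2.0
        cy = (cell // ncols) * cell_y + cell_y / 2.0
        cz = cell_z / 2.0
        if diam > min(cell_x * vx, cell_y * vy, cell_z * vz):
            raise ConfigurationError(
                f"lesion {lesion_id} diameter {diam:.1f} mm exceeds the grid cell"
            )
        r = diam / 2.0
        inside = (
            (((ii + 0.5 - cx) * vx) / r) ** 2
            + (((jj + 0.5 - cy) * vy) / r) ** 2
            + (((kk + 0.5 - cz) * vz) / r) ** 2
        ) <= 1.0
        n_vox = int(inside.sum())
        if n_vox == 0:  # tiny lesion: keep at least the centre voxel
            inside[int(cx), int(cy), int(cz)] = True
            n_vox = 1
        sig, vox_truth = _voxel_signals(truth, n_vox, spec, rng)
        noisefree[inside] = sig
        roi[inside] = lesion_id
        for k, arr in vox_truth.items():
            truth_maps[k][inside] = arr
        rows.append({"lesion_id": lesion_id, "label": label,
                     "size_mm": diam, **truth})

    volume = add_rician_noise(noisefree, spec.noise_sigma, rng)
    lesion_params = pd.DataFrame(rows)
    return SimulatedCohort(
        volume=volume,
        roi_labels=roi,
        lesion_table=lesion_params[["lesion_id", "label", "size_mm"]].copy(),
        scheme=sch,
        truth=GroundTruth(
            lesion_params=lesion_params,
            true_maps=truth_maps,
            noisefree=noisefree,
            seed=seed,
        ),
        noise_sigma=spec.noise_sigma,
        voxel_size=spec.voxel_size,
    )


def simulate_cohort_summaries(
    spec: PhantomSpec,
    seed: int | None = None,
    n_voxels_per_lesion: int = 8,
    models: Sequence[str] = ("mono", "froc", "ivim"),
) -> tuple[list[LesionRecord], pd.DataFrame]:
    """Summary-level cohort simulation for replicate studies.

    Skips spatial rendering: each lesion contributes
    ``n_voxels_per_lesion`` jittered noisy voxel signals that are fitted
    and averaged, exactly as the imaging pipeline would do over an ROI,
    without paying for a full volume.  Returns the per-lesion records
    and the per-lesion truth table.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    records: list[LesionRecord] = []
    rows = []
    for lesion_id, label in enumerate(_lesion_labels(spec), start=1):
        truth = sample_lesion_params(label, spec, rng)
        diam = _sample_diameter(label, spec, rng)
        sig, _ = _voxel_signals(truth, n_voxels_per_lesion, spec, rng)
        noisy = add_rician_noise(sig, spec.noise_sigma, rng)
        sums: dict[str, list[float]] = {}
        for vox in noisy:
            if "mono" in models:
                sums.setdefault("d_app", []).append(fit_mono(vox, spec.scheme).D_app)
            if "froc" in models:
                p, _d = fit_froc(vox, spec.scheme)
                sums.setdefault("d_froc", []).append(p.D)
                sums.setdefault("beta_froc", []).append(p.beta)
                sums.setdefault("mu_froc", []).append(p.mu)
            if "ivim" in models:
                p, _d = fit_ivim(vox, spec.scheme)
                sums.setdefault("f_ivim", []).append(p.f)
                sums.setdefault("d_ivim", []).append(p.D)
                sums.setdefault("d_star_ivim", []).append(p.D_star)
        records.append(
            LesionRecord(
                lesion_id=lesion_id,
                label=label,
                size_mm=diam,
                summaries={k: float(np.mean(v)) for k, v in sums.items()},
            )
        )
        rows.append({"lesion_id": lesion_id, "label": label,
                     "size_mm": diam, **truth})
    return records, pd.DataFrame(rows)


def zero_dispersion(spec: PhantomSpec) -> PhantomSpec:
    """A degenerate copy of ``spec`` in which every lesion of a class has
    exactly the class-median parameters and no within-lesion jitter
    (useful for closed-loop tests)."""

    def collapse(m: ClassParamModel) -> ClassParamModel:
        q = lambda v: QuantileSpec(v, v, v)  # noqa: E731
        return ClassParamModel(
            d=q(m.d.median), beta=q(m.beta.median), mu=q(m.mu.median),
            f=q(m.f.median), d_star_median=m.d_star_median, d_star_sigma=0.0,
        )

    return replace(
        spec,
        within_lesion_cv=0.0,
        malignant_model=collapse(spec.malignant_model),
        benign_model=collapse(spec.benign_model),
    )
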