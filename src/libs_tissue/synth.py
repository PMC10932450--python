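"""Synthetic single-shot LIBS spectra calibrated to published class summaries.

The study's raw patient spectra are not public, so every pipeline stage is
exercised against a generator that emulates the four tissue classes at the
level that matters for the statistics: the per-spectrum *summed* Ca, K and
Na peak areas.  Per class and element, the summed area follows a log-normal
distribution whose median and interquartile range (IQR) are calibrated in
closed form to the published per-class summaries; each drawn sum is then
rendered as a physical-looking spectrum (Gaussian emission lines on a
constant baseline with a fixed reference peak, detector noise and a random
shot-to-shot gain) built so that the measurement pipeline — baseline
subtraction, base-peak normalization, bin integration — recovers the drawn
sums.  The generator literally inverts the measurement.

Calibration.  For a log-normal with log-location ``mu`` and log-scale
``sigma``, the median is ``exp(mu)`` and the IQR is
``2*exp(mu)*sinh(z75*sigma)`` with ``z75 = Phi^-1(0.75)``, giving the closed
form ``mu = ln(median)``, ``sigma = asinh(iqr / (2*median)) / z75``.

Truncation.  Draws are winsorized (clipped) at a high class quantile so
that no emission line can out-grow the reference peak; clipping, unlike
rejection truncation, leaves the median exactly invariant, so the published
medians survive unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .core import (
    BinCatalog,
    ConsistencyError,
    ElectrolyteFeatures,
    Spectrum,
    TissueClass,
    STUDY_CLASSES,
    ValidationError,
)

__all__ = [
    "Z75",
    "LogNormalParams",
    "calibrate_lognormal",
    "ClassModel",
    "ClassIntensityModel",
    "default_model",
    "DatasetSpec",
    "DEFAULT_COUNTS",
    "sample_spectrum",
    "generate_dataset",
    "sample_features",
    "window_response",
]

#: Standard normal upper-quartile point, ~0.6745.
Z75: float = float(stats.norm.ppf(0.75))

_ELEMENT_ORDER = ("Ca", "K", "Na")

#: Published per-class spectrum counts (sum 3049).
DEFAULT_COUNTS: dict[TissueClass, int] = {
    TissueClass.FIBROSIS: 254,
    TissueClass.NERVE: 516,
    TissueClass.TUMOR_STROMA: 821,
    TissueClass.CELL_RICH_TUMOR: 1458,
}


@dataclass(frozen=True)
class LogNormalParams:
    """Log-normal location/scale on the log-AU axis."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise ValidationError("mu must be finite")
        if not (np.isfinite(self.sigma) and self.sigma >= 0):
            raise ValidationError("sigma must be finite and >= 0")

    @property
    def median(self) -> float:
        return math.exp(self.mu)

    @property
    def iqr(self) -> float:
        return 2.0 * math.exp(self.mu) * math.sinh(Z75 * self.sigma)

    def quantile(self, q: float) -> float:
        return math.exp(self.mu + self.sigma * float(stats.norm.ppf(q)))

    def sample(
        self, rng: np.random.Generator, size: int, clip_quantile: float | None = None
    ) -> np.ndarray:
        """Draw ``size`` values; optionally winsorize at ``clip_quantile``."""
        draws = rng.lognormal(mean=self.mu, sigma=self.sigma, size=size)
        if clip_quantile is not None and clip_quantile < 1.0:
            draws = np.minimum(draws, self.quantile(clip_quantile))
        return draws


def calibrate_lognormal(median: float, iqr: float) -> LogNormalParams:
    """Closed-form (median, IQR) -> log-normal calibration.

    Inverts ``median = exp(mu)`` and ``iqr = 2*median*sinh(z75*sigma)``.
    A zero IQR would make the class degenerate and is rejected.
    """
    if median <= 0:
        raise ValidationError(f"median must be positive, got {median}")
    if iqr <= 0:
        raise ValidationError(f"iqr must be positive, got {iqr}")
    mu = math.log(median)
    sigma = math.asinh(iqr / (2.0 * median)) / Z75
    return LogNormalParams(mu=mu, sigma=sigma)


@dataclass(frozen=True)
class ClassModel:
    """Per-class electrolyte-sum distributions."""

    ca: LogNormalParams
    k: LogNormalParams
    na: LogNormalParams

    def params_for(self, element: str) -> LogNormalParams:
        try:
            return {"Ca": self.ca, "K": self.k, "Na": self.na}[element]
        except KeyError:
            raise ValidationError(f"unknown element {element!r}") from None


@dataclass
class ClassIntensityModel:
    """Everything needed to render class-labelled synthetic spectra.

    Beyond the per-class sum distributions this holds the spectral rendering
    parameters: how each element's sum is split across its bins (weight
    vectors), the emission line width, the constant spectrometer baseline,
    additive detector noise, the fixed reference peak that defines the base
    peak, the winsorization quantile and the shot-to-shot gain spread.
    """

    classes: dict[TissueClass, ClassModel]
    line_fwhm_nm: float = 3.0
    baseline_au: float = 0.02
    noise_sd_au: float = 5e-5
    reference_peak_nm: float = 800.0
    reference_height_au: float = 1.0
    truncation_quantile: float = 0.975
    gain_log_sd: float = 0.3
    # Optional per-class, per-element weight overrides; empty entry -> uniform.
    weights: dict[TissueClass, dict[str, tuple[float, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.line_fwhm_nm <= 0:
            raise ValidationError("line_fwhm_nm must be positive")
        if self.baseline_au < 0 or self.noise_sd_au < 0:
            raise ValidationError("baseline_au and noise_sd_au must be >= 0")
        if self.reference_height_au <= 0:
            raise ValidationError("reference_height_au must be positive")
        if not (0.9 < self.truncation_quantile <= 1.0):
            raise ValidationError("truncation_quantile must lie in (0.9, 1]")
        if self.gain_log_sd < 0:
            raise ValidationError("gain_log_sd must be >= 0")
        for tissue, per_element in self.weights.items():
            for element, w in per_element.items():
                arr = np.asarray(w, dtype=float)
                if np.any(arr < 0) or not math.isclose(float(arr.sum()), 1.0, rel_tol=1e-9):
                    raise ValidationError(
                        f"weights for {tissue.value}/{element} must be nonnegative and sum to 1"
                    )

    def weight_vector(self, tissue: TissueClass, element: str, n_bins: int) -> np.ndarray:
        override = self.weights.get(tissue, {}).get(element)
        if override is None:
            return np.full(n_bins, 1.0 / n_bins)
        arr = np.asarray(override, dtype=float)
        if len(arr) != n_bins:
            raise ValidationError(
                f"weights for {tissue.value}/{element}: expected length {n_bins}, got {len(arr)}"
            )
        return arr

    def to_dict(self) -> dict:
        return {
            "line_fwhm_nm": self.line_fwhm_nm,
            "baseline_au": self.baseline_au,
            "noise_sd_au": self.noise_sd_au,
            "reference_peak_nm": self.reference_peak_nm,
            "reference_height_au": self.reference_height_au,
            "truncation_quantile": self.truncation_quantile,
            "gain_log_sd": self.gain_log_sd,
            "classes": {
                tissue.value: {
                    "ca": {"median": cm.ca.median, "iqr": cm.ca.iqr},
                    "k": {"median": cm.k.median, "iqr": cm.k.iqr},
                    "na": {"median": cm.na.median, "iqr": cm.na.iqr},
                }
                for tissue, cm in self.classes.items()
            },
            "weights": {
                tissue.value: {el: list(w) for el, w in per_element.items()}
                for tissue, per_element in self.weights.items()
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ClassIntensityModel":
        classes = {}
        for name, entry in data["classes"].items():
            tissue = TissueClass(name)
            classes[tissue] = ClassModel(
                ca=calibrate_lognormal(entry["ca"]["median"], entry["ca"]["iqr"]),
                k=calibrate_lognormal(entry["k"]["median"], entry["k"]["iqr"]),
                na=calibrate_lognormal(entry["na"]["median"], entry["na"]["iqr"]),
            )
        weights = {
            TissueClass(name): {el: tuple(w) for el, w in per_element.items()}
            for name, per_element in data.get("weights", {}).items()
        }
        scalar_keys = (
            "line_fwhm_nm",
            "baseline_au",
            "noise_sd_au",
            "reference_peak_nm",
            "reference_height_au",
            "truncation_quantile",
            "gain_log_sd",
        )
        scalars = {k: float(data[k]) for k in scalar_keys if k in data}
        return cls(classes=classes, weights=weights, **scalars)


def default_model() -> ClassIntensityModel:
    """The packaged default model, calibrated to the published class table.

    Loaded from the versioned config that ships with the package (single
    source of truth shared with :func:`libs_tissue.config.default_config`).
    """
    from .config import default_config

    return default_config().model


def check_model_against_catalog(model: ClassIntensityModel, catalog: BinCatalog) -> None:
    """Raise if the reference peak sits inside any integration window."""
    for b in catalog.bins:
        if b.lo_nm <= model.reference_peak_nm <= b.hi_nm:
            raise ValidationError(
                f"reference peak at {model.reference_peak_nm} nm lies inside bin {b.label!r}"
            )


@dataclass(frozen=True)
class DatasetSpec:
    """Class counts and master seed of one synthetic dataset."""

    counts: dict[TissueClass, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    seed: int = 42

    def __post_init__(self) -> None:
        for tissue, n in self.counts.items():
            if n < 0:
                raise ValidationError(f"negative count for {tissue.value}")


_response_cache: dict = {}


def window_response(grid_wl: np.ndarray, catalog: BinCatalog, fwhm_nm: float) -> np.ndarray:
    """Discrete window-response matrix ``R[i, j]``.

    Entry (i, j) is the sum, over the grid samples inside window *i*, of a
    unit-amplitude Gaussian line centered on bin *j*.  Solving
    ``R @ amplitudes = target_areas`` makes the rendered spectrum integrate to
    the target per-bin areas exactly, cross-bin tail leakage included.
    """
    key = (grid_wl[0], grid_wl[-1], len(grid_wl), catalog.bins, fwhm_nm)
    cached = _response_cache.get(key)
    if cached is not None:
        return cached
    sigma = fwhm_nm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    n = len(catalog.bins)
    R = np.zeros((n, n))
    for i, bin_i in enumerate(catalog.bins):
        mask = (grid_wl >= bin_i.lo_nm) & (grid_wl <= bin_i.hi_nm)
        wl_in = grid_wl[mask]
        for j, bin_j in enumerate(catalog.bins):
            d = wl_in - bin_j.center_nm
            R[i, j] = np.exp(-0.5 * (d / sigma) ** 2).sum()
    _response_cache[key] = R
    return R


def _draw_sums(
    model: ClassIntensityModel, tissue: TissueClass, rng: np.random.Generator
) -> dict[str, float]:
    cm = model.classes[tissue]
    q = model.truncation_quantile
    return {
        el: float(cm.params_for(el).sample(rng, 1, clip_quantile=q)[0])
        for el in _ELEMENT_ORDER
    }


def _add_line(
    out: np.ndarray, wl: np.ndarray, center: float, sigma: float, amplitude: float
) -> None:
    lo = np.searchsorted(wl, center - 8.0 * sigma)
    hi = np.searchsorted(wl, center + 8.0 * sigma)
    d = wl[lo:hi] - center
    out[lo:hi] += amplitude * np.exp(-0.5 * (d / sigma) ** 2)


def sample_spectrum(
    model: ClassIntensityModel,
    tissue: TissueClass,
    rng: np.random.Generator,
    *,
    grid_wl: np.ndarray,
    catalog: BinCatalog,
    spectrum_id: str | None = None,
    gain: float | None = None,
) -> Spectrum:
    """Render one labelled single-shot spectrum.

    Draw order per spectrum is fixed (Ca, K, Na sums; then noise; then gain)
    so that a given generator stream is reproducible.  The drawn target sums
    and gain are recorded in ``meta`` for ground-truth checks.
    """
    if tissue not in model.classes:
        raise ValidationError(f"model has no class {tissue!r}")
    check_model_against_catalog(model, catalog)
    sums = _draw_sums(model, tissue, rng)

    # Per-bin target areas: element sum split by the class weight vector.
    targets = np.zeros(len(catalog.bins))
    label_index = {label: i for i, label in enumerate(catalog.labels)}
    for element in _ELEMENT_ORDER:
        bins = catalog.bins_for(element)
        if not bins:
            continue
        w = model.weight_vector(tissue, element, len(bins))
        for b, wt in zip(bins, w):
            targets[label_index[b.label]] = sums[element] * wt

    R = window_response(grid_wl, catalog, model.line_fwhm_nm)
    amplitudes = np.linalg.solve(R, targets)
    if np.any(amplitudes >= model.reference_height_au):
        raise ConsistencyError(
            f"{tissue.value}: an emission line ({amplitudes.max():.3f} AU) would reach the "
            f"reference-peak height {model.reference_height_au}; lower the truncation "
            "quantile or broaden the lines"
        )
    if np.any(amplitudes < -1e-9):
        raise ConsistencyError("window-response solve produced a negative amplitude")
    amplitudes = np.clip(amplitudes, 0.0, None)

    sigma = model.line_fwhm_nm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    intensity = np.full(len(grid_wl), model.baseline_au)
    for j, b in enumerate(catalog.bins):
        if amplitudes[j] > 0:
            _add_line(intensity, grid_wl, b.center_nm, sigma, amplitudes[j])
    _add_line(intensity, grid_wl, model.reference_peak_nm, sigma, model.reference_height_au)
    if model.noise_sd_au > 0:
        intensity = intensity + rng.normal(0.0, model.noise_sd_au, len(grid_wl))
    else:
        rng.normal(0.0, 1.0, len(grid_wl))  # keep the stream position fixed
    if gain is None:
        gain = float(np.exp(rng.normal(0.0, model.gain_log_sd))) if model.gain_log_sd > 0 else 1.0
    elif gain <= 0:
        raise ValidationError("gain must be positive")
    intensity = np.clip(gain * intensity, 0.0, None)

    return Spectrum(
        id=spectrum_id or f"{tissue.value}-0",
        wavelengths=grid_wl.copy(),
        intensities=intensity,
        tissue=tissue,
        meta={
            "target_ca_sum": sums["Ca"],
            "target_k_sum": sums["K"],
            "target_na_sum": sums["Na"],
            "gain": gain,
        },
    )


def generate_dataset(
    model: ClassIntensityModel,
    spec: DatasetSpec,
    *,
    grid_wl: np.ndarray,
    catalog: BinCatalog,
) -> list[Spectrum]:
    """Generate an independent labelled dataset, reproducible from the seed.

    Each tissue class gets its own child random stream (spawned in fixed
    enum order), so changing one class count never perturbs the spectra of
    another class.
    """
    children = np.random.SeedSequence(spec.seed).spawn(len(TissueClass))
    spectra: list[Spectrum] = []
    for cls, child in zip(TissueClass, children):
        n = spec.counts.get(cls, 0)
        if n == 0:
            continue
        rng = np.random.default_rng(child)
        for i in range(n):
            spectra.append(
                sample_spectrum(
                    model,
                    cls,
                    rng,
                    grid_wl=grid_wl,
                    catalog=catalog,
                    spectrum_id=f"{cls.value}-{i:05d}",
                )
            )
    return spectra


def sample_features(
    model: ClassIntensityModel,
    counts: dict[TissueClass, int],
    seed: int,
) -> list[ElectrolyteFeatures]:
    """Draw electrolyte sums directly from the class model, skipping rendering.

    Distributionally identical to running the full generate -> preprocess ->
    integrate -> sum pipeline up to the (sub-0.1%) baseline/noise residuals;
    used where many seeds must be swept cheaply.  Uses the same
    per-class child-stream layout as :func:`generate_dataset`.
    """
    children = np.random.SeedSequence(seed).spawn(len(TissueClass))
    q = model.truncation_quantile
    out: list[ElectrolyteFeatures] = []
    for cls, child in zip(TissueClass, children):
        n = counts.get(cls, 0)
        if n == 0:
            continue
        rng = np.random.default_rng(child)
        cm = model.classes[cls]
        ca = cm.ca.sample(rng, n, clip_quantile=q)
        k = cm.k.sample(rng, n, clip_quantile=q)
        na = cm.na.sample(rng, n, clip_quantile=q)
        for i in range(n):
            out.append(
                ElectrolyteFeatures(
                    spectrum_id=f"{cls.value}-{i:05d}",
                    ca_sum=float(ca[i]),
                    k_sum=float(k[i]),
                    na_sum=float(na[i]),
                    tissue=cls,
                )
            )
    return out
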