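"""Spectrum processing: baseline subtraction, base-peak normalization, bin areas.

The processing chain mirrors standard single-shot LIBS practice: remove the
constant spectrometer baseline, normalize to the tallest feature (the "base
peak") so that shot-to-shot gain cancels, then integrate each catalog window
into a peak area.  Areas are discrete sample sums of the normalized
intensity (no wavelength-step factor): with a unit base peak, a sample-sum
over a ~2 nm window is the only convention under which the published
double-digit AU magnitudes are reachable, and AU are dimensionless either
way.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import (
    BinCatalog,
    PeakAreaVector,
    Spectrum,
    TissueClass,
    ValidationError,
    validate_against_catalog,
)

__all__ = [
    "DEFAULT_REFERENCE_WINDOW",
    "subtract_baseline",
    "normalize_base_peak",
    "integrate_bins",
    "preprocess_all",
    "select_representative",
]

log = logging.getLogger(__name__)

#: Wavelength window (nm) around the synthetic reference peak, excluded from
#: baseline estimation alongside the catalog windows.
DEFAULT_REFERENCE_WINDOW: tuple[float, float] = (795.0, 805.0)


def _out_of_window_mask(
    wl: np.ndarray,
    catalog: BinCatalog,
    exclude_windows: tuple[tuple[float, float], ...],
) -> np.ndarray:
    mask = np.ones(len(wl), dtype=bool)
    for lo, hi in [b.window for b in catalog.bins] + list(exclude_windows):
        mask &= ~((wl >= lo) & (wl <= hi))
    return mask


def subtract_baseline(
    spectrum: Spectrum,
    catalog: BinCatalog,
    *,
    percentile: float = 5.0,
    exclude_windows: tuple[tuple[float, float], ...] = (DEFAULT_REFERENCE_WINDOW,),
) -> Spectrum:
    """Remove a constant per-spectrum baseline; clip resulting negatives to 0.

    The baseline is the given low percentile (default 5th) of the intensities
    at samples outside every catalog window and outside ``exclude_windows``
    (by default the reference-peak region): a simple, robust estimate of the
    signal-free floor.
    """
    mask = _out_of_window_mask(spectrum.wavelengths, catalog, exclude_windows)
    if not mask.any():
        raise ValidationError(
            f"spectrum {spectrum.id!r}: no samples outside the catalog windows "
            "to estimate a baseline from"
        )
    baseline = float(np.percentile(spectrum.intensities[mask], percentile))
    cleaned = np.clip(spectrum.intensities - baseline, 0.0, None)
    return spectrum.with_intensities(cleaned, baseline_au=baseline)


def normalize_base_peak(spectrum: Spectrum) -> Spectrum:
    """Divide by the maximum intensity so the base peak equals exactly 1.

    Idempotent, and invariant under any positive gain applied upstream.
    """
    peak = float(spectrum.intensities.max())
    if peak <= 0:
        raise ValidationError(f"spectrum {spectrum.id!r}: no base peak (all intensities zero)")
    return spectrum.with_intensities(spectrum.intensities / peak, base_peak_au=peak)


def integrate_bins(spectrum: Spectrum, catalog: BinCatalog, *, normalized: bool = True) -> PeakAreaVector:
    """Peak area per bin: sum of intensities at grid samples inside the closed window."""
    if not validate_against_catalog(spectrum, catalog):
        raise ValidationError(
            f"spectrum {spectrum.id!r}: grid does not cover the catalog windows"
        )
    wl = spectrum.wavelengths
    areas = {}
    for b in catalog.bins:
        inside = (wl >= b.lo_nm) & (wl <= b.hi_nm)
        areas[b.label] = float(spectrum.intensities[inside].sum())
    return PeakAreaVector(
        spectrum_id=spectrum.id, areas=areas, normalized=normalized, tissue=spectrum.tissue
    )


def preprocess_all(
    spectra: list[Spectrum],
    catalog: BinCatalog,
    *,
    percentile: float = 5.0,
    exclude_windows: tuple[tuple[float, float], ...] = (DEFAULT_REFERENCE_WINDOW,),
) -> list[PeakAreaVector]:
    """Run subtract -> normalize -> integrate over a collection, skipping failures.

    Per-spectrum failures (e.g. an all-zero record) are logged and skipped;
    the call fails only if the collection is empty or nothing survives.
    """
    if not spectra:
        raise ValidationError("empty spectrum collection")
    out: list[PeakAreaVector] = []
    skipped = 0
    for s in spectra:
        try:
            cleaned = subtract_baseline(
                s, catalog, percentile=percentile, exclude_windows=exclude_windows
            )
            normalized = normalize_base_peak(cleaned)
            out.append(integrate_bins(normalized, catalog))
        except ValidationError as exc:
            skipped += 1
            log.warning("skipping spectrum %r: %s", s.id, exc)
    if not out:
        raise ValidationError(f"all {len(spectra)} spectra failed preprocessing")
    if skipped:
        log.info("preprocessed %d spectra, skipped %d", len(out), skipped)
    return out


def select_representative(
    vectors: list[PeakAreaVector], k: int
) -> dict[TissueClass, list[PeakAreaVector]]:
    """Per tissue class, the k vectors closest to the class median profile.

    "Representative" is read as nearest (Euclidean, over all bins) to the
    per-class median peak-area vector; ties break deterministically by
    distance then lexical spectrum id.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    by_class: dict[TissueClass, list[PeakAreaVector]] = {}
    for v in vectors:
        if v.tissue is None:
            raise ValidationError(f"spectrum {v.spectrum_id!r} is unlabelled")
        by_class.setdefault(v.tissue, []).append(v)
    out: dict[TissueClass, list[PeakAreaVector]] = {}
    for tissue, members in by_class.items():
        if k > len(members):
            raise ValidationError(
                f"k={k} exceeds class size {len(members)} for {tissue.value}"
            )
        labels = tuple(sorted(members[0].areas))
        X = np.vstack([m.as_array(labels) for m in members])
        median = np.median(X, axis=0)
        dist = np.sqrt(((X - median) ** 2).sum(axis=1))
        order = sorted(range(len(members)), key=lambda i: (dist[i], members[i].spectrum_id))
        out[tissue] = [members[i] for i in order[:k]]
    return out
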