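"""Core domain model: tissue classes, single-shot spectra, emission-line bins.

Laser-induced breakdown spectroscopy (LIBS) turns each laser pulse into one
optical emission spectrum of the micro-plasma at the laser spot.  Tissue
discrimination in bone-infiltrating head and neck cancer works on narrow
wavelength windows ("bins") around Ca-, K- and Na-associated emission
features; every downstream statistic consumes either per-bin peak areas or
their per-element sums.  This module holds the shared value types and the
default bin catalog.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import yaml

__all__ = [
    "LibsTissueError",
    "SpectraParseError",
    "ValidationError",
    "ConsistencyError",
    "TissueClass",
    "STUDY_CLASSES",
    "REFERENCE_CLASSES",
    "parse_tissue",
    "EmissionBin",
    "BinCatalog",
    "default_catalog",
    "Spectrum",
    "PeakAreaVector",
    "ElectrolyteFeatures",
    "validate_against_catalog",
    "CA_CENTERS_NM",
    "K_CENTERS_NM",
    "NA_CENTERS_NM",
]


class LibsTissueError(Exception):
    """Base class for all errors raised by this package."""


class SpectraParseError(LibsTissueError):
    """A spectra table could not be parsed."""


class ValidationError(LibsTissueError):
    """An input violates a documented invariant."""


class ConsistencyError(LibsTissueError):
    """An internal contract was violated (indicates a bug or bad config)."""


class TissueClass(str, Enum):
    """Histologically validated tissue classes.

    The four study classes come from mandible cross-sections of
    bone-infiltrating head and neck cancer; the two ``*_ref`` classes stand in
    for previously published healthy-bone / bone-infiltrating-tumor spectra
    and are used only to anchor ("fix") the PCA axes.
    """

    FIBROSIS = "fibrosis"
    NERVE = "nerve"
    TUMOR_STROMA = "tumor_stroma"
    CELL_RICH_TUMOR = "cell_rich_tumor"
    HEALTHY_BONE_REF = "healthy_bone_ref"
    TUMOR_REF = "tumor_ref"


STUDY_CLASSES: tuple[TissueClass, ...] = (
    TissueClass.FIBROSIS,
    TissueClass.NERVE,
    TissueClass.TUMOR_STROMA,
    TissueClass.CELL_RICH_TUMOR,
)

REFERENCE_CLASSES: tuple[TissueClass, ...] = (
    TissueClass.HEALTHY_BONE_REF,
    TissueClass.TUMOR_REF,
)

# Alias table: free-text labels seen in the field -> canonical class.
_TISSUE_ALIASES: dict[str, TissueClass] = {
    "nerve_tissue": TissueClass.NERVE,
    "inferior_alveolar_nerve": TissueClass.NERVE,
    "cell_rich_tumor_areas": TissueClass.CELL_RICH_TUMOR,
    "cell_rich": TissueClass.CELL_RICH_TUMOR,
    "stroma": TissueClass.TUMOR_STROMA,
    "healthy_bone": TissueClass.HEALTHY_BONE_REF,
    "tumor_tissue": TissueClass.TUMOR_REF,
}


def parse_tissue(text: str) -> TissueClass:
    """Parse a tissue label case-insensitively, accepting common aliases.

    Hyphens and spaces are treated as underscores, so ``"Cell-rich tumor"``
    maps to :attr:`TissueClass.CELL_RICH_TUMOR`.  Unknown labels raise
    :class:`ValidationError`.
    """
    key = text.strip().lower().replace("-", "_").replace(" ", "_")
    for cls in TissueClass:
        if key == cls.value:
            return cls
    if key in _TISSUE_ALIASES:
        return _TISSUE_ALIASES[key]
    raise ValidationError(f"unknown tissue label: {text!r}")


# The 15 discriminative / tracked emission wavelengths (nm).  The Ca entries
# are CaO/CaOH molecular band heads; K and Na are atomic doublet lines.
CA_CENTERS_NM: tuple[float, ...] = (
    547.89, 554.52, 560.01, 596.05, 604.21, 610.08,
    616.66, 625.88, 635.58, 643.38, 650.8,
)
K_CENTERS_NM: tuple[float, ...] = (765.86, 770.76)
NA_CENTERS_NM: tuple[float, ...] = (589.14, 819.42)

_ELEMENTS = ("Ca", "K", "Na", "other")


@dataclass(frozen=True)
class EmissionBin:
    """A labelled integration window around one emission feature."""

    label: str
    element: str
    center_nm: float
    lo_nm: float
    hi_nm: float

    def __post_init__(self) -> None:
        if self.element not in _ELEMENTS:
            raise ValidationError(
                f"bin {self.label!r}: element must be one of {_ELEMENTS}, got {self.element!r}"
            )
        if not (self.lo_nm < self.center_nm < self.hi_nm):
            raise ValidationError(
                f"bin {self.label!r}: require lo < center < hi, got "
                f"({self.lo_nm}, {self.center_nm}, {self.hi_nm})"
            )

    @property
    def window(self) -> tuple[float, float]:
        return (self.lo_nm, self.hi_nm)


@dataclass(frozen=True)
class BinCatalog:
    """An ordered collection of pairwise-disjoint emission bins."""

    bins: tuple[EmissionBin, ...]

    def __post_init__(self) -> None:
        if not self.bins:
            raise ValidationError("catalog must contain at least one bin")
        labels = [b.label for b in self.bins]
        if len(set(labels)) != len(labels):
            raise ValidationError("bin labels must be unique")
        ordered = sorted(self.bins, key=lambda b: b.lo_nm)
        for a, b in zip(ordered, ordered[1:]):
            if b.lo_nm <= a.hi_nm:  # closed windows: touching counts as overlap
                raise ValidationError(
                    f"bins {a.label!r} and {b.label!r} overlap: "
                    f"[{a.lo_nm}, {a.hi_nm}] vs [{b.lo_nm}, {b.hi_nm}]"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(b.label for b in self.bins)

    def bins_for(self, element: str) -> tuple[EmissionBin, ...]:
        return tuple(b for b in self.bins if b.element == element)

    def labels_for(self, element: str) -> tuple[str, ...]:
        return tuple(b.label for b in self.bins if b.element == element)

    @property
    def discriminative_labels(self) -> tuple[str, ...]:
        """Labels of the Ca and K bins (catalog order) — the PCA feature set."""
        return self.labels_for("Ca") + self.labels_for("K")

    def __len__(self) -> int:
        return len(self.bins)

    def __getitem__(self, label: str) -> EmissionBin:
        for b in self.bins:
            if b.label == label:
                return b
        raise KeyError(label)

    def to_dict(self) -> dict:
        return {
            "bins": [
                {
                    "label": b.label,
                    "element": b.element,
                    "center_nm": b.center_nm,
                    "lo_nm": b.lo_nm,
                    "hi_nm": b.hi_nm,
                }
                for b in self.bins
            ]
        }

    @classmethod
    def from_dict(cls, data: dict) -> "BinCatalog":
        return cls(bins=tuple(EmissionBin(**entry) for entry in data["bins"]))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "BinCatalog":
        return cls.from_dict(yaml.safe_load(text))


def default_catalog(half_width_nm: float = 1.0) -> BinCatalog:
    """The default 15-bin catalog: 11 Ca, 2 K and 2 Na windows.

    Windows are symmetric ``center +/- half_width_nm``.  The default 1 nm
    half-width keeps all 15 windows disjoint (closest centers are 4.90 nm
    apart) and is configurable because the instrument bin boundaries are not
    standardised.
    """
    if half_width_nm <= 0:
        raise ValidationError("half_width_nm must be positive")
    bins = []
    for element, centers in (("Ca", CA_CENTERS_NM), ("K", K_CENTERS_NM), ("Na", NA_CENTERS_NM)):
        for c in centers:
            bins.append(
                EmissionBin(
                    label=f"{element}_{c:g}",
                    element=element,
                    center_nm=c,
                    lo_nm=round(c - half_width_nm, 6),
                    hi_nm=round(c + half_width_nm, 6),
                )
            )
    return BinCatalog(bins=tuple(bins))


@dataclass(eq=False)
class Spectrum:
    """One single-shot LIBS record on a uniform wavelength grid.

    Spectra are deliberately not averaged: one laser shot yields one
    ``Spectrum``, preserving the natural shot-to-shot inhomogeneity of the
    tissue.
    """

    id: str
    wavelengths: np.ndarray
    intensities: np.ndarray
    tissue: TissueClass | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.ndim != 1 or self.intensities.ndim != 1:
            raise ValidationError(f"spectrum {self.id!r}: expected 1-D arrays")
        if len(self.wavelengths) != len(self.intensities):
            raise ValidationError(
                f"spectrum {self.id!r}: {len(self.wavelengths)} wavelengths vs "
                f"{len(self.intensities)} intensities"
            )
        if len(self.wavelengths) < 2:
            raise ValidationError(f"spectrum {self.id!r}: need at least 2 samples")
        steps = np.diff(self.wavelengths)
        if np.any(steps <= 0):
            raise ValidationError(f"spectrum {self.id!r}: wavelengths must be strictly increasing")
        step = steps.mean()
        if not np.allclose(steps, step, rtol=1e-9, atol=1e-9 * step):
            raise ValidationError(f"spectrum {self.id!r}: wavelength grid is not uniform")
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError(f"spectrum {self.id!r}: non-finite intensity")
        if np.any(self.intensities < 0):
            raise ValidationError(f"spectrum {self.id!r}: negative intensity")

    @property
    def step_nm(self) -> float:
        return float(np.diff(self.wavelengths).mean())

    def __len__(self) -> int:
        return len(self.wavelengths)

    def with_intensities(self, intensities: np.ndarray, **meta_updates) -> "Spectrum":
        """Copy with replaced intensities (grid, label and id are kept)."""
        return Spectrum(
            id=self.id,
            wavelengths=self.wavelengths.copy(),
            intensities=np.asarray(intensities, dtype=float),
            tissue=self.tissue,
            meta={**self.meta, **meta_updates},
        )

    def allclose(self, other: "Spectrum", rtol: float = 1e-9, atol: float = 0.0) -> bool:
        return (
            self.id == other.id
            and self.tissue == other.tissue
            and len(self) == len(other)
            and bool(np.allclose(self.wavelengths, other.wavelengths, rtol=rtol, atol=atol))
            and bool(np.allclose(self.intensities, other.intensities, rtol=rtol, atol=atol))
        )


@dataclass
class PeakAreaVector:
    """Per-bin peak areas (AU) measured from one preprocessed spectrum."""

    spectrum_id: str
    areas: dict[str, float]
    normalized: bool
    tissue: TissueClass | None = None

    def __post_init__(self) -> None:
        for label, value in self.areas.items():
            if not np.isfinite(value) or value < 0:
                raise ValidationError(
                    f"spectrum {self.spectrum_id!r}: invalid area {value!r} for bin {label!r}"
                )

    def as_array(self, labels: tuple[str, ...]) -> np.ndarray:
        try:
            return np.array([self.areas[label] for label in labels], dtype=float)
        except KeyError as exc:
            raise ValidationError(
                f"spectrum {self.spectrum_id!r}: missing bin {exc.args[0]!r}"
            ) from exc


@dataclass
class ElectrolyteFeatures:
    """Summed Ca/K/Na peak areas of one spectrum — the scalar biomarkers."""

    spectrum_id: str
    ca_sum: float
    k_sum: float
    na_sum: float
    tissue: TissueClass | None = None

    def value(self, element: str) -> float:
        try:
            return {"Ca": self.ca_sum, "K": self.k_sum, "Na": self.na_sum}[element]
        except KeyError:
            raise ValidationError(f"unknown element {element!r}") from None


def validate_against_catalog(
    spectrum: Spectrum, catalog: BinCatalog, min_samples: int = 5
) -> bool:
    """True iff the grid covers every window with at least ``min_samples`` samples.

    Pure predicate: extending the grid or refining the step can never flip the
    result from True to False.
    """
    wl = spectrum.wavelengths
    for b in catalog.bins:
        if b.lo_nm < wl[0] or b.hi_nm > wl[-1]:
            return False
        inside = np.count_nonzero((wl >= b.lo_nm) & (wl <= b.hi_nm))
        if inside < min_samples:
            return False
    return True
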