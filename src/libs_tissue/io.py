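"""Reading and writing the package's plain-text table formats.

Three CSV layouts are used throughout:

* spectra — long format, one row per (spectrum, wavelength) sample with
  columns ``spectrum_id,tissue,wavelength_nm,intensity``;
* areas — wide format, one row per spectrum with one column per bin label;
* features — one row per spectrum with the three electrolyte sums.

All files are UTF-8, comma-delimited, ``.`` decimal separator.  Writers are
deterministic: fixed row order and fixed numeric formatting, so writing the
same data twice yields byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    BinCatalog,
    ElectrolyteFeatures,
    PeakAreaVector,
    SpectraParseError,
    Spectrum,
    TissueClass,
    ValidationError,
    parse_tissue,
    validate_against_catalog,
)

__all__ = [
    "read_spectra",
    "write_spectra",
    "areas_to_frame",
    "frame_to_areas",
    "write_areas",
    "read_areas",
    "features_to_frame",
    "frame_to_features",
    "write_features",
    "read_features",
]

SPECTRA_COLUMNS = ("spectrum_id", "tissue", "wavelength_nm", "intensity")

# Fixed decimal formatting for spectra files: wavelengths to 4 decimals,
# intensities to 6 significant digits.
_WL_FMT = "%.4f"
_INT_FMT = "%.6g"


def _parse_numeric(df: pd.DataFrame, column: str) -> np.ndarray:
    values = pd.to_numeric(df[column], errors="coerce")
    bad = values.isna()
    if bad.any():
        line = int(df.index[bad][0]) + 2  # +1 header, +1 zero-based
        raise SpectraParseError(
            f"non-numeric value {df[column].iloc[int(df.index[bad][0])]!r} "
            f"in column {column!r} at line {line}"
        )
    return values.to_numpy(dtype=float)


def read_spectra(path: str | Path, catalog: BinCatalog | None = None) -> list[Spectrum]:
    """Read a long-format spectra CSV into a list of :class:`Spectrum`.

    Rows are grouped by ``spectrum_id`` and sorted by wavelength, so the file
    row order does not matter.  An optional catalog triggers a coverage check
    on every spectrum.  Parse problems raise :class:`SpectraParseError` naming
    the offending column or line.
    """
    path = Path(path)
    if not path.exists():
        raise SpectraParseError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SPECTRA_COLUMNS if c not in df.columns]
    if missing:
        raise SpectraParseError(f"missing column(s) {missing} in {path}")
    if df.empty:
        raise SpectraParseError(f"no data rows in {path}")
    wl = _parse_numeric(df, "wavelength_nm")
    inten = _parse_numeric(df, "intensity")
    work = pd.DataFrame(
        {
            "spectrum_id": df["spectrum_id"],
            "tissue": df["tissue"].str.strip(),
            "wavelength_nm": wl,
            "intensity": inten,
        }
    )
    spectra: list[Spectrum] = []
    for sid, group in work.groupby("spectrum_id", sort=True):
        group = group.sort_values("wavelength_nm", kind="mergesort")
        tissues = {t for t in group["tissue"] if t}
        if len(tissues) > 1:
            raise SpectraParseError(f"spectrum {sid!r}: conflicting tissue labels {sorted(tissues)}")
        tissue = parse_tissue(tissues.pop()) if tissues else None
        try:
            spectrum = Spectrum(
                id=str(sid),
                wavelengths=group["wavelength_nm"].to_numpy(),
                intensities=group["intensity"].to_numpy(),
                tissue=tissue,
            )
        except ValidationError as exc:
            raise SpectraParseError(f"while reading {path}: {exc}") from exc
        if catalog is not None and not validate_against_catalog(spectrum, catalog):
            raise ValidationError(
                f"spectrum {sid!r}: wavelength grid does not cover the catalog windows"
            )
        spectra.append(spectrum)
    return spectra


def write_spectra(spectra: list[Spectrum], path: str | Path) -> Path:
    """Write spectra to a long-format CSV with deterministic order and formatting."""
    if not spectra:
        raise ValidationError("cannot write an empty spectrum collection")
    path = Path(path)
    ordered = sorted(spectra, key=lambda s: s.id)
    ids = np.concatenate([np.full(len(s), s.id, dtype=object) for s in ordered])
    tissues = np.concatenate(
        [np.full(len(s), s.tissue.value if s.tissue else "", dtype=object) for s in ordered]
    )
    wl = np.concatenate([s.wavelengths for s in ordered])
    inten = np.concatenate([s.intensities for s in ordered])
    frame = pd.DataFrame(
        {
            "spectrum_id": ids,
            "tissue": tissues,
            "wavelength_nm": np.char.mod(_WL_FMT, wl),
            "intensity": np.char.mod(_INT_FMT, inten),
        }
    )
    frame.to_csv(path, index=False, lineterminator="\n")
    return path


def _tissue_column(items) -> list[str]:
    return [x.tissue.value if x.tissue else "" for x in items]


def areas_to_frame(vectors: list[PeakAreaVector], catalog: BinCatalog) -> pd.DataFrame:
    """One row per spectrum, one column per bin label (catalog order)."""
    if not vectors:
        raise ValidationError("empty peak-area collection")
    data = {
        "spectrum_id": [v.spectrum_id for v in vectors],
        "tissue": _tissue_column(vectors),
    }
    for label in catalog.labels:
        data[label] = [v.as_array((label,))[0] for v in vectors]
    return pd.DataFrame(data)


def frame_to_areas(
    df: pd.DataFrame, catalog: BinCatalog, normalized: bool = True
) -> list[PeakAreaVector]:
    missing = [c for c in ("spectrum_id", *catalog.labels) if c not in df.columns]
    if missing:
        raise SpectraParseError(f"areas table is missing column(s) {missing}")
    vectors = []
    for _, row in df.iterrows():
        tissue = parse_tissue(str(row["tissue"])) if str(row.get("tissue", "")).strip() else None
        vectors.append(
            PeakAreaVector(
                spectrum_id=str(row["spectrum_id"]),
                areas={label: float(row[label]) for label in catalog.labels},
                normalized=normalized,
                tissue=tissue,
            )
        )
    return vectors


def write_areas(vectors: list[PeakAreaVector], catalog: BinCatalog, path: str | Path) -> Path:
    path = Path(path)
    areas_to_frame(vectors, catalog).to_csv(
        path, index=False, float_format="%.9g", lineterminator="\n"
    )
    return path


def read_areas(path: str | Path, catalog: BinCatalog) -> list[PeakAreaVector]:
    return frame_to_areas(pd.read_csv(Path(path), keep_default_na=False), catalog)


def features_to_frame(features: list[ElectrolyteFeatures]) -> pd.DataFrame:
    if not features:
        raise ValidationError("empty feature collection")
    return pd.DataFrame(
        {
            "spectrum_id": [f.spectrum_id for f in features],
            "tissue": _tissue_column(features),
            "ca_sum": [f.ca_sum for f in features],
            "k_sum": [f.k_sum for f in features],
            "na_sum": [f.na_sum for f in features],
        }
    )


def frame_to_features(df: pd.DataFrame) -> list[ElectrolyteFeatures]:
    required = ("spectrum_id", "ca_sum", "k_sum", "na_sum")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SpectraParseError(f"features table is missing column(s) {missing}")
    out = []
    for _, row in df.iterrows():
        tissue = parse_tissue(str(row["tissue"])) if str(row.get("tissue", "")).strip() else None
        out.append(
            ElectrolyteFeatures(
                spectrum_id=str(row["spectrum_id"]),
                ca_sum=float(row["ca_sum"]),
                k_sum=float(row["k_sum"]),
                na_sum=float(row["na_sum"]),
                tissue=tissue,
            )
        )
    return out


def write_features(features: list[ElectrolyteFeatures], path: str | Path) -> Path:
    path = Path(path)
    features_to_frame(features).to_csv(
        path, index=False, float_format="%.9g", lineterminator="\n"
    )
    return path


def read_features(path: str | Path) -> list[ElectrolyteFeatures]:
    return frame_to_features(pd.read_csv(Path(path), keep_default_na=False))
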