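"""Collapse per-bin peak areas into the three electrolyte sums.

Every downstream statistic — the class summaries, the rank tests, the ROC
curves and the metric scales — operates on the per-spectrum sums of the
Ca-, K- and Na-tagged bin areas.  Element tags live on the catalog, the
single source of truth; nothing here hard-codes a wavelength.
"""

from __future__ import annotations

from .core import BinCatalog, ElectrolyteFeatures, PeakAreaVector, ValidationError

__all__ = ["electrolyte_sums", "features_table"]


def electrolyte_sums(vector: PeakAreaVector, catalog: BinCatalog) -> ElectrolyteFeatures:
    """Sum the Ca / K / Na bin areas of one spectrum; ``other`` bins are ignored."""
    missing = [label for label in catalog.labels if label not in vector.areas]
    if missing:
        raise ValidationError(
            f"spectrum {vector.spectrum_id!r}: missing bin area(s) {missing}"
        )
    sums = {}
    for element in ("Ca", "K", "Na"):
        sums[element] = float(sum(vector.areas[label] for label in catalog.labels_for(element)))
    return ElectrolyteFeatures(
        spectrum_id=vector.spectrum_id,
        ca_sum=sums["Ca"],
        k_sum=sums["K"],
        na_sum=sums["Na"],
        tissue=vector.tissue,
    )


def features_table(
    vectors: list[PeakAreaVector], catalog: BinCatalog
) -> list[ElectrolyteFeatures]:
    """Order-preserving map of :func:`electrolyte_sums` over a collection."""
    if not vectors:
        raise ValidationError("empty peak-area collection")
    return [electrolyte_sums(v, catalog) for v in vectors]
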