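"""PCA on the 13 discriminative Ca + K bin areas, with reference fixation.

The scatter of spectra in the 13-dimensional peak-area space is visualised
through the first two principal components.  PCA is covariance-based
(mean-centred, unscaled) by default: unit-scaling every bin would flatten
exactly the element dominance the loadings are meant to reveal.  "Fixation"
by reference spectra means the previously characterised healthy-bone and
tumor reference classes are included in the fitting set, so the axes are
anchored by known anatomy rather than floating on the study classes alone.
Components follow a deterministic sign convention: the largest-magnitude
loading of each component is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core import (
    BinCatalog,
    PeakAreaVector,
    REFERENCE_CLASSES,
    ValidationError,
)

__all__ = ["PcaModel", "fit_pca", "project", "loading_report"]


@dataclass
class PcaModel:
    """Fitted PCA: centering (and optional scaling), loadings, variance shares."""

    labels: tuple[str, ...]
    mean: np.ndarray
    components: np.ndarray  # (n_components, n_bins)
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    scale: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def _matrix(vectors: list[PeakAreaVector], labels: tuple[str, ...]) -> np.ndarray:
    return np.vstack([v.as_array(labels) for v in vectors])


def fit_pca(
    vectors: list[PeakAreaVector],
    catalog: BinCatalog,
    *,
    include_reference: bool = True,
    standardize: bool = False,
) -> PcaModel:
    """Fit PCA on the Ca + K bins of a peak-area collection.

    ``include_reference=False`` drops reference-class vectors from the fit
    (they can still be projected afterwards).  ``standardize=True`` switches
    to correlation-style PCA (per-bin unit variance); the covariance default
    is documented above.
    """
    labels = catalog.discriminative_labels
    if len(labels) < 2:
        raise ValidationError("catalog has fewer than 2 Ca/K bins")
    fit_vectors = (
        vectors
        if include_reference
        else [v for v in vectors if v.tissue not in REFERENCE_CLASSES]
    )
    if len(fit_vectors) < 3:
        raise ValidationError(f"need at least 3 vectors to fit, got {len(fit_vectors)}")
    X = _matrix(fit_vectors, labels)
    scale = None
    if standardize:
        scale = X.std(axis=0, ddof=1)
        if np.any(scale == 0):
            raise ValidationError("cannot standardize: a bin has zero variance")
        X = X / scale
    if float(((X - X.mean(axis=0)) ** 2).sum()) <= 1e-24:
        raise ValidationError("peak-area matrix has no variance; PCA is undefined")
    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(X)
    components = pca.components_.copy()
    for row in components:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1.0
    return PcaModel(
        labels=labels,
        mean=pca.mean_.copy(),
        components=components,
        explained_variance=pca.explained_variance_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        scale=scale,
    )


def project(model: PcaModel, vectors: list[PeakAreaVector]) -> pd.DataFrame:
    """Score table: spectrum id, tissue label, and PC1..PCk coordinates."""
    if not vectors:
        raise ValidationError("nothing to project")
    X = _matrix(vectors, model.labels)
    if model.scale is not None:
        X = X / model.scale
    scores = (X - model.mean) @ model.components.T
    frame = pd.DataFrame(
        {
            "spectrum_id": [v.spectrum_id for v in vectors],
            "tissue": [v.tissue.value if v.tissue else "" for v in vectors],
        }
    )
    for k in range(model.n_components):
        frame[f"PC{k + 1}"] = scores[:, k]
    return frame


def loading_report(model: PcaModel) -> pd.DataFrame:
    """Bins ranked by absolute loading within each component."""
    rows = []
    for k in range(model.n_components):
        loadings = model.components[k]
        order = sorted(range(len(model.labels)), key=lambda i: (-abs(loadings[i]), model.labels[i]))
        for rank, i in enumerate(order, start=1):
            rows.append(
                {
                    "component": k + 1,
                    "rank": rank,
                    "bin": model.labels[i],
                    "loading": float(loadings[i]),
                    "explained_variance_ratio": float(model.explained_variance_ratio[k]),
                }
            )
    return pd.DataFrame(rows)
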