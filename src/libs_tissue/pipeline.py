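"""End-to-end orchestration: simulate -> preprocess -> features -> statistics.

``run_pipeline`` chains every stage under one seed and writes a reproducible
report bundle: the simulated spectra and intermediate tables as CSV, the
class summaries / pairwise tests / ROC rows / metric scales / PCA outputs as
JSON, plus a manifest pinning the configuration hash and library versions.
Identical config + seed always yields an identical bundle.
"""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from pathlib import Path

from .config import PipelineConfig
from .core import REFERENCE_CLASSES, STUDY_CLASSES, LibsTissueError
from .features import features_table
from .io import write_areas, write_features, write_spectra
from .pca import fit_pca, loading_report, project
from .preprocess import preprocess_all, select_representative
from .roc import build_metric_scale, pairwise_roc_report
from .stats import dunn_posthoc, kruskal_wallis, summarize_groups
from .synth import DatasetSpec, generate_dataset, sample_features  # noqa: F401  (re-export)

log = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


@contextmanager
def _stage(name: str):
    """Re-raise stage failures with the stage name attached."""
    try:
        yield
    except LibsTissueError as exc:
        raise LibsTissueError(f"pipeline stage {name!r} failed: {exc}") from exc


def _grouped_values(features, element):
    out = {}
    for f in features:
        out.setdefault(f.tissue, []).append(f.value(element))
    return out


def run_pipeline(
    config: PipelineConfig,
    seed: int,
    out_dir: str | Path,
    *,
    write_spectra_csv: bool = True,
) -> dict:
    """Run the whole analysis once; returns the bundle as a dict of objects.

    Reference-class spectra (``config.pca_reference_count`` each) are
    generated alongside the study classes for PCA fixation but are excluded
    from the group statistics, ROC rows and metric scales.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid_wl = config.grid.wavelengths()

    counts = dict(config.counts)
    for ref in REFERENCE_CLASSES:
        counts.setdefault(ref, config.pca_reference_count)
    spec = DatasetSpec(counts=counts, seed=seed)

    log.info("stage=simulate classes=%d total=%d", len(counts), sum(counts.values()))
    with _stage("simulate"):
        spectra = generate_dataset(config.model, spec, grid_wl=grid_wl, catalog=config.catalog)
        if write_spectra_csv:
            write_spectra(spectra, out_dir / "spectra.csv")

    log.info("stage=preprocess in=%d", len(spectra))
    with _stage("preprocess"):
        vectors = preprocess_all(
            spectra, config.catalog, percentile=config.baseline_percentile
        )
        write_areas(vectors, config.catalog, out_dir / "areas.csv")
    log.info("stage=preprocess out=%d skipped=%d", len(vectors), len(spectra) - len(vectors))

    with _stage("features"):
        features = features_table(vectors, config.catalog)
        write_features(features, out_dir / "features.csv")
    study = [f for f in features if f.tissue in STUDY_CLASSES]
    log.info("stage=features out=%d study=%d", len(features), len(study))

    summary = {}
    pairwise = {}
    with _stage("stats"):
        for element in ("Ca", "K"):
            groups = _grouped_values(study, element)
            summary[element] = {
                "classes": {
                    s.tissue.value: {"n": s.n, "median": s.median, "iqr": s.iqr}
                    for s in summarize_groups(study, element)
                },
            }
            kw = kruskal_wallis([groups[c] for c in STUDY_CLASSES])
            summary[element]["kruskal_wallis"] = {"H": kw.H, "df": kw.df, "p": kw.p}
            pairwise[element] = [
                {
                    "pair": [d.pair[0].value, d.pair[1].value],
                    "z": d.z,
                    "p_raw": d.p_raw,
                    "p_adj": d.p_adj,
                }
                for d in dunn_posthoc({c: groups[c] for c in STUDY_CLASSES})
            ]
    _json_dump(summary, out_dir / "summary.json")
    _json_dump(pairwise, out_dir / "pairwise.json")
    log.info("stage=stats elements=2")

    with _stage("roc"):
        roc_rows = pairwise_roc_report(study)
        _json_dump([r.to_dict() for r in roc_rows], out_dir / "roc.json")
        scales = {el: build_metric_scale(study, el).to_dict() for el in ("Ca", "K")}
        _json_dump(scales, out_dir / "scales.json")
    log.info("stage=roc rows=%d scales=%d", len(roc_rows), len(scales))

    pca_out = {}
    scores_paths = {}
    study_vectors = [v for v in vectors if v.tissue in STUDY_CLASSES]
    ref_vectors = [v for v in vectors if v.tissue in REFERENCE_CLASSES]
    rep_k = min(config.representative_k, min(config.counts.values()))
    representative = select_representative(study_vectors, rep_k)
    variants = {
        "all": vectors,
        "representative": [v for members in representative.values() for v in members]
        + ref_vectors,
    }
    for name, subset in variants.items():
        model = fit_pca(subset, config.catalog, include_reference=True)
        scores = project(model, subset)
        scores_path = out_dir / f"pca_scores_{name}.csv"
        scores.to_csv(scores_path, index=False, float_format="%.6g", lineterminator="\n")
        scores_paths[name] = scores_path
        pca_out[name] = {
            "n_fit": len(subset),
            "explained_variance_ratio": [float(x) for x in model.explained_variance_ratio],
            "loadings": loading_report(model).to_dict(orient="records"),
        }
    _json_dump(pca_out, out_dir / "pca.json")
    log.info("stage=pca variants=%d", len(pca_out))

    import numpy, pandas, scipy, sklearn  # versions for the manifest

    from . import __version__

    manifest = {
        "config_hash": config.config_hash(),
        "seed": seed,
        "counts": {t.value: n for t, n in counts.items()},
        "n_spectra": len(spectra),
        "n_preprocessed": len(vectors),
        "n_skipped": len(spectra) - len(vectors),
        "versions": {
            "libs_tissue": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "sklearn": sklearn.__version__,
        },
    }
    _json_dump(manifest, out_dir / "manifest.json")

    return {
        "spectra": spectra,
        "vectors": vectors,
        "features": features,
        "summary": summary,
        "pairwise": pairwise,
        "roc": roc_rows,
        "scales": scales,
        "pca": pca_out,
        "manifest": manifest,
        "out_dir": out_dir,
    }
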