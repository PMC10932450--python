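#!/usr/bin/env python
"""Reference-fixed PCA of the 13 Ca/K bin areas (representative + all spectra).

Fits covariance PCA twice — once on the per-class representative spectra
(nearest to the class median profile) and once on all spectra — each time
including the healthy-bone / tumor reference spectra that anchor the axes.
Exports scores and ranked loadings; prints the variance shares and the bins
dominating PC1/PC2.
"""

import argparse
import json
from pathlib import Path

from libs_tissue import (
    REFERENCE_CLASSES,
    STUDY_CLASSES,
    default_config,
    fit_pca,
    load_config,
    loading_report,
    project,
    read_areas,
    select_representative,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--config", type=Path, default=None)
    parser.add_argument("--in", dest="in_path", type=Path, default=Path("results/areas.csv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    cfg = load_config(args.config) if args.config else default_config()
    vectors = read_areas(args.in_path, cfg.catalog)
    study = [v for v in vectors if v.tissue in STUDY_CLASSES]
    refs = [v for v in vectors if v.tissue in REFERENCE_CLASSES]

    k = min(cfg.representative_k,
            min(sum(v.tissue is c for v in study) for c in STUDY_CLASSES))
    chosen = select_representative(study, k)
    variants = {
        "representative": [v for members in chosen.values() for v in members] + refs,
        "all": vectors,
    }

    args.out.mkdir(parents=True, exist_ok=True)
    payload = {}
    for name, subset in variants.items():
        model = fit_pca(subset, cfg.catalog, include_reference=True)
        report = loading_report(model)
        scores = project(model, subset)
        scores.to_csv(args.out / f"pca_scores_{name}.csv", index=False,
                      float_format="%.6g", lineterminator="\n")
        payload[name] = {
            "n_fit": len(subset),
            "explained_variance_ratio": [float(x) for x in model.explained_variance_ratio],
            "loadings": report.to_dict(orient="records"),
        }
        evr = model.explained_variance_ratio
        tops = {
            pc: report[(report.component == pc) & (report["rank"] == 1)]["bin"].iloc[0]
            for pc in (1, 2)
        }
        print(f"{name}: n={len(subset)}  PC1 {evr[0]:.1%} (top bin {tops[1]})  "
              f"PC2 {evr[1]:.1%} (top bin {tops[2]})")

    (args.out / "pca.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    print(f"wrote {args.out / 'pca.json'} and score tables")


if __name__ == "__main__":
    main()
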