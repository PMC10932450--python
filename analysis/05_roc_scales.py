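#!/usr/bin/env python
"""Pairwise ROC analysis and the Ca / K metric scales.

For every study-class pair and element this reports AUC (DeLong 95% CI),
the Mann-Whitney p-value and the Youden-optimal cutoff with its
sensitivity/specificity, then assembles the two ordered four-class metric
scales.  Writes ``<out>/roc.json`` and ``<out>/scales.json``.
"""

import argparse
import json
from pathlib import Path

from libs_tissue import (
    STUDY_CLASSES,
    build_metric_scale,
    pairwise_roc_report,
    read_features,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in", dest="in_path", type=Path, default=Path("results/features.csv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    features = [f for f in read_features(args.in_path) if f.tissue in STUDY_CLASSES]
    rows = pairwise_roc_report(features)
    print("pairwise discrimination (AUC [95% CI], Youden cutoff, sens/spec):")
    for r in rows:
        lo, hi = r.ci95
        arrow = ">" if r.direction.startswith("higher") else "<"
        print(f"  {r.positive_class.value:>15} vs {r.negative_class.value:<15} {r.element:>2}: "
              f"AUC {r.auc:.4f} [{lo:.4f}-{hi:.4f}]  cutoff {arrow}{r.cutoff:.4g}  "
              f"sens {r.sensitivity:.3f} spec {r.specificity:.3f}")

    scales = {}
    for element in ("Ca", "K"):
        scale = build_metric_scale(features, element)
        scales[element] = scale.to_dict()
        pretty = " < ".join(c.value for c in scale.ordered_classes)
        cuts = ", ".join(f"{c:.4g}" for c in scale.cutoffs)
        print(f"\n{element} metric scale: {pretty}  (cutoffs: {cuts})")

    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "roc.json").write_text(
        json.dumps([r.to_dict() for r in rows], indent=2, sort_keys=True) + "\n")
    (args.out / "scales.json").write_text(json.dumps(scales, indent=2, sort_keys=True) + "\n")
    print(f"\nwrote {args.out / 'roc.json'} and {args.out / 'scales.json'}")


if __name__ == "__main__":
    main()
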