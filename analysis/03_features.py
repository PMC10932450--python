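#!/usr/bin/env python
"""Collapse bin areas into the Ca/K/Na electrolyte sums and summarise them.

Writes ``<out>/features.csv`` and prints the per-class median (IQR) table
for Ca and K — the synthetic analog of the study's class-summary table.
"""

import argparse
from pathlib import Path

from libs_tissue import (
    STUDY_CLASSES,
    default_config,
    features_table,
    load_config,
    read_areas,
    summarize_groups,
    write_features,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--config", type=Path, default=None)
    parser.add_argument("--in", dest="in_path", type=Path, default=Path("results/areas.csv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    cfg = load_config(args.config) if args.config else default_config()
    vectors = read_areas(args.in_path, cfg.catalog)
    features = features_table(vectors, cfg.catalog)
    args.out.mkdir(parents=True, exist_ok=True)
    path = write_features(features, args.out / "features.csv")
    print(f"wrote {len(features)} feature rows -> {path}\n")

    study = [f for f in features if f.tissue in STUDY_CLASSES]
    for element in ("Ca", "K"):
        print(f"median {element} peak-area sum (IQR) per class:")
        for s in summarize_groups(study, element):
            print(f"  {s.tissue.value:>17}: {s.median:8.3f} ({s.iqr:.3f})   n={s.n}")
        print()


if __name__ == "__main__":
    main()
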