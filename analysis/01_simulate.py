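#!/usr/bin/env python
"""Simulate the study dataset: 3049 labelled single-shot spectra (+ references).

Generates the four tissue classes at the published sizes (fibrosis 254,
nerve 516, tumor stroma 821, cell-rich tumor 1458), plus a small number of
healthy-bone / tumor reference spectra used later to fix the PCA, and writes
everything to ``<out>/spectra.csv``.

Note: at the default 0.1 nm grid this file is large (~10.7 million rows);
pass ``--per-class N`` for a quick look.
"""

import argparse
from pathlib import Path

from libs_tissue import (
    DEFAULT_COUNTS,
    DatasetSpec,
    REFERENCE_CLASSES,
    default_config,
    generate_dataset,
    load_config,
    write_spectra,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--config", type=Path, default=None)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--per-class", type=int, default=None,
                        help="override every study-class count (quick runs)")
    args = parser.parse_args()

    cfg = load_config(args.config) if args.config else default_config()
    counts = dict(cfg.counts)
    if args.per_class is not None:
        counts = {cls: args.per_class for cls in counts}
    for ref in REFERENCE_CLASSES:
        counts[ref] = min(cfg.pca_reference_count, min(counts.values()))

    spectra = generate_dataset(
        cfg.model, DatasetSpec(counts=counts, seed=args.seed),
        grid_wl=cfg.grid.wavelengths(), catalog=cfg.catalog,
    )
    args.out.mkdir(parents=True, exist_ok=True)
    path = write_spectra(spectra, args.out / "spectra.csv")

    print(f"simulated {len(spectra)} single-shot spectra (seed {args.seed}) -> {path}")
    for cls, n in counts.items():
        print(f"  {cls.value:>17}: {n}")


if __name__ == "__main__":
    main()
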