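#!/usr/bin/env python
"""Preprocess the simulated spectra into per-bin peak areas.

Applies the measurement chain — constant-baseline subtraction (5th
percentile of out-of-window samples), base-peak normalization, discrete
integration of the 15 catalog windows — and writes ``<out>/areas.csv``.
"""

import argparse
from pathlib import Path

from libs_tissue import default_config, load_config, preprocess_all, read_spectra, write_areas


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--config", type=Path, default=None)
    parser.add_argument("--in", dest="in_path", type=Path, default=Path("results/spectra.csv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    cfg = load_config(args.config) if args.config else default_config()
    spectra = read_spectra(args.in_path, cfg.catalog)
    vectors = preprocess_all(spectra, cfg.catalog, percentile=cfg.baseline_percentile)
    args.out.mkdir(parents=True, exist_ok=True)
    path = write_areas(vectors, cfg.catalog, args.out / "areas.csv")
    skipped = len(spectra) - len(vectors)
    print(f"preprocessed {len(vectors)} spectra ({skipped} skipped) -> {path}")


if __name__ == "__main__":
    main()
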