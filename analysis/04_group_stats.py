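#!/usr/bin/env python
"""Rank tests on the electrolyte sums: Kruskal-Wallis omnibus + Dunn post hoc.

Answers "do the four tissue classes differ in Ca (and K) at all, and which
pairs differ?"  Writes ``<out>/group_stats.json`` and prints the test table.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from libs_tissue import STUDY_CLASSES, dunn_posthoc, kruskal_wallis, read_features


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in", dest="in_path", type=Path, default=Path("results/features.csv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    features = [f for f in read_features(args.in_path) if f.tissue in STUDY_CLASSES]
    payload = {}
    for element in ("Ca", "K"):
        groups = {}
        for f in features:
            groups.setdefault(f.tissue, []).append(f.value(element))
        arrays = {c: np.asarray(groups[c]) for c in STUDY_CLASSES}
        kw = kruskal_wallis(list(arrays.values()))
        dunn = dunn_posthoc(arrays)
        print(f"{element}: Kruskal-Wallis H = {kw.H:.1f} (df={kw.df}), p = {kw.p:.3g}")
        for d in dunn:
            print(f"    {d.pair[0].value:>17} vs {d.pair[1].value:<17} "
                  f"z={d.z:+7.2f}  p_adj={d.p_adj:.3g}")
        payload[element] = {
            "kruskal_wallis": {"H": kw.H, "df": kw.df, "p": kw.p},
            "dunn": [
                {"pair": [d.pair[0].value, d.pair[1].value], "z": d.z,
                 "p_raw": d.p_raw, "p_adj": d.p_adj}
                for d in dunn
            ],
        }
    args.out.mkdir(parents=True, exist_ok=True)
    out = args.out / "group_stats.json"
    out.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
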