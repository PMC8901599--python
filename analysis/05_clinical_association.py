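"""Brain-behaviour association: connection scores vs symptom scales.

Computes each patient's per-connection classification score (mean weight x
standardised feature value) and correlates it with the five symptom scales,
mirroring the selected-connection/scale correlation table of the analysis.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from borutafc.clinical import classification_scores, correlate_with_scales
from borutafc.connectome import read_atlas, read_feature_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    atlas = read_atlas(args.results / "atlas.tsv")
    table = read_feature_table(args.results / "features.csv", atlas)
    sel = json.loads((args.results / "boruta_result.json").read_text())["confirmed_index"]
    weights = np.asarray(list(json.loads(
        (args.results / "classification_report.json").read_text()
    )["mean_weights"].values()))
    clinical = pd.read_csv(args.results / "clinical.csv")

    sub = table.restrict(sel)
    pat = table.labels == 1
    scores = classification_scores(sub.features[pat], weights)
    corr = correlate_with_scales(scores, clinical, sub.connection_names())
    corr.to_csv(args.results / "clinical_correlations.csv", index=False)

    sig = corr[corr["significant"]].sort_values("p")
    print(f"{len(sig)} of {len(corr)} connection-scale pairs significant at p < 0.05 "
          f"({int((sig['sign'] > 0).sum())} positive, {int((sig['sign'] < 0).sum())} negative)")
    if len(sig):
        print(sig.head(10)[["connection", "scale", "r", "p"]].to_string(index=False))


if __name__ == "__main__":
    main()
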