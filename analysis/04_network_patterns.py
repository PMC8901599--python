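"""Network-level anatomy of the discriminative connection set.

Aggregates mean classification weights to regions and networks, applies the
2-SD important-region rule, computes each network's degree (between-network
connection count), and decomposes the connection set into k-means patterns
by subject profile.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from borutafc.connectome import read_atlas, read_feature_table
from borutafc.patterns import (
    ConnectionSet,
    contributing_mask,
    important_regions,
    kmeans_patterns,
    network_degree,
    network_weights,
    region_weights,
    within_between_counts,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--k", type=int, default=3)
    ap.add_argument("--results", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    atlas = read_atlas(args.results / "atlas.tsv")
    table = read_feature_table(args.results / "features.csv", atlas)
    sel = json.loads((args.results / "boruta_result.json").read_text())["confirmed_index"]
    weights = np.asarray(list(json.loads(
        (args.results / "classification_report.json").read_text()
    )["mean_weights"].values()))

    cs = ConnectionSet(
        connections=[table.connection_index[i] for i in sel],
        weights=weights, atlas=atlas,
    )
    rw = region_weights(cs)
    nw = network_weights(rw, atlas)
    nd = network_degree(cs)
    wb = within_between_counts(cs)
    imp = important_regions(rw, contributing_mask(cs))

    sub = table.restrict(sel)
    pat = kmeans_patterns(sub.features.T, k=min(args.k, len(cs)), seed=args.seed + 2)

    pd.DataFrame({
        "network": list(nd), "network_degree": list(nd.values()),
        "network_weight": [nw[n] for n in nd],
        "n_within": [wb[n][0] for n in nd], "n_between": [wb[n][1] for n in nd],
    }).to_csv(args.results / "network_summary.csv", index=False)
    pd.DataFrame({"connection": sub.connection_names(), "pattern_id": pat}).to_csv(
        args.results / "pattern_assignments.csv", index=False
    )

    top = max(nd, key=nd.get)
    print(f"network degree: {nd} -> highest in {top}")
    print(f"important regions (weight > mean + 2 SD of contributing): "
          f"{[atlas.names[i] for i in imp]}")
    print(f"pattern sizes (k={args.k}): {np.bincount(pat).tolist()}")


if __name__ == "__main__":
    main()
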