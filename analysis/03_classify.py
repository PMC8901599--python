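"""LOOCV SVM classification of the confirmed connections + permutation test.

Fits the RBF-kernel SVM under leave-one-out cross-validation on the
confirmed connection set, reports accuracy / sensitivity / specificity, and
assesses significance against a label-permutation null.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from borutafc.classify import SvmConfig, loocv_classify, permutation_test
from borutafc.connectome import read_atlas, read_feature_table
from borutafc.pipeline import save_classification_report


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-perm", type=int, default=199)
    ap.add_argument("--results", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    atlas = read_atlas(args.results / "atlas.tsv")
    table = read_feature_table(args.results / "features.csv", atlas)
    sel = json.loads((args.results / "boruta_result.json").read_text())["confirmed_index"]
    sub = table.restrict(sel)

    rep = loocv_classify(sub, SvmConfig())
    p, null = permutation_test(sub, SvmConfig(), args.n_perm, seed=args.seed + 1,
                               observed_accuracy=rep.accuracy)
    rep.p_value = p
    rep.permutation_null = null
    save_classification_report(rep, args.results, sub.connection_names())
    pd.DataFrame({"null_accuracy": null}).to_csv(
        args.results / "permutation_null.csv", index=False
    )

    print(f"LOOCV on {len(sel)} confirmed connections, {sub.n_subjects} subjects:")
    print(f"  accuracy {100 * rep.accuracy:.1f}%, sensitivity {100 * rep.sensitivity:.1f}%, "
          f"specificity {100 * rep.specificity:.1f}%")
    print(f"  permutation test ({args.n_perm} permutations): p = {p:.4g}, "
          f"null accuracy mean {100 * null.mean():.1f}%")


if __name__ == "__main__":
    main()
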