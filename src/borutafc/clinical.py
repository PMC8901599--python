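"""Brain-behaviour association of connection classification scores.

The classification score of connection c in subject i is defined as the
connection's additive contribution to the (pseudo-primal) decision value:
mean classification weight w_c times the subject's standardised feature
value z_ic.  Scores are correlated (Pearson) with clinician-administered
symptom scales — ADI-R social and verbal totals, ADOS total, communication
and social — in the patient group only, with pairwise deletion of missing
scale values and two-sided p-values from the t-distribution with n-2 df.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SCALE_COLUMNS = (
    "ADI_R_social",
    "ADI_R_verbal",
    "ADOS_total",
    "ADOS_communication",
    "ADOS_social",
)


def classification_scores(
    features: np.ndarray, mean_weights: np.ndarray
) -> np.ndarray:
    """Per-subject, per-connection score: weight x standardised feature value.

    Features are z-scored per connection across the given subjects
    (population SD); the score matrix has the same shape as ``features``.
    """
    X = np.asarray(features, dtype=float)
    w = np.asarray(mean_weights, dtype=float)
    if X.ndim != 2 or X.shape[1] != w.size:
        raise ValueError("mean_weights must align with feature columns")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd * w


def correlate_with_scales(
    scores: np.ndarray,
    clinical: pd.DataFrame,
    connection_names: list[str] | None = None,
    alpha: float = 0.05,
    correction: str = "none",
) -> pd.DataFrame:
    """Pearson correlation of every (connection score, clinical scale) pair.

    ``clinical`` rows must align with ``scores`` rows (patients only);
    missing scale values are pairwise-deleted.  Pairs with fewer than 3
    complete observations, or with a constant score or scale vector, are
    reported with NaN r and flagged ``undefined`` rather than dropped.
    Optional Benjamini-Hochberg correction across all defined pairs.
    """
    if correction not in ("none", "bh"):
        raise ValueError("correction must be 'none' or 'bh'")
    scores = np.asarray(scores, dtype=float)
    n, p = scores.shape
    if len(clinical) != n:
        raise ValueError("clinical rows must align with score rows")
    scales = [c for c in SCALE_COLUMNS if c in clinical.columns]
    if not scales:
        raise ValueError(f"clinical table has none of {SCALE_COLUMNS}")
    names = connection_names or [f"conn{c}" for c in range(p)]

    rows = []
    for c in range(p):
        for scale in scales:
            sv = clinical[scale].to_numpy(float)
            ok = ~np.isnan(sv)
            x, yv = scores[ok, c], sv[ok]
            n_used = int(ok.sum())
            if n_used < 3 or np.std(x) == 0 or np.std(yv) == 0:
                rows.append((names[c], scale, np.nan, np.nan, n_used, 0, True))
                continue
            r, pval = stats.pearsonr(x, yv)
            rows.append(
                (names[c], scale, float(r), float(pval), n_used, int(np.sign(r)), False)
            )
    out = pd.DataFrame(
        rows, columns=["connection", "scale", "r", "p", "n_used", "sign", "undefined"]
    )
    defined = ~out["undefined"]
    if correction == "bh" and defined.any():
        adj = multipletests(out.loc[defined, "p"], alpha=alpha, method="fdr_bh")
        out["p_adj"] = np.nan
        out.loc[defined, "p_adj"] = adj[1]
        out["significant"] = False
        out.loc[defined, "significant"] = adj[0]
    else:
        out["significant"] = defined & (out["p"] < alpha)
    return out


def read_clinical(path: str, subjects: list[str]) -> pd.DataFrame:
    """Clinical CSV keyed by subject_id, reindexed to the given subject order."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError("clinical table needs a subject_id column")
    df = df.set_index("subject_id")
    return df.reindex([str(s) for s in subjects])
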