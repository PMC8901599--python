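"""All-relevant feature selection with shadow features ("Boruta").

Each iteration shuffles every feature column across subjects to create
"shadow" features with the same marginal distribution but no label
association, fits a random-forest classifier to [real | shadow], and awards
a *hit* to every real feature whose Gini importance exceeds the 95th
percentile of the shadow importances.  After t iterations a feature with h
hits is tested against Binomial(t, null_hit_prob): a significant upper tail
confirms it, a significant lower tail rejects it, and rejected features are
dropped from the matrix.  The loop stops when nothing is undecided or a
maximum iteration count is reached; survivors are reported as tentative.

Multiple testing within each iteration uses a two-step correction: a
Benjamini-Hochberg step across the currently undecided features, and a
Bonferroni step at alpha divided by the number of still-active features;
a feature changes state only when both corrected tests are significant.
The conjunction is what keeps the confirmed set empty on pure-noise data:
features with chance in-sample label correlation outlive early rejection,
and a lone BH step across the shrunken family would eventually pass them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

from .connectome import FeatureTable

CONFIRMED = "confirmed"
REJECTED = "rejected"
TENTATIVE = "tentative"
UNDECIDED = "undecided"

_CORRECTIONS = ("two_step_fdr_bonferroni", "bonferroni_only", "none")


@dataclass
class BorutaConfig:
    """Settings of the selection loop.

    Defaults are the published settings: 500 trees, at most 250 iterations,
    the 95th shadow percentile as the hit threshold, alpha = 0.05 with the
    two-step correction.  ``null_hit_prob`` is the binomial null for the hit
    count; 0.5 follows the reference implementation lineage, 0.05 is the
    alternative reading and is selectable.
    """

    n_trees: int = 500
    max_iter: int = 250
    hit_percentile: float = 95.0
    alpha: float = 0.05
    null_hit_prob: float = 0.5
    correction: str = "two_step_fdr_bonferroni"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.hit_percentile <= 100:
            raise ValueError("hit_percentile must be in (0, 100]")
        if not 0 < self.null_hit_prob < 1:
            raise ValueError("null_hit_prob must be in (0, 1)")
        if self.correction not in _CORRECTIONS:
            raise ValueError(f"correction must be one of {_CORRECTIONS}")
        if self.max_iter < 1 or self.n_trees < 1:
            raise ValueError("n_trees and max_iter must be >= 1")


@dataclass
class BorutaResult:
    decision: np.ndarray  # (p,) of {confirmed, rejected, tentative}
    hits: np.ndarray  # (p,) ints
    n_iter_run: int
    importance_history: np.ndarray  # (n_iter_run, 2p); NaN once inactive
    confirmed_index: np.ndarray  # sorted original feature indices
    config: BorutaConfig = field(repr=False, default=None)

    @property
    def tentative_index(self) -> np.ndarray:
        return np.flatnonzero(self.decision == TENTATIVE)

    def selected(self, include_tentative: bool = False) -> np.ndarray:
        """Feature indices passed on to classification (confirmed only by default)."""
        if include_tentative:
            return np.sort(
                np.concatenate([self.confirmed_index, self.tentative_index])
            )
        return self.confirmed_index


def make_shadow_features(A: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute every column of A across rows (subjects)."""
    A = np.asarray(A, dtype=float)
    if A.size == 0:
        raise ValueError("cannot shadow an empty matrix")
    if A.shape[0] < 2:
        raise ValueError("need at least 2 rows to permute")
    out = np.empty_like(A)
    n = A.shape[0]
    for k in range(A.shape[1]):
        out[:, k] = A[rng.permutation(n), k]
    return out


def ensemble_importance(
    C: np.ndarray, labels: np.ndarray, n_trees: int, seed: int
) -> np.ndarray:
    """Gini importances of a random forest fit to the mixture matrix C.

    Mean decrease in Gini impurity per feature, nonnegative and normalised
    to sum to 1 (up to all-zero degenerate forests).
    """
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("need two classes for ensemble importance")
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features="sqrt",
        bootstrap=True,
        random_state=int(seed),
        n_jobs=1,
    )
    rf.fit(np.asarray(C, dtype=float), y)
    return rf.feature_importances_


def update_hits(
    importances: np.ndarray, hits: np.ndarray, hit_percentile: float
) -> np.ndarray:
    """Increment hit counts for real features beating the shadow percentile.

    ``importances`` holds the p real features first, then their p shadows.
    The threshold is the linearly interpolated ``hit_percentile`` of the
    shadow importances; the comparison is strict.
    """
    imp = np.asarray(importances, dtype=float)
    if imp.size == 0 or imp.size % 2:
        raise ValueError("importances must hold p real + p shadow values")
    p = imp.size // 2
    if len(hits) != p:
        raise ValueError("hits length mismatch")
    threshold = np.percentile(imp[p:], hit_percentile)  # linear interpolation
    return np.asarray(hits) + (imp[:p] > threshold).astype(int)


def binomial_decision(
    hits: int,
    n_iter: int,
    null_hit_prob: float = 0.5,
    alpha: float = 0.05,
    n_comparisons: int = 1,
) -> str:
    """Single-feature binomial test on an accumulated hit count.

    Exact tail probabilities: confirm when P(X >= hits) < alpha/m under
    Binomial(n_iter, null_hit_prob), reject when P(X <= hits) < alpha/m,
    else undecided.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not 0 <= hits <= n_iter:
        raise ValueError("hits must lie in [0, n_iter]")
    upper = stats.binom.sf(hits - 1, n_iter, null_hit_prob)
    lower = stats.binom.cdf(hits, n_iter, null_hit_prob)
    bound = alpha / n_comparisons
    if upper < bound:
        return CONFIRMED
    if lower < bound:
        return REJECTED
    return UNDECIDED


def _two_step_significant(pvals: np.ndarray, alpha: float, n_active: int) -> np.ndarray:
    """BH across the undecided family AND Bonferroni at alpha/n_active."""
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    bh = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    bonf = pvals < alpha / n_active
    return bh & bonf


def _decide(
    hits: np.ndarray,
    undecided: np.ndarray,
    n_iter: int,
    n_active: int,
    cfg: BorutaConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices (into the original feature set) to confirm and to reject."""
    idx = np.flatnonzero(undecided)
    h = hits[idx]
    upper = stats.binom.sf(h - 1, n_iter, cfg.null_hit_prob)
    lower = stats.binom.cdf(h, n_iter, cfg.null_hit_prob)
    if cfg.correction == "two_step_fdr_bonferroni":
        conf = _two_step_significant(upper, cfg.alpha, n_active)
        rej = _two_step_significant(lower, cfg.alpha, n_active)
    elif cfg.correction == "bonferroni_only":
        conf = upper < cfg.alpha / n_active
        rej = lower < cfg.alpha / n_active
    else:  # no correction
        conf = upper < cfg.alpha
        rej = lower < cfg.alpha
    rej &= ~conf  # a feature cannot be both; confirmation takes precedence
    return idx[conf], idx[rej]


def run_boruta(table: FeatureTable, cfg: BorutaConfig) -> BorutaResult:
    """Run the shadow-feature selection loop on a feature table.

    Rejected features are removed from the working matrix at the iteration
    they are rejected; confirmed features stay in the forest.  Features
    still undecided when the loop ends are reported as tentative.  Fully
    reproducible from ``cfg.seed``.
    """
    X = np.asarray(table.features, dtype=float)
    y = np.asarray(table.labels)
    n, p = X.shape
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if np.unique(y).size < 2:
        raise ValueError("need two classes")
    if np.all(X.std(axis=0) == 0):
        raise ValueError("degenerate feature table: every feature is constant")

    rng = np.random.default_rng(cfg.seed)
    status = np.full(p, UNDECIDED, dtype=object)
    hits = np.zeros(p, dtype=int)
    history: list[np.ndarray] = []

    n_iter_run = 0
    for t in range(1, cfg.max_iter + 1):
        active = status != REJECTED
        act_idx = np.flatnonzero(active)
        A = X[:, act_idx]
        B = make_shadow_features(A, rng)
        imp = ensemble_importance(
            np.hstack([A, B]), y, cfg.n_trees, seed=int(rng.integers(2**31))
        )
        m = act_idx.size
        real_imp, shadow_imp = imp[:m], imp[m:]

        hits[act_idx] = update_hits(imp, hits[act_idx], cfg.hit_percentile)

        row = np.full(2 * p, np.nan)
        row[act_idx] = real_imp
        row[p + act_idx] = shadow_imp
        history.append(row)
        n_iter_run = t

        to_confirm, to_reject = _decide(
            hits, status == UNDECIDED, t, int(active.sum()), cfg
        )
        status[to_confirm] = CONFIRMED
        status[to_reject] = REJECTED
        if not np.any(status == UNDECIDED):
            break

    status[status == UNDECIDED] = TENTATIVE
    return BorutaResult(
        decision=status.astype(str),
        hits=hits,
        n_iter_run=n_iter_run,
        importance_history=np.vstack(history),
        confirmed_index=np.flatnonzero(status == CONFIRMED),
        config=cfg,
    )
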