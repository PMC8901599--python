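"""Synthetic connectome datasets with planted group structure.

The generator emulates the study conditions the analysis assumes: 48
patients vs 50 controls, a 160-ROI atlas partitioned into six networks,
Fisher-z functional-connectivity features over the 12,720 ROI pairs, a
sparse set of 125 group-discriminative connections, and patient symptom
scales linearly related to a subset of those connections.  Features can be
drawn directly on the z scale (the fast, primary path) or derived from
generated ROI time series through the same Pearson + Fisher-z pipeline the
real analysis uses (the integration path).

All randomness flows from one master seed through named SeedSequence
substreams, so every artefact is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import (
    CANONICAL_NETWORKS,
    FeatureTable,
    RoiAtlas,
    SubjectTimeSeries,
    upper_triangle_index,
)

#: Network sizes of the 160-ROI six-network functional atlas
#: (default mode 34, frontoparietal 21, cingulo-opercular 32,
#: sensorimotor 33, occipital 22, cerebellum 18).
ATLAS_160_SIZES = {"DMN": 34, "FPN": 21, "CON": 32, "SMN": 33, "ON": 22, "CN": 18}

#: Patient symptom-scale calibration: (mean, SD, min, max) per scale,
#: matching the study cohort's clinical profile.
SCALE_CALIBRATION = {
    "ADI_R_social": (19.85, 5.10, 0, 30),
    "ADI_R_verbal": (15.34, 3.84, 0, 26),
    "ADOS_total": (11.71, 4.28, 0, 24),
    "ADOS_communication": (3.56, 1.64, 0, 10),
    "ADOS_social": (8.15, 2.97, 0, 14),
}


def default_network_sizes(R: int) -> dict[str, int]:
    """Six-network partition of R ROIs, proportional to the 160-ROI atlas."""
    if R < 6:
        raise ValueError("need at least one ROI per network (R >= 6)")
    if R == 160:
        return dict(ATLAS_160_SIZES)
    quotas = {k: R * v / 160 for k, v in ATLAS_160_SIZES.items()}
    sizes = {k: max(1, int(q)) for k, q in quotas.items()}
    # largest-remainder top-up to hit R exactly
    while sum(sizes.values()) < R:
        k = max(quotas, key=lambda k: quotas[k] - sizes[k])
        sizes[k] += 1
    while sum(sizes.values()) > R:
        k = min(quotas, key=lambda k: quotas[k] - sizes[k])
        if sizes[k] > 1:
            sizes[k] -= 1
    return sizes


@dataclass
class SyntheticConfig:
    """Study-shaped generator settings.

    ``effect_size`` is Cohen's d on the z-scale FC values of the planted
    discriminative connections; ``latent_strength`` is the SD of the shared
    network-block term that induces within-network feature correlation
    across subjects; ``noise_sd`` the independent per-connection noise SD
    (0.25 approximates typical between-subject variability of Fisher-z FC).
    """

    seed: int = 0
    n_patients: int = 48
    n_controls: int = 50
    n_rois: int = 160
    network_sizes: dict[str, int] | None = None
    n_timepoints: int = 170  # 180 acquired volumes minus 10 discarded
    n_discriminative: int = 125
    effect_size: float = 1.0
    latent_strength: float = 0.10
    noise_sd: float = 0.25
    baseline_within: float = 0.50
    baseline_between: float = 0.15
    n_clinical_linked: int = 5
    r_clin: float = 0.40
    round_clinical: bool = True

    def __post_init__(self) -> None:
        if self.network_sizes is None:
            self.network_sizes = default_network_sizes(self.n_rois)
        if sum(self.network_sizes.values()) != self.n_rois:
            raise ValueError("network sizes must sum to n_rois")
        p = self.n_rois * (self.n_rois - 1) // 2
        if not 0 <= self.n_discriminative <= p:
            raise ValueError("n_discriminative exceeds connection count")
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")
        if not abs(self.r_clin) < 1:
            raise ValueError("|r_clin| must be < 1")
        if not 0 <= self.n_clinical_linked <= self.n_discriminative:
            raise ValueError("clinical-linked connections must be a subset of planted")


@dataclass
class Truth:
    """Planted ground truth: which connections discriminate, and which drive scales."""

    discriminative: np.ndarray  # connection indices
    signs: np.ndarray  # +1 hyper- / -1 hypo-connectivity in patients
    clinical_linked: np.ndarray  # subset of discriminative


@dataclass
class SyntheticDataset:
    atlas: RoiAtlas
    feature_table: FeatureTable
    clinical: pd.DataFrame  # patients only, indexed like patient subjects
    truth: Truth
    time_series: list[SubjectTimeSeries] | None = field(default=None, repr=False)


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_atlas(
    R: int, network_sizes: dict[str, int] | None = None, seed: int = 0
) -> RoiAtlas:
    """Block-structured atlas: ROIs assigned to networks in contiguous blocks,
    with synthetic MNI coordinates in plausible cortical ranges."""
    sizes = network_sizes or default_network_sizes(R)
    if sum(sizes.values()) != R:
        raise ValueError("network sizes must sum to R")
    rng = np.random.default_rng(seed)
    names, networks = [], []
    for net in CANONICAL_NETWORKS:
        for k in range(sizes.get(net, 0)):
            names.append(f"{net}_{k:03d}")
            networks.append(net)
    xyz = np.column_stack(
        [
            rng.uniform(-70, 70, R),  # left-right
            rng.uniform(-105, 70, R),  # posterior-anterior
            rng.uniform(-45, 75, R),  # inferior-superior
        ]
    ).round(1)
    return RoiAtlas(names=tuple(names), networks=tuple(networks), mni_xyz=xyz)


def _block_id(index: list[tuple[int, int]], networks: np.ndarray) -> np.ndarray:
    """Unordered network-pair block id per connection."""
    nets = sorted(set(networks))
    pos = {n: k for k, n in enumerate(nets)}
    ids = np.empty(len(index), dtype=int)
    for c, (i, j) in enumerate(index):
        a, b = sorted((pos[networks[i]], pos[networks[j]]))
        ids[c] = a * len(nets) + b
    return ids


def generate_fc_features(
    atlas: RoiAtlas, cfg: SyntheticConfig
) -> tuple[FeatureTable, Truth]:
    """Draw z-scale FC feature vectors directly (the fast primary path).

    Each connection value = baseline (higher within-network) + shared
    network-block latent term + group shift of d*sigma on planted
    connections for patients + independent Gaussian noise.
    """
    rng_struct, rng_subj = _streams(cfg.seed, 2)
    index = upper_triangle_index(atlas.n_rois)
    p = len(index)
    networks = atlas.network_of

    within = np.array([networks[i] == networks[j] for i, j in index])
    baseline = np.where(within, cfg.baseline_within, cfg.baseline_between)
    baseline = baseline + rng_struct.normal(0, 0.05, p)  # per-connection variation

    planted = np.sort(rng_struct.choice(p, size=cfg.n_discriminative, replace=False))
    signs = rng_struct.choice([-1, 1], size=cfg.n_discriminative)
    linked = np.sort(
        rng_struct.choice(planted, size=cfg.n_clinical_linked, replace=False)
    )

    n = cfg.n_patients + cfg.n_controls
    labels = np.concatenate([np.ones(cfg.n_patients), -np.ones(cfg.n_controls)])
    sigma = float(np.hypot(cfg.latent_strength, cfg.noise_sd))  # within-group SD
    shift = cfg.effect_size * sigma

    blocks = _block_id(index, networks)
    n_blocks = blocks.max() + 1
    X = np.empty((n, p))
    for s in range(n):
        latent = rng_subj.normal(0, cfg.latent_strength, n_blocks)
        x = baseline + latent[blocks] + rng_subj.normal(0, cfg.noise_sd, p)
        if labels[s] > 0:
            x[planted] += signs * shift
        X[s] = x

    subjects = [f"ASD_{k:03d}" for k in range(cfg.n_patients)] + [
        f"TDC_{k:03d}" for k in range(cfg.n_controls)
    ]
    table = FeatureTable(
        subjects=subjects,
        labels=labels.astype(int),
        features=X,
        connection_index=index,
        atlas=atlas,
    )
    return table, Truth(discriminative=planted, signs=signs, clinical_linked=linked)


def generate_time_series(
    atlas: RoiAtlas, cfg: SyntheticConfig, truth: Truth | None = None
) -> tuple[list[SubjectTimeSeries], Truth]:
    """ROI time series whose derived FC carries the planted structure.

    Each ROI signal = autocorrelated shared network latent + pair-specific
    shared components on planted connections (with group-dependent mixing,
    creating the group FC difference) + white noise.
    """
    if cfg.n_timepoints < 30:
        raise ValueError("need at least 30 timepoints")
    rng_struct, rng_subj = _streams(cfg.seed ^ 0x5A17, 2)
    index = upper_triangle_index(atlas.n_rois)
    p = len(index)
    if truth is None:
        planted = np.sort(
            rng_struct.choice(p, size=cfg.n_discriminative, replace=False)
        )
        signs = rng_struct.choice([-1, 1], size=cfg.n_discriminative)
        linked = np.sort(
            rng_struct.choice(planted, size=cfg.n_clinical_linked, replace=False)
        )
        truth = Truth(discriminative=planted, signs=signs, clinical_linked=linked)

    networks = atlas.network_of
    nets = sorted(set(networks))
    net_pos = {nm: k for k, nm in enumerate(nets)}
    T, R = cfg.n_timepoints, atlas.n_rois
    a = 0.55  # network-latent mixing -> within-network r ~ a^2/(1+a^2+...)
    b_base, b_extra = 0.25, 0.55  # planted-pair mixing: controls, patient increment

    labels = np.concatenate(
        [np.ones(cfg.n_patients, int), -np.ones(cfg.n_controls, int)]
    )
    subjects = [f"ASD_{k:03d}" for k in range(cfg.n_patients)] + [
        f"TDC_{k:03d}" for k in range(cfg.n_controls)
    ]
    out = []
    for s, sid in enumerate(subjects):
        # AR(1) network latents
        latents = np.empty((T, len(nets)))
        latents[0] = rng_subj.normal(0, 1, len(nets))
        for t in range(1, T):
            latents[t] = 0.3 * latents[t - 1] + rng_subj.normal(0, 1, len(nets))
        sig = a * latents[:, [net_pos[nm] for nm in networks]]
        sig = sig + rng_subj.normal(0, 1, (T, R))
        for c, sgn in zip(truth.discriminative, truth.signs):
            i, j = index[c]
            # hyper-connectivity (+1): patients share more; hypo (-1): less
            if labels[s] > 0:
                b = b_base + (b_extra if sgn > 0 else -b_base)
            else:
                b = b_base + (b_extra if sgn < 0 else 0.0)
            if b > 0:
                comp = rng_subj.normal(0, 1, T)
                sig[:, i] += b * comp
                sig[:, j] += b * comp
        out.append(SubjectTimeSeries(subject_id=sid, data=sig))
    return out, truth


def generate_clinical(
    table: FeatureTable, truth: Truth, cfg: SyntheticConfig
) -> pd.DataFrame:
    """Patient symptom scales linearly tied to the clinical-linked connections.

    Each scale = r_clin * (standardised mean of the linked connections'
    z-scored values) + sqrt(1 - r_clin^2) * noise, affinely mapped to the
    scale's calibrated mean/SD and (by default) rounded and clipped into
    its plausible integer range.
    """
    (rng,) = _streams(cfg.seed ^ 0xC11, 1)
    pat = table.labels == 1
    if not pat.any():
        raise ValueError("no patients in table")
    Xp = table.features[pat]
    if truth.clinical_linked.size:
        Z = (Xp[:, truth.clinical_linked] - Xp[:, truth.clinical_linked].mean(0)) / (
            Xp[:, truth.clinical_linked].std(0) + 1e-12
        )
        u = Z.mean(axis=1)
        u = (u - u.mean()) / (u.std() + 1e-12)
    else:
        u = np.zeros(pat.sum())
    n = u.size
    data = {"subject_id": [s for s, m in zip(table.subjects, pat) if m]}
    for scale, (mu, sd, lo, hi) in SCALE_CALIBRATION.items():
        zsc = cfg.r_clin * u + np.sqrt(1 - cfg.r_clin**2) * rng.normal(0, 1, n)
        vals = mu + sd * zsc
        if cfg.round_clinical:
            vals = np.clip(np.round(vals), lo, hi)
        data[scale] = vals
    return pd.DataFrame(data)


def generate_dataset(cfg: SyntheticConfig, with_time_series: bool = False) -> SyntheticDataset:
    """The full synthetic study: atlas, features, patient scales, truth."""
    atlas = generate_atlas(cfg.n_rois, cfg.network_sizes, seed=cfg.seed)
    if with_time_series:
        from .connectome import assemble_feature_table

        ts, truth = generate_time_series(atlas, cfg)
        labels = {
            t.subject_id: (1 if t.subject_id.startswith("ASD") else -1) for t in ts
        }
        table = assemble_feature_table(ts, atlas, labels)
    else:
        ts = None
        table, truth = generate_fc_features(atlas, cfg)
    clinical = generate_clinical(table, truth, cfg)
    return SyntheticDataset(
        atlas=atlas, feature_table=table, clinical=clinical, truth=truth, time_series=ts
    )


def planted_feature_table(
    n_patients: int,
    n_controls: int,
    n_features: int,
    n_planted: int,
    effect_size: float,
    seed: int,
) -> tuple[FeatureTable, np.ndarray]:
    """Plain planted-signal table (no atlas structure) for calibration studies.

    Standard-normal noise features; the first ``n_planted`` (returned as the
    truth index) are shifted by ``effect_size`` SD in patients.  Connection
    indices are synthetic placeholders.
    """
    rng = np.random.default_rng(seed)
    n = n_patients + n_controls
    X = rng.normal(0, 1, (n, n_features))
    planted = np.arange(n_planted)
    labels = np.concatenate([np.ones(n_patients, int), -np.ones(n_controls, int)])
    if n_planted:
        X[np.ix_(labels == 1, planted)] += effect_size
    subjects = [f"P{k:03d}" for k in range(n_patients)] + [
        f"C{k:03d}" for k in range(n_controls)
    ]
    index = [(0, k + 1) for k in range(n_features)]  # placeholder pairs
    table = FeatureTable(
        subjects=subjects,
        labels=labels,
        features=X,
        connection_index=index,
        atlas=None,
    )
    return table, planted
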