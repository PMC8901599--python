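"""Whole-brain interregional functional-connectivity feature construction.

Each subject contributes a regions-of-interest (ROI) time-series matrix
(timepoints x ROIs).  Pairwise Pearson correlations between ROI time series
give a symmetric R x R connectivity matrix; Fisher's r-to-z transform
improves normality; the upper triangle (row-major over pairs (i, j), i < j)
is the subject's feature vector of length R(R-1)/2.  Stacking subjects gives
the feature table fed to feature selection and classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Canonical network labels of the six-network functional atlas:
#: default mode, frontoparietal, cingulo-opercular, sensorimotor,
#: occipital and cerebellum networks.
CANONICAL_NETWORKS = ("DMN", "FPN", "CON", "SMN", "ON", "CN")

#: Clip bound so that atanh stays finite on perfectly correlated series.
R_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class RoiAtlas:
    """A brain parcellation: ROI names, network membership, MNI coordinates.

    ROI ids are the 0-based positions in ``names``.  Every ROI belongs to
    exactly one network; network labels must come from the six canonical
    labels in :data:`CANONICAL_NETWORKS`.
    """

    names: tuple[str, ...]
    networks: tuple[str, ...]
    mni_xyz: np.ndarray  # (R, 3) floats, millimetres

    def __post_init__(self) -> None:
        if len(self.names) < 2:
            raise ValueError("atlas needs at least 2 ROIs")
        if len(self.names) != len(self.networks):
            raise ValueError("names and networks length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate ROI names")
        bad = sorted({n for n in self.networks} - set(CANONICAL_NETWORKS))
        if bad:
            raise ValueError(f"unknown network labels: {bad}")
        xyz = np.asarray(self.mni_xyz, dtype=float)
        if xyz.shape != (len(self.names), 3):
            raise ValueError("mni_xyz must be (R, 3)")

    @property
    def n_rois(self) -> int:
        return len(self.names)

    @property
    def network_of(self) -> np.ndarray:
        return np.asarray(self.networks, dtype=object)

    def network_members(self) -> dict[str, np.ndarray]:
        nets = np.asarray(self.networks, dtype=object)
        return {
            net: np.flatnonzero(nets == net)
            for net in CANONICAL_NETWORKS
            if np.any(nets == net)
        }


@dataclass(frozen=True)
class SubjectTimeSeries:
    """One subject's preprocessed ROI time series (T timepoints x R ROIs)."""

    subject_id: str
    data: np.ndarray
    t_start_discarded: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2:
            raise ValueError("time series must be 2-D (T x R)")
        if arr.shape[0] < 3:
            raise ValueError("need at least 3 timepoints")
        if np.isnan(arr).any():
            raise ValueError(f"NaN in time series of subject {self.subject_id}")


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric R x R matrix of pairwise connectivity values.

    ``scale`` is ``"pearson_r"`` (unit diagonal, entries in [-1, 1]) or
    ``"fisher_z"`` (zero diagonal).
    """

    values: np.ndarray
    scale: str  # "pearson_r" | "fisher_z"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if self.scale not in ("pearson_r", "fisher_z"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if not np.allclose(v, v.T, atol=0, rtol=0):
            raise ValueError("connectivity matrix must be exactly symmetric")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class FeatureTable:
    """Subjects x connections matrix of Fisher-z connectivity features.

    ``labels`` uses +1 for patients (the positive class) and -1 for controls.
    ``connection_index`` fixes the feature ordering as row-major pairs
    (0,1), (0,2), ..., (R-2, R-1).
    """

    subjects: list[str]
    labels: np.ndarray  # (n,) of +1/-1
    features: np.ndarray  # (n, p)
    connection_index: list[tuple[int, int]]
    atlas: RoiAtlas | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.features = np.asarray(self.features, dtype=float)
        n, p = self.features.shape
        if len(self.subjects) != n or len(self.labels) != n:
            raise ValueError("subjects / labels / features row mismatch")
        if len(set(self.subjects)) != n:
            raise ValueError("duplicate subject ids")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be +1 / -1")
        if len(self.connection_index) != p:
            raise ValueError("connection_index length must equal feature count")

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]

    @property
    def n_connections(self) -> int:
        return self.features.shape[1]

    def connection_names(self) -> list[str]:
        if self.atlas is None:
            return [f"roi{i}--roi{j}" for i, j in self.connection_index]
        nm = self.atlas.names
        return [f"{nm[i]}--{nm[j]}" for i, j in self.connection_index]

    def restrict(self, columns: Sequence[int]) -> "FeatureTable":
        """A new table with only the given connection columns (in order)."""
        cols = list(columns)
        return FeatureTable(
            subjects=list(self.subjects),
            labels=self.labels.copy(),
            features=self.features[:, cols],
            connection_index=[self.connection_index[c] for c in cols],
            atlas=self.atlas,
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.features, columns=self.connection_names())
        df.insert(0, "label", self.labels)
        df.insert(0, "subject_id", self.subjects)
        df.to_csv(path, index=False)


def compute_fc_matrix(ts: SubjectTimeSeries) -> ConnectivityMatrix:
    """Pearson-correlation connectivity matrix of one subject.

    Raises if any ROI time series has zero variance (correlation undefined),
    naming the offending column.
    """
    x = np.asarray(ts.data, dtype=float)
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"zero-variance time series for ROI column(s) {dead.tolist()} "
            f"of subject {ts.subject_id}"
        )
    r = np.corrcoef(x, rowvar=False)
    r = (r + r.T) / 2.0  # enforce exact symmetry against float round-off
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(values=r, scale="pearson_r")


def fisher_z(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Fisher r-to-z transform, z = atanh(r), applied elementwise.

    |r| is clipped to 1 - 1e-7 first so the map is total; the diagonal is
    set to 0 (self-connections are never features).
    """
    if m.scale != "pearson_r":
        raise ValueError("fisher_z expects a pearson_r matrix")
    r = np.clip(m.values, -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(values=z, scale="fisher_z")


def upper_triangle_index(n_rois: int) -> list[tuple[int, int]]:
    """Row-major upper-triangle pair ordering (0,1), (0,2), ..., (R-2,R-1)."""
    iu = np.triu_indices(n_rois, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


def vectorize_upper_triangle(
    m: ConnectivityMatrix,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Extract the strict upper triangle as a vector of length R(R-1)/2."""
    v = m.values
    iu = np.triu_indices(m.n_rois, k=1)
    return v[iu].copy(), upper_triangle_index(m.n_rois)


def fold_upper_triangle(vec: np.ndarray, n_rois: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper_triangle` (zero diagonal)."""
    vec = np.asarray(vec, dtype=float)
    if vec.size != n_rois * (n_rois - 1) // 2:
        raise ValueError("vector length does not match n_rois")
    out = np.zeros((n_rois, n_rois))
    iu = np.triu_indices(n_rois, k=1)
    out[iu] = vec
    out += out.T
    return out


def assemble_feature_table(
    ts_list: Sequence[SubjectTimeSeries],
    atlas: RoiAtlas,
    labels: dict[str, int],
) -> FeatureTable:
    """FC -> Fisher z -> upper triangle for every subject, stacked in order."""
    rows = []
    subjects = []
    y = []
    index = upper_triangle_index(atlas.n_rois)
    for ts in ts_list:
        if ts.data.shape[1] != atlas.n_rois:
            raise ValueError(
                f"subject {ts.subject_id} has {ts.data.shape[1]} ROIs, "
                f"atlas has {atlas.n_rois}"
            )
        if ts.subject_id not in labels:
            raise ValueError(f"no group label for subject {ts.subject_id}")
        z = fisher_z(compute_fc_matrix(ts))
        vec, _ = vectorize_upper_triangle(z)
        rows.append(vec)
        subjects.append(ts.subject_id)
        y.append(labels[ts.subject_id])
    return FeatureTable(
        subjects=subjects,
        labels=np.asarray(y),
        features=np.vstack(rows),
        connection_index=index,
        atlas=atlas,
    )


# ---------------------------------------------------------------------------
# File formats: atlas TSV, per-subject time-series TSV, subject manifest CSV.


def write_atlas(atlas: RoiAtlas, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "roi_id": np.arange(atlas.n_rois),
            "name": atlas.names,
            "network": atlas.networks,
            "x": atlas.mni_xyz[:, 0],
            "y": atlas.mni_xyz[:, 1],
            "z": atlas.mni_xyz[:, 2],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_atlas(path: str | Path) -> RoiAtlas:
    df = pd.read_csv(path, sep="\t")
    required = {"roi_id", "name", "network", "x", "y", "z"}
    if not required <= set(df.columns):
        raise ValueError(f"atlas file missing columns {required - set(df.columns)}")
    df = df.sort_values("roi_id")
    if not np.array_equal(df["roi_id"].to_numpy(), np.arange(len(df))):
        raise ValueError("roi_id must be contiguous 0..R-1")
    return RoiAtlas(
        names=tuple(df["name"].astype(str)),
        networks=tuple(df["network"].astype(str)),
        mni_xyz=df[["x", "y", "z"]].to_numpy(float),
    )


def write_time_series(ts: SubjectTimeSeries, atlas: RoiAtlas, path: str | Path) -> None:
    pd.DataFrame(ts.data, columns=list(atlas.names)).to_csv(path, sep="\t", index=False)


def read_time_series(subject_id: str, path: str | Path) -> SubjectTimeSeries:
    df = pd.read_csv(path, sep="\t")
    return SubjectTimeSeries(subject_id=subject_id, data=df.to_numpy(float))


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Manifest CSV: subject_id, path, label (+1 patient / -1 control)."""
    df = pd.read_csv(path)
    required = {"subject_id", "path", "label"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest missing columns {required - set(df.columns)}")
    return df


def read_feature_table(path: str | Path, atlas: RoiAtlas | None = None) -> FeatureTable:
    df = pd.read_csv(path)
    conn_cols = [c for c in df.columns if c not in ("subject_id", "label")]
    if atlas is not None:
        name_to_id = {n: i for i, n in enumerate(atlas.names)}
        index = []
        for c in conn_cols:
            a, b = c.split("--")
            i, j = name_to_id[a], name_to_id[b]
            index.append((min(i, j), max(i, j)))
    else:
        index = [(int(c.split("--")[0][3:]), int(c.split("--")[1][3:])) for c in conn_cols]
    return FeatureTable(
        subjects=df["subject_id"].astype(str).tolist(),
        labels=df["label"].to_numpy(int),
        features=df[conn_cols].to_numpy(float),
        connection_index=index,
        atlas=atlas,
    )
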