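"""End-to-end orchestration: FC features -> selection -> LOOCV SVM ->
permutation test -> network/pattern analytics -> clinical association.

Every stage writes its artefact to the output directory before the next
stage starts, so a run is auditable stage by stage; a rerun with identical
config and seed reproduces every decision and metric.  All defaults that
the method leaves open (gamma rule, binomial null, k, selection mode) are
echoed into the consolidated report so it is self-describing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .boruta import BorutaConfig, BorutaResult, run_boruta
from .classify import (
    ClassificationReport,
    SvmConfig,
    format_metrics_percent,
    loocv_classify,
    permutation_test,
)
from .clinical import classification_scores, correlate_with_scales, read_clinical
from .connectome import (
    FeatureTable,
    RoiAtlas,
    assemble_feature_table,
    read_atlas,
    read_feature_table,
    read_manifest,
    read_time_series,
)
from .patterns import (
    ConnectionSet,
    contributing_mask,
    important_regions,
    kmeans_patterns,
    network_degree,
    network_weights,
    region_weights,
    silhouette_scan,
    within_between_counts,
)
from .simulate import SyntheticConfig, SyntheticDataset, generate_dataset


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Everything a run needs.  Either file paths (manifest/atlas/features)
    or a synthetic config must be provided."""

    output_dir: str | Path = "results/run"
    seed: int = 0
    atlas_path: str | None = None
    manifest_path: str | None = None
    features_path: str | None = None
    clinical_path: str | None = None
    synthetic: SyntheticConfig | None = None
    boruta: BorutaConfig = field(default_factory=BorutaConfig)
    svm: SvmConfig = field(default_factory=SvmConfig)
    n_perm: int = 10_000
    selection_mode: str = "once"  # once | nested
    k_patterns: int = 3
    include_tentative: bool = False

    def __post_init__(self) -> None:
        if self.selection_mode not in ("once", "nested"):
            raise ValueError("selection_mode must be 'once' or 'nested'")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.k_patterns < 1:
            raise ValueError("k_patterns must be >= 1")
        has_files = self.features_path or (self.manifest_path and self.atlas_path)
        if not has_files and self.synthetic is None:
            raise ValueError(
                "provide features_path, or manifest_path + atlas_path, or synthetic"
            )


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")


def load_inputs(cfg: RunConfig) -> tuple[FeatureTable, RoiAtlas | None, pd.DataFrame | None, SyntheticDataset | None]:
    """Resolve the feature table, atlas and clinical table from config."""
    if cfg.synthetic is not None:
        ds = generate_dataset(cfg.synthetic)
        return ds.feature_table, ds.atlas, ds.clinical, ds
    atlas = read_atlas(cfg.atlas_path) if cfg.atlas_path else None
    if cfg.features_path:
        table = read_feature_table(cfg.features_path, atlas)
    else:
        manifest = read_manifest(cfg.manifest_path)
        ts = [
            read_time_series(str(r.subject_id), r.path) for r in manifest.itertuples()
        ]
        labels = {str(r.subject_id): int(r.label) for r in manifest.itertuples()}
        table = assemble_feature_table(ts, atlas, labels)
    clinical = None
    if cfg.clinical_path:
        pat = [s for s, y in zip(table.subjects, table.labels) if y == 1]
        clinical = read_clinical(cfg.clinical_path, pat)
    return table, atlas, clinical, None


def save_boruta_result(res: BorutaResult, out: Path, names: list[str]) -> None:
    _write_json(
        out / "boruta_result.json",
        {
            "decision": dict(zip(names, res.decision.tolist())),
            "hits": dict(zip(names, res.hits.tolist())),
            "n_iter_run": res.n_iter_run,
            "confirmed_index": res.confirmed_index,
            "config": res.config,
        },
    )
    hist_cols = [f"real:{n}" for n in names] + [f"shadow:{n}" for n in names]
    pd.DataFrame(res.importance_history, columns=hist_cols).to_csv(
        out / "importance_history.csv", index=False
    )


def save_classification_report(
    rep: ClassificationReport, out: Path, names: list[str], label: str = "classification"
) -> None:
    acc, sens, spec = format_metrics_percent(rep.accuracy, rep.sensitivity, rep.specificity)
    _write_json(
        out / f"{label}_report.json",
        {
            "accuracy_pct": acc,
            "sensitivity_pct": sens,
            "specificity_pct": spec,
            "config": rep.config,
            "mean_weights": dict(zip(names, rep.mean_weights.tolist())),
            "folds": [
                {
                    "held_out_subject": f.held_out_subject,
                    "true_label": f.true_label,
                    "predicted_label": f.predicted_label,
                    "decision_value": f.decision_value,
                }
                for f in rep.folds
            ],
            "p_value": rep.p_value,
        },
    )


def _plot_permutation_null(null: np.ndarray, observed: float, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist(100 * null, bins=30, color="steelblue", edgecolor="white")
    ax.axvline(100 * observed, color="crimson", lw=2, label=f"observed {100*observed:.1f}%")
    ax.set_xlabel("null accuracy (%)")
    ax.set_ylabel("count")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages in order; returns the consolidated report dict."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "effective_config": {
            "boruta": _jsonable(cfg.boruta),
            "svm": _jsonable(cfg.svm),
            "n_perm": cfg.n_perm,
            "selection_mode": cfg.selection_mode,
            "k_patterns": cfg.k_patterns,
            "include_tentative": cfg.include_tentative,
            "synthetic": _jsonable(cfg.synthetic) if cfg.synthetic else None,
        },
    }

    # --- stage: features -------------------------------------------------
    try:
        table, atlas, clinical, ds = load_inputs(cfg)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("features", str(e)) from e
    names = table.connection_names()
    table.to_csv(out / "feature_table.csv")
    report["features"] = {
        "n_subjects": table.n_subjects,
        "n_patients": int(np.sum(table.labels == 1)),
        "n_controls": int(np.sum(table.labels == -1)),
        "n_connections": table.n_connections,
    }

    # --- stage: selection -------------------------------------------------
    try:
        bres = run_boruta(table, cfg.boruta)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("selection", str(e)) from e
    save_boruta_result(bres, out, names)
    selected = bres.selected(include_tentative=cfg.include_tentative)
    report["selection"] = {
        "n_confirmed": int(bres.confirmed_index.size),
        "n_tentative": int(bres.tentative_index.size),
        "n_rejected": int(np.sum(bres.decision == "rejected")),
        "n_iter_run": bres.n_iter_run,
        "selected_connections": [names[i] for i in selected],
    }

    # --- stage: classification --------------------------------------------
    if selected.size == 0:
        raise PipelineError(
            "classification", "no connection was confirmed by feature selection"
        )
    sub = table.restrict(selected)
    try:
        crep = loocv_classify(sub, cfg.svm)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("classification", str(e)) from e
    sel_names = [names[i] for i in selected]
    acc, sens, spec = format_metrics_percent(
        crep.accuracy, crep.sensitivity, crep.specificity
    )
    report["classification"] = {
        "accuracy_pct": acc,
        "sensitivity_pct": sens,
        "specificity_pct": spec,
        "n_selected": int(selected.size),
    }

    # --- stage: permutation -----------------------------------------------
    try:
        if cfg.selection_mode == "nested":
            boruta_cfg = cfg.boruta

            def select(X, y):
                t = FeatureTable(
                    subjects=table.subjects,
                    labels=y,
                    features=X,
                    connection_index=table.connection_index,
                    atlas=table.atlas,
                )
                return run_boruta(t, boruta_cfg).confirmed_index

            p_value, null = permutation_test(
                table, cfg.svm, cfg.n_perm, cfg.seed + 1,
                observed_accuracy=crep.accuracy, select=select,
            )
        else:
            p_value, null = permutation_test(
                sub, cfg.svm, cfg.n_perm, cfg.seed + 1,
                observed_accuracy=crep.accuracy,
            )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("permutation", str(e)) from e
    crep.permutation_null = null
    crep.p_value = p_value
    save_classification_report(crep, out, sel_names)
    pd.DataFrame({"null_accuracy": null}).to_csv(out / "permutation_null.csv", index=False)
    _plot_permutation_null(null, crep.accuracy, out / "permutation_hist.png")
    report["permutation"] = {"n_perm": cfg.n_perm, "p_value": p_value,
                             "selection_mode": cfg.selection_mode}

    # --- stage: patterns ---------------------------------------------------
    if atlas is None:
        report["patterns"] = None
    else:
        try:
            cs = ConnectionSet(
                connections=[table.connection_index[i] for i in selected],
                weights=crep.mean_weights,
                atlas=atlas,
            )
            rw = region_weights(cs, mode="absolute")
            contrib = contributing_mask(cs)
            nw = network_weights(rw, atlas)
            imp = important_regions(rw, contrib) if contrib.sum() >= 2 else []
            nd = network_degree(cs)
            wb = within_between_counts(cs)
            k = min(cfg.k_patterns, len(cs))
            pat = kmeans_patterns(sub.features.T, k, seed=cfg.seed + 2)
            sil = (
                silhouette_scan(sub.features.T, seed=cfg.seed + 2)
                if len(cs) > 8
                else {}
            )
        except Exception as e:  # noqa: BLE001
            raise PipelineError("patterns", str(e)) from e
        pd.DataFrame(
            {
                "network": list(nd),
                "network_degree": list(nd.values()),
                "network_weight": [nw[n] for n in nd],
                "n_within": [wb[n][0] for n in nd],
                "n_between": [wb[n][1] for n in nd],
            }
        ).to_csv(out / "network_summary.csv", index=False)
        pd.DataFrame({"connection": sel_names, "pattern_id": pat}).to_csv(
            out / "pattern_assignments.csv", index=False
        )
        _write_json(
            out / "pattern_summary.json",
            {
                "region_weight": dict(zip(atlas.names, rw.tolist())),
                "network_weight": nw,
                "important_regions": [atlas.names[i] for i in imp],
                "network_degree": nd,
                "pattern_sizes": np.bincount(pat, minlength=k),
                "silhouette_by_k": sil,
                "weight_mode": "absolute",
                "sd_convention": "sample (n-1)",
            },
        )
        report["patterns"] = {
            "network_degree": nd,
            "important_regions": [atlas.names[i] for i in imp],
            "pattern_sizes": np.bincount(pat, minlength=k).tolist(),
        }

    # --- stage: clinical ----------------------------------------------------
    if clinical is None and ds is not None:
        clinical = ds.clinical.set_index("subject_id")
    if clinical is None:
        report["clinical"] = None
    else:
        try:
            pat_mask = table.labels == 1
            scores = classification_scores(
                sub.features[pat_mask], crep.mean_weights
            )
            corr = correlate_with_scales(scores, clinical.reset_index(), sel_names)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("clinical", str(e)) from e
        corr.to_csv(out / "clinical_correlations.csv", index=False)
        sig = corr[corr["significant"]]
        report["clinical"] = {
            "n_pairs_tested": int(len(corr)),
            "n_significant": int(len(sig)),
            "n_positive": int((sig["sign"] > 0).sum()),
            "n_negative": int((sig["sign"] < 0).sum()),
        }

    _write_json(out / "run_report.json", report)
    return report
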