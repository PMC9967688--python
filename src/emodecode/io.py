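"""On-disk artifact formats for the pipeline stages.

Trial signals and observation tensors are stored as ``.npz`` array
containers with JSON/CSV sidecars for row metadata and exclusion logs;
feature matrices as CSV with a JSON sidecar of row labels; selection
results and cross-validation reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .preprocess import ObservationSet
from .select import SelectionResult
from .synthgen import TrialRecording


def save_trial(path, trial: TrialRecording) -> None:
    np.savez_compressed(
        path,
        baseline=trial.baseline_signal,
        emotional=trial.emotional_signal,
        participant=trial.participant,
        session=trial.session,
        trial_index=trial.trial_index,
        condition=trial.condition,
        sampling_rate=trial.sampling_rate,
    )


def load_trial(path) -> TrialRecording:
    with np.load(path, allow_pickle=False) as z:
        return TrialRecording(
            participant=int(z["participant"]),
            session=int(z["session"]),
            trial_index=int(z["trial_index"]),
            condition=str(z["condition"]),
            baseline_signal=z["baseline"],
            emotional_signal=z["emotional"],
            sampling_rate=float(z["sampling_rate"]),
        )


def save_observation_set(prefix, obs: ObservationSet) -> None:
    """Write tensors to ``<prefix>.npz`` plus metadata/exclusion sidecars."""
    prefix = Path(prefix)
    arrays = {f"emotional__{k}": v for k, v in obs.emotional.items()}
    arrays |= {f"baseline__{k}": v for k, v in obs.baseline.items()}
    np.savez_compressed(prefix.with_suffix(".npz"), **arrays)
    meta = {
        "sampling_rate": obs.sampling_rate,
        "rows": obs.metadata.to_dict(orient="list"),
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    obs.exclusions.to_csv(prefix.parent / (prefix.name + "_exclusions.csv"), index=False)


def load_observation_set(prefix) -> ObservationSet:
    prefix = Path(prefix)
    emotional, baseline = {}, {}
    with np.load(prefix.with_suffix(".npz"), allow_pickle=False) as z:
        for key in z.files:
            side, band = key.split("__", 1)
            (emotional if side == "emotional" else baseline)[band] = z[key]
    meta = json.loads(prefix.with_suffix(".json").read_text())
    excl_path = prefix.parent / (prefix.name + "_exclusions.csv")
    exclusions = (
        pd.read_csv(excl_path)
        if excl_path.exists()
        else pd.DataFrame(columns=["participant", "session", "trial", "reason"])
    )
    obs = ObservationSet(
        emotional=emotional,
        baseline=baseline,
        metadata=pd.DataFrame(meta["rows"]),
        sampling_rate=float(meta["sampling_rate"]),
        exclusions=exclusions,
    )
    obs.validate()
    return obs


def save_feature_matrix(prefix, fm: FeatureMatrix) -> None:
    prefix = Path(prefix)
    fm.data.to_csv(prefix.with_suffix(".csv"), index=False)
    sidecar = {
        "family": fm.family,
        "is_baseline": fm.is_baseline,
        "labels": fm.labels.to_dict(orient="list"),
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_feature_matrix(prefix) -> FeatureMatrix:
    prefix = Path(prefix)
    data = pd.read_csv(prefix.with_suffix(".csv"))
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    return FeatureMatrix(
        data=data,
        labels=pd.DataFrame(sidecar["labels"]),
        family=sidecar["family"],
        is_baseline=bool(sidecar["is_baseline"]),
    )


def save_selection_result(path, result: SelectionResult) -> None:
    payload = {
        "mode": result.mode,
        "family": result.family,
        "retained": result.retained,
        "alpha_phase1": result.alpha_phase1,
        "alpha_phase2": result.alpha_phase2,
        "phase1_p": None
        if result.phase1_p is None
        else {
            "columns": list(result.phase1_p.index),
            "conditions": list(result.phase1_p.columns),
            "values": result.phase1_p.to_numpy().tolist(),
        },
        "phase2_p": {k: (None if pd.isna(v) else v) for k, v in result.phase2_p.items()},
        "dropped_undefined": result.dropped_undefined,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def save_confusion_heatmap(path, report, dpi: int = 120) -> None:
    """Render the row-normalized confusion matrix as a heatmap image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .classify import confusion

    pct = confusion(report)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(pct, vmin=0, vmax=100, cmap="viridis")
    ax.set_xticks(range(len(report.class_order)), report.class_order, rotation=45, ha="right")
    ax.set_yticks(range(len(report.class_order)), report.class_order)
    ax.set_xlabel("predicted")
    ax.set_ylabel("actual")
    ax.set_title(f"{report.scheme} — test {report.test_mean:.1f}%")
    for i in range(pct.shape[0]):
        for j in range(pct.shape[1]):
            ax.text(j, i, f"{pct[i, j]:.1f}", ha="center", va="center", color="w", fontsize=8)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
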