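"""File-format plumbing: session container, ground truth, CSV/JSON exports.

A Session is persisted as raw little-endian float32 samples (``<prefix>.f32``,
channel-major) plus a JSON sidecar (``<prefix>.json``) holding the sampling
rate, channel labels, montage coordinates and the trial manifest.  Derived
artifacts use plain CSV/JSON so any plotting tool can consume them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .decode import CvResult
from .discrim import RsqMap
from .specpca import SpectralBasis
from .synth import GroundTruth, Session


def save_session(session: Session, prefix: str | Path) -> tuple[Path, Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    raw = prefix.with_suffix(".f32")
    meta = prefix.with_suffix(".json")
    session.data.astype("<f4").tofile(raw)
    sidecar = {
        "sampling_rate_hz": int(session.sampling_rate_hz),
        "n_channels": int(session.n_channels),
        "n_samples": int(session.n_samples),
        "dtype": "<f4",
        "channel_labels": list(session.channel_labels),
        "montage_xy": session.montage_xy.tolist(),
        "trials": [[int(onset), str(lab)] for onset, lab in session.trials],
        "fingers": list(session.fingers),
    }
    meta.write_text(json.dumps(sidecar, indent=1))
    return raw, meta


def load_session(prefix: str | Path) -> Session:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    data = np.fromfile(prefix.with_suffix(".f32"), dtype=meta["dtype"])
    data = data.reshape(meta["n_channels"], meta["n_samples"]).astype(float)
    return Session(data=data,
                   sampling_rate_hz=meta["sampling_rate_hz"],
                   channel_labels=tuple(meta["channel_labels"]),
                   montage_xy=np.asarray(meta["montage_xy"], dtype=float),
                   trials=[(int(o), str(lab)) for o, lab in meta["trials"]],
                   fingers=tuple(meta["fingers"]))


def save_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "freqs": truth.freqs.tolist(),
        "broadband_profile": truth.broadband_profile.tolist(),
        "rhythm_profile": truth.rhythm_profile.tolist(),
        "expected_log_power": {c: arr.tolist()
                               for c, arr in truth.expected_log_power.items()},
    }
    path.write_text(json.dumps(payload))
    return path


def load_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        freqs=np.asarray(payload["freqs"], dtype=float),
        broadband_profile=np.asarray(payload["broadband_profile"], dtype=float),
        rhythm_profile=np.asarray(payload["rhythm_profile"], dtype=float),
        expected_log_power={c: np.asarray(a, dtype=float)
                            for c, a in payload["expected_log_power"].items()})


def save_basis_csv(basis: SpectralBasis, path: str | Path,
                   n_components: int = 3) -> Path:
    """Leading spectral PC profiles as CSV (one row per analysis frequency)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = {"freq_hz": basis.freqs}
    for k in range(n_components):
        cols[f"PC{k + 1}"] = basis.eigenvectors[:, k]
    frame = pd.DataFrame(cols)
    frame.attrs["eigenvalues"] = basis.eigenvalues[:n_components].tolist()
    header = "# eigenvalues: " + ",".join(
        f"{v:.10g}" for v in basis.eigenvalues[:n_components]) + "\n"
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, index=False)
    return path


def load_basis_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def save_rsq_csv(rsq: RsqMap, path: str | Path) -> Path:
    """Per-channel topography CSV: channel, x, y, r, r2."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame({
        "channel": list(rsq.channel_labels),
        "x": rsq.montage_xy[:, 0],
        "y": rsq.montage_xy[:, 1],
        "r": rsq.r,
        "r2": rsq.r2,
    })
    frame.to_csv(path, index=False)
    return path


def save_topography_csv(values: np.ndarray, channel_labels, montage_xy,
                        path: str | Path, column: str = "value") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"channel": list(channel_labels),
                  "x": montage_xy[:, 0], "y": montage_xy[:, 1],
                  column: values}).to_csv(path, index=False)
    return path


def save_cv_result(result: CvResult, prefix: str | Path) -> tuple[Path, Path, Path]:
    """JSON summary + confusion CSV (rows predicted, columns actual) + fold CSV."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    summary = prefix.with_suffix(".json")
    summary.write_text(json.dumps({
        "task": result.task,
        "feature_kinds": list(result.feature_kinds),
        "classes": list(result.classes),
        "seed": int(result.seed),
        "mean_accuracy": result.mean_accuracy,
        "pooled_accuracy": result.pooled_accuracy,
        "per_repeat_means": result.per_repeat_means.tolist(),
    }, indent=1))
    conf = prefix.parent / (prefix.name + "_confusion.csv")
    pd.DataFrame(result.confusion,
                 index=[f"pred_{c}" for c in result.classes],
                 columns=[f"actual_{c}" for c in result.classes]).to_csv(conf)
    folds = prefix.parent / (prefix.name + "_fold_accuracies.csv")
    reps, nf = result.accuracies.shape
    pd.DataFrame({
        "repeat": np.repeat(np.arange(reps), nf),
        "fold": np.tile(np.arange(nf), reps),
        "accuracy": result.accuracies.ravel(),
    }).to_csv(folds, index=False)
    return summary, conf, folds
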