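"""Readers/writers for the package's on-disk formats.

Recordings travel as flat little-endian float32 binary (channel-major)
with a JSON sidecar, or as single-channel two-column delimited text
(time_s, value).  Ground truth and onset tables are JSON / CSV; traces are
delimited matrices with a frame-time column; movies are multi-page TIFF
and masks labeled 16-bit TIFF.  EDF ingestion is optional and available
when `mne` is importable.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import Recording
from .synthgen import GroundTruth


def save_recording(rec: Recording, prefix: str | Path) -> tuple[Path, Path]:
    """Write flat binary (.f32, channel-major) + JSON sidecar (.json)."""
    prefix = Path(prefix)
    bin_path = prefix.with_suffix(".f32")
    meta_path = prefix.with_suffix(".json")
    rec.samples.astype("<f4").tofile(bin_path)
    meta = {
        "sampling_rate": rec.sampling_rate,
        "channels": rec.channel_labels,
        "t0": rec.t0,
        "n_samples": rec.n_samples,
        "dtype": "<f4",
        "order": "channel-major",
    }
    meta_path.write_text(json.dumps(meta, indent=2))
    return bin_path, meta_path


def load_recording(prefix: str | Path) -> Recording:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    data = np.fromfile(prefix.with_suffix(".f32"), dtype="<f4")
    samples = data.reshape(len(meta["channels"]), meta["n_samples"]).astype(float)
    return Recording(samples, meta["sampling_rate"], meta["channels"], meta["t0"])


def save_recording_text(rec: Recording, path: str | Path, channel: int = 0) -> Path:
    """Two-column delimited text: time_s, value (single channel)."""
    path = Path(path)
    out = np.column_stack([rec.times(), rec.samples[channel]])
    np.savetxt(path, out, fmt="%.6f", header="time_s\tvalue", delimiter="\t")
    return path


def load_recording_text(path: str | Path, label: str = "ch0") -> Recording:
    data = np.loadtxt(path)
    t, v = data[:, 0], data[:, 1]
    fs = 1.0 / float(np.median(np.diff(t)))
    return Recording(v[None, :], fs, [label], t0=float(t[0]))


def save_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    obj = {
        "interictal_spike_times": truth.interictal_spike_times.tolist(),
        "seizure_intervals": [list(iv) for iv in truth.seizure_intervals],
        "per_seizure_spike_times": [np.asarray(s).tolist()
                                    for s in truth.per_seizure_spike_times],
        "light_intervals": [list(iv) for iv in truth.light_intervals],
        "applied_truncation_factor": truth.applied_truncation_factor,
        "duration": truth.duration,
        "flags": truth.flags,
    }
    path.write_text(json.dumps(obj, indent=2))
    return path


def load_truth(path: str | Path) -> GroundTruth:
    obj = json.loads(Path(path).read_text())
    return GroundTruth(
        np.asarray(obj["interictal_spike_times"], float),
        [tuple(iv) for iv in obj["seizure_intervals"]],
        [np.asarray(s, float) for s in obj["per_seizure_spike_times"]],
        [tuple(iv) for iv in obj["light_intervals"]],
        obj["applied_truncation_factor"],
        obj["duration"],
        obj.get("flags", {}),
    )


def save_traces(traces: np.ndarray, frame_times: np.ndarray,
                path: str | Path) -> Path:
    """Delimited matrix with a frame-time column (one column per cell)."""
    path = Path(path)
    df = pd.DataFrame(
        traces.T, columns=[f"cell{i}" for i in range(traces.shape[0])]
    )
    df.insert(0, "frame_time_s", frame_times)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def load_traces(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    ft = df.pop("frame_time_s").to_numpy()
    return df.to_numpy().T, ft


def save_movie(movie: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, movie.astype(np.float32))
    return path


def load_movie(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def save_masks(label_image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, label_image.astype(np.uint16))
    return path


def load_masks(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def save_onset_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(table.to_json(orient="records", indent=2))
    return path


def load_onset_table(path: str | Path) -> pd.DataFrame:
    return pd.read_json(Path(path))


def read_edf(path: str | Path) -> Recording:
    """Optional EDF ingestion (requires `mne`)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF ingestion requires the optional 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(raw.get_data(), float(raw.info["sfreq"]),
                     list(raw.ch_names), float(raw.first_time))
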