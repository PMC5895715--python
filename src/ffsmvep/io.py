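"""File round-tripping: recordings, sessions, signals, and frame stacks.

Delimited numeric text plus a JSON sidecar is the canonical interchange:
it is diffable, portable, and loses nothing at float repr precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .stimulus import FrameSequence, StimulusSignal
from .synth import MultichannelRecording

__all__ = [
    "save_recording",
    "load_recording",
    "save_session",
    "load_session",
    "save_signal",
    "load_signal",
    "save_frames",
]

_SIDE = ".json"


def save_recording(path, rec: MultichannelRecording) -> Path:
    """Write samples x channels matrix as TSV plus a JSON sidecar.

    The sidecar carries sampling rate, channel labels, onsets and the
    sample count (used to cross-check the matrix on load).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, rec.data, delimiter="\t", fmt="%.10g")
    sidecar = {
        "fs_hz": rec.fs_hz,
        "channel_labels": list(rec.channel_labels),
        "onsets": [[int(s), float(f)] for s, f in rec.onsets],
        "n_samples": rec.n_samples,
    }
    path.with_suffix(path.suffix + _SIDE).write_text(json.dumps(sidecar, indent=1))
    return path


def load_recording(path) -> MultichannelRecording:
    path = Path(path)
    side_path = path.with_suffix(path.suffix + _SIDE)
    if not side_path.exists():
        raise FileNotFoundError(f"missing sidecar {side_path}")
    try:
        side = json.loads(side_path.read_text())
    except json.JSONDecodeError as err:
        raise ValueError(f"malformed sidecar {side_path}: {err}") from err
    data = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    if data.shape[0] == 1 and len(side["channel_labels"]) == 1:
        data = data.T
    if "n_samples" in side and data.shape[0] != side["n_samples"]:
        raise ValueError(
            f"sidecar declares {side['n_samples']} samples but matrix has {data.shape[0]}"
        )
    return MultichannelRecording(
        data=data,
        fs_hz=float(side["fs_hz"]),
        channel_labels=tuple(side["channel_labels"]),
        onsets=[(int(s), float(f)) for s, f in side.get("onsets", [])],
    )


def save_session(directory, session, seed=None) -> Path:
    """One TSV per trial plus a JSON manifest (labels, fs, seed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (rec, f_true) in enumerate(session):
        name = f"trial_{i:04d}.tsv"
        save_recording(directory / name, rec)
        entries.append({"file": name, "true_freq_hz": float(f_true)})
    manifest = {
        "n_trials": len(entries),
        "trials": entries,
        "seed": seed,
    }
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def load_session(manifest_path) -> list[tuple[MultichannelRecording, float]]:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    out = []
    for entry in manifest["trials"]:
        rec = load_recording(manifest_path.parent / entry["file"])
        out.append((rec, float(entry["true_freq_hz"])))
    return out


def save_signal(path, sig: StimulusSignal) -> Path:
    """Two-column delimited text: time, value."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, np.column_stack([sig.t, sig.values]), delimiter="\t", fmt="%.10g")
    return path


def load_signal(path) -> StimulusSignal:
    arr = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    t, v = arr[:, 0], arr[:, 1]
    dt = np.diff(t)
    rate = 1.0 / float(np.median(dt)) if dt.size else 0.0
    return StimulusSignal(t, v, rate)


def save_frames(directory, seq: FrameSequence, fmt: str = "raw") -> Path:
    """Export a frame stack.

    ``fmt='raw'``: one flattened matrix file (frames x pixels) plus a JSON
    sidecar with the grid shape.  ``fmt='png'``: one PNG per frame
    (requires pillow).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if fmt == "raw":
        n, h, w = seq.frames.shape
        path = directory / "frames.tsv"
        np.savetxt(path, seq.frames.reshape(n, h * w), delimiter="\t", fmt="%.6g")
        meta = {
            "n_frames": n,
            "height": h,
            "width": w,
            "refresh_rate_hz": seq.refresh_rate_hz,
            "duration_s": seq.duration_s,
        }
        (directory / "frames.json").write_text(json.dumps(meta, indent=1))
        np.savetxt(
            directory / "displacement.tsv",
            np.column_stack([np.arange(n) / seq.refresh_rate_hz, seq.displacement_px]),
            delimiter="\t",
            fmt="%.10g",
        )
        return path
    if fmt == "png":
        from PIL import Image  # optional extra

        for i, frame in enumerate(seq.frames):
            img = Image.fromarray((np.clip(frame, 0, 1) * 255).astype(np.uint8))
            img.save(directory / f"frame_{i:04d}.png")
        return directory
    raise ValueError(f"unknown format {fmt!r}")
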