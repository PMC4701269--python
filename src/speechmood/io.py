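"""File formats: WAV input, the per-frame track file, segment TSV, feature CSV.

The track file (TrackFileV1) is the compact per-frame text export that a
phone-side analyser would upload instead of raw audio: one header line
(format version, sampling rate, hop) and one tab-separated row per frame
with the frame time (3 decimals), F0 in Hz (2 decimals, ``NA`` when the
frame carries no estimate) and pitch strength (3 decimals).  A 30-s
recording at a 10-ms hop fits in well under 75 kB, versus ~6 MB of
uncompressed 48-kHz/32-bit PCM.

Segment lists travel as BED-like 3-column TSV (start_s, end_s, label),
0-based half-open in seconds; features and summaries as headed CSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .features import FEATURE_NAMES, SUMMARY_STATS, FeatureSummary, SegmentFeatures
from .pitch import AudioSignal, PitchConfig, PitchTrack
from .segmentation import VoicedSegment

__all__ = [
    "NotWavFileError",
    "UnsupportedCodecError",
    "TruncatedPayloadError",
    "TrackParseError",
    "read_wav",
    "write_wav",
    "write_track",
    "read_track",
    "write_segments",
    "read_segments",
    "write_features",
    "read_features",
    "write_summary",
    "read_summary",
]

TRACK_MAGIC = "trackfile"
TRACK_VERSION = 1


class NotWavFileError(ValueError):
    """The file is not a RIFF/WAVE container."""


class UnsupportedCodecError(ValueError):
    """The WAV payload uses a codec outside PCM 16/24/32-bit int or 32-bit float."""


class TruncatedPayloadError(ValueError):
    """The WAV data chunk is shorter than its header declares."""


class TrackParseError(ValueError):
    """A track file row or header failed to parse."""


def read_wav(path: str | Path) -> AudioSignal:
    """Read a PCM WAV file into a mono, [-1, 1]-normalised signal.

    Multi-channel input is mixed down by per-sample arithmetic mean; the
    sampling rate comes from the header.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(12)
    if len(head) < 12 or head[:4] != b"RIFF" or head[8:12] != b"WAVE":
        raise NotWavFileError(f"{path} is not a RIFF/WAVE file")
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        msg = str(exc).lower()
        if "format" in msg or "compressed" in msg or "unsupported" in msg or "unknown wave" in msg:
            raise UnsupportedCodecError(f"{path}: {exc}") from exc
        raise TruncatedPayloadError(f"{path}: {exc}") from exc
    if data.size == 0:
        raise TruncatedPayloadError(f"{path}: empty data chunk")
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise UnsupportedCodecError(f"{path}: unsupported sample format {data.dtype}")
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioSignal(samples=np.asarray(samples, dtype=np.float64), rate=float(rate))


def write_wav(audio: AudioSignal, path: str | Path) -> None:
    """Write the signal as 32-bit float WAV."""
    wavfile.write(str(path), int(round(audio.rate)), audio.samples.astype(np.float32))


def write_track(track: PitchTrack, path: str | Path) -> None:
    """Write a TrackFileV1 file: header then time/f0/strength rows."""
    lines = [f"{TRACK_MAGIC}\tv{TRACK_VERSION}\trate={track.rate:g}\thop={track.hop:g}"]
    for t, f0, s in zip(track.times, track.f0, track.strength):
        f0_txt = "NA" if not np.isfinite(f0) else f"{f0:.2f}"
        lines.append(f"{t:.3f}\t{f0_txt}\t{s:.3f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_track(path: str | Path) -> PitchTrack:
    """Read a TrackFileV1 file back into a track."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise TrackParseError(f"{path}:1: empty file")
    head = lines[0].split("\t")
    if len(head) != 4 or head[0] != TRACK_MAGIC:
        raise TrackParseError(f"{path}:1: not a track file header")
    if head[1] != f"v{TRACK_VERSION}":
        raise TrackParseError(f"{path}:1: unsupported track file version {head[1]!r}")
    try:
        rate = float(head[2].split("=", 1)[1])
        hop = float(head[3].split("=", 1)[1])
    except (IndexError, ValueError) as exc:
        raise TrackParseError(f"{path}:1: malformed header: {exc}") from exc
    times, f0s, strengths = [], [], []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise TrackParseError(f"{path}:{ln}: expected 3 tab-separated fields")
        try:
            times.append(float(parts[0]))
            f0s.append(np.nan if parts[1] == "NA" else float(parts[1]))
            strengths.append(float(parts[2]))
        except ValueError as exc:
            raise TrackParseError(f"{path}:{ln}: {exc}") from exc
    return PitchTrack(
        times=np.array(times),
        f0=np.array(f0s),
        strength=np.array(strengths),
        rate=rate,
        hop=hop,
        config=PitchConfig(hop=hop),
    )


def write_segments(
    segments: Sequence[VoicedSegment], path: str | Path, label: str = "voiced"
) -> None:
    """Write segments as BED-like TSV: start_s, end_s, label (half-open seconds)."""
    lines = [f"{s.start:.3f}\t{s.end:.3f}\t{label}" for s in segments]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_segments(path: str | Path) -> list[VoicedSegment]:
    path = Path(path)
    segments = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{ln}: expected at least start and end columns")
        segments.append(VoicedSegment(start=float(parts[0]), end=float(parts[1])))
    return segments


def write_features(features: Sequence[SegmentFeatures], path: str | Path) -> None:
    """Per-segment feature CSV with header."""
    df = pd.DataFrame(
        {
            "segment_id": [f.segment_id for f in features],
            "start_s": [f.start for f in features],
            "end_s": [f.end for f in features],
            "n_frames": [f.n_frames for f in features],
            "mean_f0_hz": [f.mean_f0 for f in features],
            "std_f0_hz": [f.std_f0 for f in features],
            "jitter": [f.jitter for f in features],
        }
    )
    df.to_csv(path, index=False)


def read_features(path: str | Path) -> list[SegmentFeatures]:
    df = pd.read_csv(path)
    return [
        SegmentFeatures(
            segment_id=int(r.segment_id),
            mean_f0=float(r.mean_f0_hz),
            std_f0=float(r.std_f0_hz),
            jitter=float(r.jitter),
            n_frames=int(r.n_frames),
            start=float(r.start_s),
            end=float(r.end_s),
        )
        for r in df.itertuples()
    ]


def write_summary(summary: FeatureSummary, path: str | Path) -> None:
    """One-row CSV of the flattened summary plus the segment count."""
    row = summary.as_dict()
    row["n_segments"] = summary.n_segments
    pd.DataFrame([row]).to_csv(path, index=False)


def read_summary(path: str | Path) -> FeatureSummary:
    row = pd.read_csv(path).iloc[0]
    values = {
        stat: {feat: float(row[f"{stat}_{feat}"]) for feat in FEATURE_NAMES}
        for stat in SUMMARY_STATS
    }
    return FeatureSummary(values=values, n_segments=int(row["n_segments"]))
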