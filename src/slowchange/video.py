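"""Encoding, decoding and reproducibility manifests for stimulus videos.

The quality-control path needs bit-exact round-trips, so the default codec
(``rawvideo``) writes uncompressed 24-bit RGB frames into a plain AVI/RIFF
container with a constant frame rate — written and read natively, with no
external encoder.  ``ffv1`` (lossless) and ``h264`` (lossy deployment
preset, browser-playable) are also exposed; they dispatch to an ``ffmpeg``
binary on PATH and raise :class:`EncoderError` when none is installed.

Every encode writes a JSON *manifest* sidecar recording the full generation
configuration, schedule, codec and (for lossless runs) per-frame SHA-256
checksums, so any stimulus can be regenerated and verified bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import struct
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .errors import DecodeError, EncoderError
from .morph import FrameSequence

MANIFEST_SCHEMA_VERSION = 1

LOSSLESS_CODECS = ("rawvideo", "ffv1")
CODECS = ("rawvideo", "ffv1", "h264")


def frame_checksum(frame: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(frame).tobytes()).hexdigest()


@dataclass
class StimulusManifest:
    """Sidecar metadata that fully determines regeneration of a stimulus."""

    config: dict
    codec: str
    lossless: bool
    fps: int
    width: int
    height: int
    n_frames: int
    image_id: int | None = None
    color_labels: tuple[str, str] | None = None
    colors_rgb: dict | None = None
    schedule: list | None = None
    frame_checksums: list[str] | None = None
    schema_version: int = MANIFEST_SCHEMA_VERSION
    tool_version: str = __version__

    def to_dict(self) -> dict:
        d = {
            "schema_version": self.schema_version,
            "tool_version": self.tool_version,
            "config": self.config,
            "codec": self.codec,
            "lossless": self.lossless,
            "fps": self.fps,
            "width": self.width,
            "height": self.height,
            "n_frames": self.n_frames,
        }
        if self.image_id is not None:
            d["image_id"] = self.image_id
        if self.color_labels is not None:
            d["color_labels"] = list(self.color_labels)
        if self.colors_rgb is not None:
            d["colors_rgb"] = self.colors_rgb
        if self.schedule is not None:
            d["schedule"] = self.schedule
        if self.frame_checksums is not None:
            d["frame_checksums"] = self.frame_checksums
        return d

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusManifest":
        return cls(
            config=d["config"],
            codec=d["codec"],
            lossless=d["lossless"],
            fps=d["fps"],
            width=d["width"],
            height=d["height"],
            n_frames=d["n_frames"],
            image_id=d.get("image_id"),
            color_labels=tuple(d["color_labels"]) if "color_labels" in d else None,
            colors_rgb=d.get("colors_rgb"),
            schedule=d.get("schedule"),
            frame_checksums=d.get("frame_checksums"),
            schema_version=d.get("schema_version", MANIFEST_SCHEMA_VERSION),
            tool_version=d.get("tool_version", "unknown"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "StimulusManifest":
        return cls.from_dict(json.loads(Path(path).read_text()))


def manifest_path_for(video_path: str | Path) -> Path:
    p = Path(video_path)
    return p.with_name(p.name + ".manifest.json")


# ---------------------------------------------------------------------------
# native uncompressed-RGB AVI container
# ---------------------------------------------------------------------------

def _bgr_bottom_up(frame: np.ndarray) -> bytes:
    """One AVI 'DIB' frame: bottom-up row order, BGR, rows padded to 4 bytes."""
    h, w, _ = frame.shape
    stride = (w * 3 + 3) & ~3
    bgr = frame[::-1, :, ::-1]
    if stride == w * 3:
        return np.ascontiguousarray(bgr).tobytes()
    padded = np.zeros((h, stride), dtype=np.uint8)
    padded[:, : w * 3] = bgr.reshape(h, w * 3)
    return padded.tobytes()


def _chunk(fourcc: bytes, payload: bytes) -> bytes:
    data = struct.pack("<4sI", fourcc, len(payload)) + payload
    if len(payload) % 2:
        data += b"\x00"
    return data


def _list_chunk(list_type: bytes, payload: bytes) -> bytes:
    return _chunk(b"LIST", list_type + payload)


def write_avi(path: str | Path, seq: FrameSequence) -> None:
    """Write ``seq`` as an uncompressed RGB24 AVI at its constant frame rate."""
    if not seq.frames:
        raise ValueError("cannot encode an empty frame sequence")
    h, w, _ = seq.frames[0].shape
    n = len(seq.frames)
    stride = (w * 3 + 3) & ~3
    frame_bytes = stride * h

    avih = struct.pack(
        "<IIIIIIIIIIIIII",
        round(1_000_000 / seq.fps),  # microseconds per frame
        frame_bytes * seq.fps,       # max bytes/s
        0,                           # padding granularity
        0x10,                        # AVIF_HASINDEX
        n, 0, 1,                     # total frames, initial frames, streams
        frame_bytes,                 # suggested buffer size
        w, h, 0, 0, 0, 0,
    )
    strh = struct.pack(
        "<4s4sIHHIIIIIIIIhhhh",
        b"vids", b"DIB ",
        0, 0, 0, 0,
        1, seq.fps,                  # scale, rate -> fps = rate / scale
        0, n,
        frame_bytes, 0xFFFFFFFF, 0,
        0, 0, w, h,
    )
    strf = struct.pack(
        "<IiiHHIIiiII",
        40, w, h, 1, 24, 0,          # BITMAPINFOHEADER, BI_RGB
        frame_bytes, 0, 0, 0, 0,
    )
    hdrl = _list_chunk(
        b"hdrl",
        _chunk(b"avih", avih)
        + _list_chunk(b"strl", _chunk(b"strh", strh) + _chunk(b"strf", strf)),
    )

    movi_payload = b"movi"
    index = []
    for frame in seq.frames:
        if frame.shape != (h, w, 3):
            raise ValueError("all frames must share one shape")
        index.append((len(movi_payload), frame_bytes))
        movi_payload += _chunk(b"00db", _bgr_bottom_up(frame))
    movi = _chunk(b"LIST", movi_payload)

    idx1 = b"".join(
        struct.pack("<4sIII", b"00db", 0x10, off, size) for off, size in index
    )
    body = hdrl + movi + _chunk(b"idx1", idx1)
    riff = _chunk(b"RIFF", b"AVI " + body)
    Path(path).write_bytes(riff)


def _read_exact(data: bytes, offset: int, size: int, what: str) -> bytes:
    if offset + size > len(data):
        raise DecodeError(f"truncated AVI file: {what} extends past end of file")
    return data[offset : offset + size]


def read_avi(path: str | Path) -> FrameSequence:
    """Read an uncompressed RGB24 AVI written by :func:`write_avi` (or any
    BI_RGB 24-bit AVI with a constant frame rate)."""
    data = Path(path).read_bytes()
    if len(data) < 12 or data[:4] != b"RIFF" or data[8:12] != b"AVI ":
        raise DecodeError(f"{path} is not an AVI/RIFF file")
    riff_size = struct.unpack("<I", data[4:8])[0]
    if riff_size + 8 > len(data):
        raise DecodeError("truncated AVI file: RIFF size exceeds file length")

    fps = width = height = None
    declared_frames = None
    frames: list[np.ndarray] = []

    def walk(offset: int, end: int) -> None:
        nonlocal fps, width, height, declared_frames
        while offset + 8 <= end:
            fourcc, size = struct.unpack("<4sI", data[offset : offset + 8])
            payload_start = offset + 8
            payload = _read_exact(data, payload_start, size, fourcc.decode("latin1"))
            if fourcc == b"LIST":
                walk(payload_start + 4, payload_start + size)
            elif fourcc == b"strh":
                fcc_type, _, _, _, _, _, scale, rate, _, length = struct.unpack(
                    "<4s4sIHHIIIII", payload[:36]
                )
                if fcc_type == b"vids":
                    if scale == 0 or rate % scale:
                        raise DecodeError(
                            "unsupported format: non-integer or variable frame rate"
                        )
                    fps = rate // scale
                    declared_frames = length
            elif fourcc == b"strf" and width is None:
                _, w, h, _, bitcount, compression = struct.unpack("<IiiHHI", payload[:20])
                if compression != 0 or bitcount != 24:
                    raise DecodeError(
                        "unsupported AVI codec: only uncompressed 24-bit RGB "
                        "(BI_RGB) is read natively"
                    )
                width, height = w, abs(h)
            elif fourcc in (b"00db", b"00dc"):
                if width is None or height is None:
                    raise DecodeError("frame chunk before stream format header")
                stride = (width * 3 + 3) & ~3
                if size < stride * height:
                    raise DecodeError("truncated AVI file: short frame chunk")
                rows = np.frombuffer(payload[: stride * height], dtype=np.uint8)
                rows = rows.reshape(height, stride)[:, : width * 3]
                frames.append(rows.reshape(height, width, 3)[::-1, :, ::-1].copy())
            offset = payload_start + size + (size % 2)

    walk(12, 8 + riff_size)
    if fps is None or width is None:
        raise DecodeError("missing AVI stream headers")
    if declared_frames is not None and declared_frames != len(frames):
        raise DecodeError(
            f"truncated AVI file: header declares {declared_frames} frames, "
            f"found {len(frames)}"
        )
    return FrameSequence(fps=fps, frames=frames)


# ---------------------------------------------------------------------------
# ffmpeg-backed codecs (optional)
# ---------------------------------------------------------------------------

def ffmpeg_binary() -> str | None:
    return shutil.which("ffmpeg")


def _require_ffmpeg() -> str:
    binary = ffmpeg_binary()
    if binary is None:
        raise EncoderError(
            "no 'ffmpeg' binary on PATH; install ffmpeg to use the ffv1/h264 "
            "codecs, or use codec='rawvideo' (native, lossless)"
        )
    return binary


def _ffmpeg_encode(seq: FrameSequence, path: Path, codec: str) -> None:
    binary = _require_ffmpeg()
    h, w, _ = seq.frames[0].shape
    if codec == "ffv1":
        args = ["-c:v", "ffv1", "-level", "3"]
    else:
        args = ["-c:v", "libx264", "-preset", "medium", "-crf", "18",
                "-pix_fmt", "yuv420p"]
    cmd = [
        binary, "-y", "-f", "rawvideo", "-pix_fmt", "rgb24",
        "-s", f"{w}x{h}", "-r", str(seq.fps), "-i", "-",
        *args, str(path),
    ]
    raw = b"".join(np.ascontiguousarray(f).tobytes() for f in seq.frames)
    proc = subprocess.run(cmd, input=raw, capture_output=True)
    if proc.returncode != 0:
        raise EncoderError(f"ffmpeg failed: {proc.stderr.decode(errors='replace')[-500:]}")


def _ffmpeg_decode(path: Path) -> FrameSequence:
    binary = _require_ffmpeg()
    probe = shutil.which("ffprobe")
    if probe is None:
        raise EncoderError("no 'ffprobe' binary on PATH to read stream metadata")
    meta = subprocess.run(
        [probe, "-v", "error", "-select_streams", "v:0", "-show_entries",
         "stream=width,height,r_frame_rate,avg_frame_rate", "-of", "json", str(path)],
        capture_output=True,
    )
    if meta.returncode != 0:
        raise DecodeError(f"ffprobe failed on {path}")
    info = json.loads(meta.stdout)["streams"][0]
    num, den = info["r_frame_rate"].split("/")
    if info["avg_frame_rate"] not in ("0/0", info["r_frame_rate"]):
        raise DecodeError("unsupported format: variable frame rate")
    if int(num) % int(den):
        raise DecodeError("unsupported format: non-integer frame rate")
    fps = int(num) // int(den)
    w, h = info["width"], info["height"]
    proc = subprocess.run(
        [binary, "-v", "error", "-i", str(path), "-f", "rawvideo",
         "-pix_fmt", "rgb24", "-"],
        capture_output=True,
    )
    if proc.returncode != 0:
        raise DecodeError(f"ffmpeg failed to decode {path}")
    raw = np.frombuffer(proc.stdout, dtype=np.uint8)
    if raw.size % (w * h * 3):
        raise DecodeError("truncated video: partial frame in decoded stream")
    frames = list(raw.reshape(-1, h, w, 3))
    return FrameSequence(fps=fps, frames=frames)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def encode(
    seq: FrameSequence,
    path: str | Path,
    codec: str = "rawvideo",
    manifest_extra: dict | None = None,
    write_manifest: bool = True,
) -> tuple[Path, StimulusManifest]:
    """Encode a frame sequence and write its manifest sidecar.

    ``rawvideo`` (default) is the native lossless path; ``ffv1`` and
    ``h264`` require an ffmpeg binary.  Returns the video path and the
    manifest (checksums included only for lossless codecs).
    """
    if codec not in CODECS:
        raise ValueError(f"unknown codec {codec!r}; choose from {CODECS}")
    if not seq.frames:
        raise ValueError("cannot encode an empty frame sequence")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if codec == "rawvideo":
        write_avi(path, seq)
    else:
        _ffmpeg_encode(seq, path, codec)

    lossless = codec in LOSSLESS_CODECS
    extra = dict(manifest_extra or {})
    h, w, _ = seq.frames[0].shape
    manifest = StimulusManifest(
        config=extra.pop("config", {}),
        codec=codec,
        lossless=lossless,
        fps=seq.fps,
        width=w,
        height=h,
        n_frames=len(seq.frames),
        frame_checksums=[frame_checksum(f) for f in seq.frames] if lossless else None,
        **extra,
    )
    if write_manifest:
        manifest.save(manifest_path_for(path))
    return path, manifest


def decode(path: str | Path) -> FrameSequence:
    """Decode a video back to 8-bit RGB frames (fps from container metadata).

    Uncompressed AVI is read natively; anything else needs ffmpeg.
    """
    path = Path(path)
    if not path.exists():
        raise DecodeError(f"{path} does not exist")
    try:
        return read_avi(path)
    except DecodeError as native_err:
        if path.suffix.lower() == ".avi" and ffmpeg_binary() is None:
            raise native_err
        if ffmpeg_binary() is None:
            raise
        return _ffmpeg_decode(path)


def verify_checksums(seq: FrameSequence, manifest: StimulusManifest) -> bool:
    """True iff every frame matches the manifest's lossless checksums."""
    if manifest.frame_checksums is None:
        raise ValueError("manifest carries no checksums (lossy run)")
    if len(seq.frames) != len(manifest.frame_checksums):
        return False
    return all(
        frame_checksum(f) == c for f, c in zip(seq.frames, manifest.frame_checksums)
    )
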