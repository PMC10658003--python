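"""Reading and writing of annotations, prosody tracks, feature tables and config.

Supported external formats
--------------------------
* Praat TextGrid, both the *long* and the *short* text dialect (interval
  tiers only; one tier per speaker, a non-empty interval label marks
  speech).
* RTTM diarization files (``SPEAKER`` lines; start + duration convention).
* Delimited prosody-track files: CSV with columns ``time_s, pitch_hz,
  intensity_db`` where an empty field means missing (silent/unvoiced).
* Delimited feature tables (CSV, UTF-8, ``.`` decimal) with a fixed,
  documented column schema; round-trips are lossless to 12 significant
  digits.
* YAML run-configuration files.

Conventions: time is in seconds from conversation start; intervals are
half-open ``[start, end)``; frame ``i`` of a track sits at ``i *
frame_step_s``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from convosync.errors import ConfigError, ParseError, SchemaError, ValidationError

__all__ = [
    "AnnotationSet",
    "ProsodyTrack",
    "ConversationRecord",
    "ID_COLUMNS",
    "FEATURE_COLUMNS",
    "read_annotations",
    "write_textgrid",
    "write_rttm",
    "read_track",
    "write_track",
    "read_feature_table",
    "write_feature_table",
    "load_config",
    "get_logger",
]

TASKS = ("hobbies", "meal_planning")

Segment = tuple[float, float]


def get_logger(name: str = "convosync") -> logging.Logger:
    """Package logger with a line-oriented, levelled format."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


@dataclass
class AnnotationSet:
    """Speaking-instance annotations of one two-party conversation.

    Attributes
    ----------
    conversation_id : str
    task : str
        Conversation task label, e.g. ``"hobbies"`` or ``"meal_planning"``.
    speakers : tuple of two speaker ids
    segments : mapping speaker id -> list of (start_s, end_s)
        Per speaker: sorted, non-overlapping, within [0, duration_s].
    duration_s : float
        Total conversation length in seconds.
    """

    conversation_id: str
    task: str
    speakers: tuple[str, str]
    segments: dict[str, list[Segment]]
    duration_s: float

    def __post_init__(self) -> None:
        if len(self.speakers) != 2 or len(set(self.speakers)) != 2:
            raise ValidationError(
                f"{self.conversation_id}: exactly two distinct speakers required, "
                f"got {list(self.speakers)}"
            )
        if set(self.segments) != set(self.speakers):
            raise ValidationError(f"{self.conversation_id}: segments must cover both speakers")
        if self.duration_s <= 0:
            raise ValidationError(f"{self.conversation_id}: duration_s must be positive")
        for spk, segs in self.segments.items():
            prev_end = -np.inf
            for start, end in segs:
                if not (0.0 <= start < end <= self.duration_s + 1e-9):
                    raise ValidationError(
                        f"{self.conversation_id}/{spk}: bad interval ({start}, {end}) "
                        f"for duration {self.duration_s}"
                    )
                if start < prev_end:
                    raise ValidationError(
                        f"{self.conversation_id}/{spk}: intervals unsorted or overlapping "
                        f"near ({start}, {end})"
                    )
                prev_end = end

    def total_speech_s(self, speaker: str) -> float:
        return float(sum(e - s for s, e in self.segments[speaker]))


@dataclass
class ProsodyTrack:
    """Frame-level pitch and intensity for one speaker.

    Frame ``i`` covers time ``i * frame_step_s``; missing values (silence,
    unvoiced frames) are ``NaN``.  Pitch must be positive wherever present.
    """

    frame_step_s: float
    pitch_hz: np.ndarray
    intensity_db: np.ndarray

    def __post_init__(self) -> None:
        self.pitch_hz = np.asarray(self.pitch_hz, dtype=float)
        self.intensity_db = np.asarray(self.intensity_db, dtype=float)
        if self.frame_step_s <= 0:
            raise ValidationError("frame_step_s must be positive")
        if self.pitch_hz.shape != self.intensity_db.shape:
            raise ValidationError("pitch and intensity must have the same number of frames")
        voiced = np.isfinite(self.pitch_hz)
        if np.any(self.pitch_hz[voiced] <= 0):
            raise ValidationError("pitch_hz must be > 0 wherever present")

    @property
    def n_frames(self) -> int:
        return int(self.pitch_hz.shape[0])

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_step_s


@dataclass
class ConversationRecord:
    """One dyad x one task: annotations, per-speaker prosody tracks, metadata."""

    annotations: AnnotationSet
    tracks: dict[str, ProsodyTrack]
    dyad_id: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.tracks) != set(self.annotations.speakers):
            raise ValidationError("tracks must be provided for exactly the annotated speakers")


# ---------------------------------------------------------------------------
# annotation reading


def _merge_close(segments: list[Segment], min_gap_s: float) -> list[Segment]:
    """Merge adjacent same-speaker intervals separated by less than one frame."""
    merged: list[Segment] = []
    for start, end in sorted(segments):
        if merged and start - merged[-1][1] < min_gap_s:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def read_annotations(
    path: str | Path,
    dialect: str | None = None,
    *,
    task: str = "hobbies",
    duration_s: float | None = None,
    frame_step_s: float = 0.01,
) -> AnnotationSet:
    """Read speaking-instance annotations from a TextGrid or RTTM file.

    Parameters
    ----------
    path : file path
    dialect : {"textgrid", "rttm"}, optional
        Inferred from the file extension when omitted.
    task : task label stored on the returned :class:`AnnotationSet`.
    duration_s : total conversation length; defaults to the TextGrid's
        ``xmax`` or, for RTTM, the last segment end.
    frame_step_s : adjacent same-speaker intervals closer than this are
        merged (annotation tools often split on frame boundaries).
    """
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower()
        dialect = {"textgrid": "textgrid", ".textgrid": "textgrid", ".rttm": "rttm"}.get(
            suffix, "textgrid" if suffix == ".textgrid" else None
        )
        if dialect is None:
            raise ParseError(f"{path}: cannot infer dialect from extension {suffix!r}")
    if dialect == "textgrid":
        tiers, xmax = _parse_textgrid(path)
        speakers = list(tiers)
        if len(speakers) != 2:
            raise ValidationError(
                f"{path}: expected exactly 2 speaker tiers, found {len(speakers)} "
                f"({speakers})"
            )
        duration = duration_s if duration_s is not None else xmax
    elif dialect == "rttm":
        tiers, last_end = _parse_rttm(path)
        speakers = sorted(tiers)
        if len(speakers) != 2:
            raise ValidationError(
                f"{path}: expected exactly 2 speakers in RTTM, found {len(speakers)} "
                f"({speakers})"
            )
        duration = duration_s if duration_s is not None else last_end
    else:
        raise ParseError(f"unknown dialect {dialect!r}")
    segments = {spk: _merge_close(tiers[spk], frame_step_s) for spk in speakers}
    return AnnotationSet(
        conversation_id=path.stem,
        task=task,
        speakers=(speakers[0], speakers[1]),
        segments=segments,
        duration_s=float(duration),
    )


_NUM_RE = re.compile(r"-?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?")


def _parse_textgrid(path: Path) -> tuple[dict[str, list[Segment]], float]:
    """Parse a Praat TextGrid (long or short text form) into interval tiers."""
    lines = path.read_text(encoding="utf-8-sig").splitlines()
    if len(lines) < 2 or "ooTextFile" not in lines[0] or "TextGrid" not in lines[1]:
        raise ParseError(f"{path}:1: not a text TextGrid file")
    is_long = any(re.match(r"\s*xmin\s*=", ln) for ln in lines[2:8])
    if is_long:
        return _parse_textgrid_long(path, lines)
    return _parse_textgrid_short(path, lines)


def _parse_textgrid_long(path: Path, lines: list[str]) -> tuple[dict[str, list[Segment]], float]:
    kv = re.compile(r'^\s*([\w\[\]? ]+?)\s*=\s*(.*?)\s*$')
    tiers: dict[str, list[Segment]] = {}
    xmax_file = None
    cur_name: str | None = None
    cur_class = ""
    xmin = xmax = None
    for i, raw in enumerate(lines, start=1):
        m = kv.match(raw)
        if m is None:
            continue
        key, val = m.group(1), m.group(2)
        val = val.strip()
        try:
            if key == "xmax" and xmax_file is None and cur_name is None:
                xmax_file = float(val)
            elif key == "class":
                cur_class = val.strip('"')
                cur_name = None
            elif key == "name":
                cur_name = val.strip('"')
                if cur_class == "IntervalTier":
                    if cur_name in tiers:
                        raise ParseError(f"{path}:{i}: duplicate tier name {cur_name!r}")
                    tiers[cur_name] = []
                xmin = xmax = None
            elif key == "xmin" and cur_name is not None:
                xmin = float(val)
            elif key == "xmax" and cur_name is not None:
                xmax = float(val)
            elif key == "text" and cur_class == "IntervalTier" and cur_name is not None:
                if xmin is None or xmax is None:
                    raise ParseError(f"{path}:{i}: interval text before its bounds")
                if val.strip('"').strip():
                    tiers[cur_name].append((xmin, xmax))
                xmin = xmax = None
        except ValueError as exc:
            raise ParseError(f"{path}:{i}: {exc}") from exc
    if xmax_file is None:
        raise ParseError(f"{path}: missing file-level xmax")
    return tiers, xmax_file


def _parse_textgrid_short(path: Path, lines: list[str]) -> tuple[dict[str, list[Segment]], float]:
    # Short form: bare values in fixed order after the two header lines.
    tokens: list[tuple[int, str]] = []
    for i, raw in enumerate(lines[2:], start=3):
        s = raw.strip()
        if s:
            tokens.append((i, s))
    pos = 0

    def take() -> tuple[int, str]:
        nonlocal pos
        if pos >= len(tokens):
            raise ParseError(f"{path}:{tokens[-1][0] if tokens else 0}: truncated short TextGrid")
        tok = tokens[pos]
        pos += 1
        return tok

    def take_num() -> float:
        lineno, s = take()
        m = _NUM_RE.search(s)
        if m is None:
            raise ParseError(f"{path}:{lineno}: expected a number, got {s!r}")
        return float(m.group(0))

    def take_str() -> str:
        lineno, s = take()
        if not (s.startswith('"') and s.endswith('"')):
            raise ParseError(f"{path}:{lineno}: expected a quoted string, got {s!r}")
        return s[1:-1]

    take_num()  # file xmin
    xmax_file = take_num()
    take()  # <exists>
    n_tiers = int(take_num())
    tiers: dict[str, list[Segment]] = {}
    for _ in range(n_tiers):
        tier_class = take_str()
        name = take_str()
        take_num()  # tier xmin
        take_num()  # tier xmax
        n_items = int(take_num())
        if tier_class == "IntervalTier":
            if name in tiers:
                raise ParseError(f"{path}: duplicate tier name {name!r}")
            tiers[name] = []
            for _ in range(n_items):
                lo = take_num()
                hi = take_num()
                text = take_str()
                if text.strip():
                    tiers[name].append((lo, hi))
        else:  # PointTier: skip points (number + label)
            for _ in range(n_items):
                take_num()
                take_str()
    return tiers, xmax_file


def _parse_rttm(path: Path) -> tuple[dict[str, list[Segment]], float]:
    tiers: dict[str, list[Segment]] = {}
    last_end = 0.0
    for i, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(";;"):
            continue
        parts = line.split()
        if parts[0] != "SPEAKER":
            continue
        if len(parts) < 8:
            raise ParseError(f"{path}:{i}: RTTM SPEAKER line has {len(parts)} fields, need >= 8")
        try:
            start = float(parts[3])
            dur = float(parts[4])
        except ValueError as exc:
            raise ParseError(f"{path}:{i}: bad start/duration field: {exc}") from exc
        spk = parts[7]
        tiers.setdefault(spk, []).append((start, start + dur))
        last_end = max(last_end, start + dur)
    if not tiers:
        raise ParseError(f"{path}: no SPEAKER lines found")
    return tiers, last_end


def write_textgrid(annotations: AnnotationSet, path: str | Path) -> None:
    """Write an :class:`AnnotationSet` as a long-form text TextGrid.

    Speaking intervals get the label ``"speech"``; gaps are written as
    empty-label intervals so the tier tiles ``[0, duration_s]``.
    """
    path = Path(path)
    dur = annotations.duration_s
    out = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {dur:.6f}",
        "tiers? <exists>",
        f"size = {len(annotations.speakers)}",
        "item []:",
    ]
    for t, spk in enumerate(annotations.speakers, start=1):
        segs = annotations.segments[spk]
        intervals: list[tuple[float, float, str]] = []
        cursor = 0.0
        for s, e in segs:
            if s > cursor:
                intervals.append((cursor, s, ""))
            intervals.append((s, e, "speech"))
            cursor = e
        if cursor < dur:
            intervals.append((cursor, dur, ""))
        out += [
            f"    item [{t}]:",
            '        class = "IntervalTier"',
            f'        name = "{spk}"',
            "        xmin = 0",
            f"        xmax = {dur:.6f}",
            f"        intervals: size = {len(intervals)}",
        ]
        for k, (lo, hi, text) in enumerate(intervals, start=1):
            out += [
                f"        intervals [{k}]:",
                f"            xmin = {lo:.6f}",
                f"            xmax = {hi:.6f}",
                f'            text = "{text}"',
            ]
    path.write_text("\n".join(out) + "\n", encoding="utf-8")


def write_rttm(annotations: AnnotationSet, path: str | Path) -> None:
    path = Path(path)
    lines = []
    for spk in annotations.speakers:
        for s, e in annotations.segments[spk]:
            lines.append(
                f"SPEAKER {annotations.conversation_id} 1 {s:.3f} {e - s:.3f} "
                f"<NA> <NA> {spk} <NA> <NA>"
            )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# prosody track files


def write_track(track: ProsodyTrack, path: str | Path) -> None:
    """Write a frame table ``time_s,pitch_hz,intensity_db`` (empty = missing)."""
    df = pd.DataFrame(
        {
            "time_s": track.times_s,
            "pitch_hz": track.pitch_hz,
            "intensity_db": track.intensity_db,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_track(path: str | Path) -> ProsodyTrack:
    df = pd.read_csv(path)
    expected = ["time_s", "pitch_hz", "intensity_db"]
    if list(df.columns) != expected:
        raise SchemaError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ParseError(f"{path}: need at least two frames to infer the frame step")
    step = float(np.median(np.diff(t)))
    return ProsodyTrack(
        frame_step_s=step,
        pitch_hz=df["pitch_hz"].to_numpy(dtype=float),
        intensity_db=df["intensity_db"].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# feature tables

ID_COLUMNS = ["participant_id", "dyad_id", "conversation_id", "task"]

#: Individual features (one value per participant x task) followed by dyadic
#: features (shared by both members of the dyad in that task).
FEATURE_COLUMNS = [
    # individual
    "articulation_rate_sps",
    "n_pauses",
    "n_syllables",
    "phonation_time_s",
    "adapt_articulation",
    "adapt_intensity",
    "adapt_pitch",
    "var_intensity_db2",
    "var_pitch_hz2",
    # dyadic
    "n_turns",
    "silence_to_turn_ratio",
    "speech_rate_sps",
    "sync_intensity",
    "sync_pitch",
    "mean_turn_gap_s",
]

ALL_COLUMNS = ID_COLUMNS + FEATURE_COLUMNS


def _check_schema(columns: Iterable[str], where: str) -> None:
    cols = list(columns)
    unknown = [c for c in cols if c not in ALL_COLUMNS]
    if unknown:
        raise SchemaError(f"{where}: unknown feature-table column(s) {unknown}")
    missing = [c for c in ALL_COLUMNS if c not in cols]
    if missing:
        raise SchemaError(f"{where}: missing feature-table column(s) {missing}")


def write_feature_table(features: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as CSV (schema-checked, 12 significant digits)."""
    _check_schema(features.columns, str(path))
    features[ALL_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table; columns are matched by name, order-insensitive."""
    df = pd.read_csv(path)
    _check_schema(df.columns, str(path))
    return df[ALL_COLUMNS]


# ---------------------------------------------------------------------------
# configuration


def load_config(path: str | Path) -> dict:
    """Load a YAML run-configuration file into a plain mapping."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, Mapping):
        raise ConfigError(f"{path}: top level of the config must be a mapping")
    return dict(cfg)
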