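"""Per-speaker prosodic features and per-turn prosody summaries.

Individual features per participant and task: articulation rate (syllable
nuclei per second of phonation), number of pauses, number of syllables,
phonation time, pitch variance and intensity variance.  Turn-based
adaptation features are computed by :mod:`convosync.coordination` and
merged into the same record.

Syllable nuclei are detected as local intensity maxima within speaking
segments that exceed the median voiced intensity, are separated from the
previous nucleus by an intensity dip of at least 2 dB, and coincide with a
voiced (pitch-bearing) frame — the standard nucleus-counting recipe for
intensity tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from convosync.errors import UndefinedStatisticError
from convosync.io_formats import AnnotationSet, ProsodyTrack, Segment
from convosync.turn_structure import TurnSequence

__all__ = [
    "IndividualFeatures",
    "TurnProsody",
    "segment_frame_mask",
    "detect_syllable_nuclei",
    "individual_features",
    "turn_prosody",
]

#: minimum silent interval between own segments inside one turn to count as a pause
MIN_PAUSE_S = 0.3
#: required intensity dip between consecutive syllable nuclei
NUCLEUS_DIP_DB = 2.0


@dataclass
class IndividualFeatures:
    """Individual speech features of one participant in one task."""

    participant_id: str
    articulation_rate_sps: float
    n_pauses: int
    n_syllables: int
    phonation_time_s: float
    var_intensity_db2: float
    var_pitch_hz2: float
    adapt_articulation: float = field(default=float("nan"))
    adapt_intensity: float = field(default=float("nan"))
    adapt_pitch: float = field(default=float("nan"))


@dataclass
class TurnProsody:
    """Per-turn prosody summary (frames restricted to the turn's own segments)."""

    speaker_id: str
    mean_pitch_hz: float
    mean_intensity_db: float
    n_syllables: int
    articulation_rate_sps: float


def segment_frame_mask(n_frames: int, frame_step_s: float, segments: list[Segment]) -> np.ndarray:
    """Boolean mask of frames whose time ``i * frame_step_s`` lies in a segment."""
    mask = np.zeros(n_frames, dtype=bool)
    for start, end in segments:
        lo = int(np.ceil(start / frame_step_s - 1e-9))
        hi = int(np.ceil(end / frame_step_s - 1e-9))
        mask[max(lo, 0) : min(hi, n_frames)] = True
    return mask


def detect_syllable_nuclei(track: ProsodyTrack, segments: list[Segment]) -> list[float]:
    """Detect syllable nuclei inside the given speaking segments.

    A nucleus is a local intensity maximum that (a) exceeds the median
    intensity over voiced in-segment frames, (b) is preceded by a dip of at
    least ``NUCLEUS_DIP_DB`` below the peak since the previous nucleus (or
    the start of speech), and (c) falls on a voiced frame.

    Returns sorted nucleus times in seconds; empty if intensity is missing
    everywhere.
    """
    x = track.intensity_db
    in_seg = segment_frame_mask(track.n_frames, track.frame_step_s, segments)
    valid = in_seg & np.isfinite(x)
    voiced = valid & np.isfinite(track.pitch_hz)
    if not np.any(valid):
        return []
    threshold = float(np.median(x[voiced])) if np.any(voiced) else float(np.median(x[valid]))

    work = np.where(valid, x, -np.inf)
    left = np.empty_like(work)
    right = np.empty_like(work)
    left[0] = -np.inf
    left[1:] = work[:-1]
    right[-1] = -np.inf
    right[:-1] = work[1:]
    is_peak = valid & voiced & (work > threshold) & (work > left) & (work >= right)
    peak_idx = np.flatnonzero(is_peak)

    kept: list[int] = []
    prev = 0
    for i in peak_idx:
        between = np.flatnonzero(valid[prev:i]) + prev
        dip = work[between].min() if between.size else -np.inf
        if work[i] - dip >= NUCLEUS_DIP_DB:
            kept.append(int(i))
            prev = i
    return [i * track.frame_step_s for i in kept]


def _count_pauses(turns: TurnSequence, speaker: str) -> int:
    n = 0
    for turn in turns.turns:
        if turn.speaker_id != speaker:
            continue
        for (s0, e0), (s1, e1) in zip(turn.segments, turn.segments[1:]):
            if s1 - e0 >= MIN_PAUSE_S:
                n += 1
    return n


def individual_features(
    annotations: AnnotationSet,
    track: ProsodyTrack,
    turns: TurnSequence,
    speaker: str,
) -> IndividualFeatures:
    """Individual speech features of ``speaker`` for one conversation/task.

    Phonation time is the summed duration of the speaker's own segments;
    pauses are silent intervals >= 0.3 s between consecutive own segments
    inside one own turn; variances are sample variances over the speaker's
    own voiced (pitch) or speaking (intensity) frames across the whole task.
    """
    segments = annotations.segments[speaker]
    phonation = float(sum(e - s for s, e in segments))
    nuclei = detect_syllable_nuclei(track, segments)
    n_syll = len(nuclei)
    if phonation <= 0:
        raise UndefinedStatisticError(
            f"{speaker}: articulation rate undefined — zero phonation time"
        )
    in_seg = segment_frame_mask(track.n_frames, track.frame_step_s, segments)
    pitch = track.pitch_hz[in_seg & np.isfinite(track.pitch_hz)]
    intensity = track.intensity_db[in_seg & np.isfinite(track.intensity_db)]
    return IndividualFeatures(
        participant_id=speaker,
        articulation_rate_sps=n_syll / phonation,
        n_pauses=_count_pauses(turns, speaker),
        n_syllables=n_syll,
        phonation_time_s=phonation,
        var_intensity_db2=float(np.var(intensity, ddof=1)) if intensity.size > 1 else 0.0,
        var_pitch_hz2=float(np.var(pitch, ddof=1)) if pitch.size > 1 else 0.0,
    )


def turn_prosody(turns: TurnSequence, tracks: dict[str, ProsodyTrack]) -> list[TurnProsody]:
    """Per-turn mean pitch, mean intensity, syllable count and articulation rate.

    Nuclei are detected once per speaker over all of their segments and
    assigned to turns by time, so per-turn counts sum exactly to the
    speaker's total syllable count.  A turn with no voiced frame gets a
    missing (NaN) mean pitch.
    """
    nuclei_by_speaker = {
        spk: np.asarray(
            detect_syllable_nuclei(
                tracks[spk], [seg for t in turns.turns if t.speaker_id == spk for seg in t.segments]
            )
        )
        for spk in tracks
    }
    out: list[TurnProsody] = []
    for turn in turns.turns:
        track = tracks[turn.speaker_id]
        mask = segment_frame_mask(track.n_frames, track.frame_step_s, turn.segments)
        pitch = track.pitch_hz[mask]
        intensity = track.intensity_db[mask]
        pitch = pitch[np.isfinite(pitch)]
        intensity = intensity[np.isfinite(intensity)]
        times = nuclei_by_speaker[turn.speaker_id]
        if times.size:
            idx = np.rint(times / track.frame_step_s).astype(int)
            n_syll = int(np.sum(mask[idx]))
        else:
            n_syll = 0
        phonation = sum(e - s for s, e in turn.segments)
        out.append(
            TurnProsody(
                speaker_id=turn.speaker_id,
                mean_pitch_hz=float(np.mean(pitch)) if pitch.size else float("nan"),
                mean_intensity_db=float(np.mean(intensity)) if intensity.size else float("nan"),
                n_syllables=n_syll,
                articulation_rate_sps=n_syll / phonation if phonation > 0 else float("nan"),
            )
        )
    return out
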