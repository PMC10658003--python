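"""Turn segmentation and dyadic turn-taking features.

A *turn* is all speaking instances of one interactant until the end of the
speaking instance preceding the next speaking instance of the other
interactant.  Equivalently: order all speaking segments by onset; maximal
runs of consecutive same-speaker segments form turns, so speakers strictly
alternate by construction.

The *turn-taking gap* is signed: a turn's onset minus the previous turn's
offset, negative when the new speaker starts while the previous one is
still talking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from convosync.errors import UndefinedStatisticError
from convosync.io_formats import AnnotationSet, Segment

__all__ = ["Turn", "TurnSequence", "segment_turns", "dyadic_turn_features"]


@dataclass
class Turn:
    speaker_id: str
    start_s: float
    end_s: float
    segments: list[Segment]
    #: this turn's start minus the previous turn's end; None for the first turn
    gap_before_s: float | None = None


@dataclass
class TurnSequence:
    """Ordered, speaker-alternating turns of one conversation."""

    turns: list[Turn]
    duration_s: float
    #: total speech time: length of the union of all speaking segments
    talk_s: float = field(init=False)

    def __post_init__(self) -> None:
        self.talk_s = _union_length([s for t in self.turns for s in t.segments])

    @property
    def n_turns(self) -> int:
        return len(self.turns)

    @property
    def gaps(self) -> list[float]:
        return [t.gap_before_s for t in self.turns[1:]]

    @property
    def silence_s(self) -> float:
        return self.duration_s - self.talk_s


def _union_length(segments: list[Segment]) -> float:
    total = 0.0
    end = -np.inf
    for s, e in sorted(segments):
        if s > end:
            total += e - s
            end = e
        elif e > end:
            total += e - end
            end = e
    return total


def segment_turns(annotations: AnnotationSet) -> TurnSequence:
    """Segment a two-party conversation into alternating turns.

    Segments are walked in onset order; consecutive same-speaker segments
    coalesce into one turn.  When both speakers have a segment with the
    identical onset, the speaker holding the floor loses it (the new
    speaker's turn starts first) — a deterministic tie-break.

    An empty annotation yields an empty :class:`TurnSequence`; a
    single-speaker conversation yields one turn spanning that speaker's
    first to last segment.
    """
    pending: list[tuple[float, float, str]] = sorted(
        (s, e, spk) for spk, segs in annotations.segments.items() for s, e in segs
    )
    turns: list[Turn] = []
    current: Turn | None = None
    i = 0
    while i < len(pending):
        start, end, spk = pending[i]
        # tie-break: on identical onsets, the non-floor-holding speaker first
        if (
            current is not None
            and spk == current.speaker_id
            and i + 1 < len(pending)
            and pending[i + 1][0] == start
            and pending[i + 1][2] != spk
        ):
            pending[i], pending[i + 1] = pending[i + 1], pending[i]
            start, end, spk = pending[i]
        if current is not None and spk == current.speaker_id:
            current.segments.append((start, end))
            current.end_s = max(current.end_s, end)
        else:
            if current is not None:
                turns.append(current)
            current = Turn(speaker_id=spk, start_s=start, end_s=end, segments=[(start, end)])
        i += 1
    if current is not None:
        turns.append(current)
    for prev, turn in zip(turns, turns[1:]):
        turn.gap_before_s = turn.start_s - prev.end_s
    return TurnSequence(turns=turns, duration_s=annotations.duration_s)


def dyadic_turn_features(turns: TurnSequence, syllables_total: int) -> dict[str, float]:
    """Dyad-level turn-taking features of one conversation.

    Returns ``n_turns``, ``mean_gap_s`` (mean of signed turn-taking gaps),
    ``silence_to_turn_ratio`` (total non-speech time of the conversation
    divided by the summed turn spans) and ``speech_rate_sps``
    (``syllables_total`` over the total conversation duration — pauses
    included, unlike articulation rate).
    """
    turn_span_sum = sum(t.end_s - t.start_s for t in turns.turns)
    if turn_span_sum <= 0:
        raise UndefinedStatisticError("silence-to-turn ratio undefined: zero total turn duration")
    gaps = turns.gaps
    return {
        "n_turns": float(turns.n_turns),
        "mean_gap_s": float(np.mean(gaps)) if gaps else float("nan"),
        "silence_to_turn_ratio": turns.silence_s / turn_span_sum,
        "speech_rate_sps": syllables_total / turns.duration_s,
    }
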