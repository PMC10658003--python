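"""Feature-extraction pipeline: conversations -> per-individual feature table.

Ties the turn, prosody and coordination layers together: for every
conversation record it segments turns, summarizes per-turn prosody,
computes the individual features (including turn-based adaptation) and the
dyad-level features (turn counts, gaps, silence-to-turn ratio, speech rate,
WCLC synchrony of pitch and intensity), and emits one feature-table row per
participant and task.

WCLC synchrony operates on gap-bridged series (see
:func:`convosync.coordination.fill_missing`): single-speaker prosody is
undefined while the partner talks, and cross-partner correlation needs
gap-free series.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from convosync.coordination import (
    WclcConfig,
    compare_to_pseudo,
    fill_missing,
    pseudosynchrony,
    turn_adaptation,
    wclc_synchrony,
)
from convosync.errors import UndefinedStatisticError
from convosync.io_formats import ALL_COLUMNS, ConversationRecord, get_logger
from convosync.prosody import individual_features, turn_prosody
from convosync.turn_structure import dyadic_turn_features, segment_turns

__all__ = [
    "synchrony_series",
    "extract_conversation_features",
    "extract_corpus_features",
    "coordination_report",
]

logger = get_logger(__name__)


def synchrony_series(record: ConversationRecord, signal: str) -> dict[str, np.ndarray]:
    """Gap-bridged per-speaker series (``pitch`` or ``intensity``) for WCLC."""
    attr = {"pitch": "pitch_hz", "intensity": "intensity_db"}[signal]
    return {
        spk: fill_missing(getattr(track, attr)) for spk, track in record.tracks.items()
    }


def extract_conversation_features(
    record: ConversationRecord, wclc_cfg: WclcConfig | None = None
) -> pd.DataFrame:
    """Feature-table rows (one per participant) for one conversation.

    Statistics that are undefined on a given conversation (e.g. adaptation
    with too few turns, synchrony on a too-short recording) are recorded as
    missing rather than raised, so corpus extraction is robust to
    degenerate conversations.
    """
    wclc_cfg = wclc_cfg or WclcConfig()
    ann = record.annotations
    turns = segment_turns(ann)
    tp = turn_prosody(turns, record.tracks)

    sync: dict[str, float] = {}
    for signal in ("pitch", "intensity"):
        try:
            series = synchrony_series(record, signal)
            a, b = (series[s] for s in ann.speakers)
            step = record.tracks[ann.speakers[0]].frame_step_s
            sync[signal] = wclc_synchrony(a, b, step, wclc_cfg).summary
        except UndefinedStatisticError as exc:
            logger.warning("%s: %s synchrony undefined (%s)", ann.conversation_id, signal, exc)
            sync[signal] = float("nan")

    rows = []
    syllables_total = 0
    indiv = {}
    for spk in ann.speakers:
        feats = individual_features(ann, record.tracks[spk], turns, spk)
        try:
            adapt = turn_adaptation(tp, spk)
            feats.adapt_pitch = adapt["adapt_pitch"]
            feats.adapt_intensity = adapt["adapt_intensity"]
            feats.adapt_articulation = adapt["adapt_articulation"]
        except UndefinedStatisticError as exc:
            logger.warning("%s/%s: adaptation undefined (%s)", ann.conversation_id, spk, exc)
        indiv[spk] = feats
        syllables_total += feats.n_syllables
    dyadic = dyadic_turn_features(turns, syllables_total)
    for spk in ann.speakers:
        feats = indiv[spk]
        rows.append(
            {
                "participant_id": spk,
                "dyad_id": record.dyad_id,
                "conversation_id": ann.conversation_id,
                "task": ann.task,
                "articulation_rate_sps": feats.articulation_rate_sps,
                "n_pauses": feats.n_pauses,
                "n_syllables": feats.n_syllables,
                "phonation_time_s": feats.phonation_time_s,
                "adapt_articulation": feats.adapt_articulation,
                "adapt_intensity": feats.adapt_intensity,
                "adapt_pitch": feats.adapt_pitch,
                "var_intensity_db2": feats.var_intensity_db2,
                "var_pitch_hz2": feats.var_pitch_hz2,
                "n_turns": dyadic["n_turns"],
                "silence_to_turn_ratio": dyadic["silence_to_turn_ratio"],
                "speech_rate_sps": dyadic["speech_rate_sps"],
                "sync_intensity": sync["intensity"],
                "sync_pitch": sync["pitch"],
                "mean_turn_gap_s": dyadic["mean_gap_s"],
            }
        )
    return pd.DataFrame(rows)


def extract_corpus_features(
    records: list[ConversationRecord], wclc_cfg: WclcConfig | None = None
) -> pd.DataFrame:
    """Feature table for a whole corpus (one row per participant x task)."""
    parts = [extract_conversation_features(r, wclc_cfg) for r in records]
    return pd.concat(parts, ignore_index=True)[ALL_COLUMNS]


def coordination_report(
    records: list[ConversationRecord],
    signal: str = "intensity",
    n_surrogates: int = 100,
    seed: int = 0,
    wclc_cfg: WclcConfig | None = None,
) -> tuple[pd.DataFrame, float]:
    """Observed WCLC synchrony vs. its pseudosynchrony null, per conversation.

    Returns a table with one row per conversation (observed value and
    surrogate mean) and the one-sided paired log Bayes factor comparing
    observed values against their matched pseudo values across
    conversations.
    """
    wclc_cfg = wclc_cfg or WclcConfig()
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = seed_seq.generate_state(len(records))
    rows = []
    for rec, child in zip(records, child_seeds):
        series = synchrony_series(rec, signal)
        a, b = (series[s] for s in rec.annotations.speakers)
        step = rec.tracks[rec.annotations.speakers[0]].frame_step_s
        res = pseudosynchrony(a, b, step, wclc_cfg, n_surrogates=n_surrogates, seed=int(child))
        rows.append(
            {
                "conversation_id": rec.annotations.conversation_id,
                "dyad_id": rec.dyad_id,
                "task": rec.annotations.task,
                "signal": signal,
                "observed": res.observed,
                "pseudo_mean": res.surrogate_mean,
            }
        )
    table = pd.DataFrame(rows)
    log_bf = compare_to_pseudo(table["observed"], table["pseudo_mean"])
    return table, log_bf
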