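"""Synthetic dyadic-conversation generator with known ground truth.

Emulates corpora of two ~10-minute conversations per dyad (tasks *hobbies*
and *meal planning*) between either a mixed dyad (one autistic, one
non-autistic speaker) or a non-autistic dyad:

* an alternating turn skeleton with log-normal turn lengths (median 1.8 s)
  and inter-turn gaps (median 0.2 s), plus within-turn pauses that split
  turns into speaking segments;
* frame-level prosody inside own segments: pitch = speaker base (drawn from
  a bimodal, voice-register-like range) + smooth AR(1) noise; intensity =
  base + AR(1) noise + syllable-scale intensity bumps placed at the
  speaker's articulation rate;
* turn-level prosody offsets that follow the partner's previous turn with
  a configurable adaptation gain (plants turn-based adaptation);
* a lagged linear cross-partner intensity (and optionally pitch) influence
  that plants WCLC-detectable synchrony, with a dyad-type-specific gain;
* configurable group effects via multipliers relative to the non-autistic
  baseline (autistic speakers: lower pitch/intensity variance and
  articulation rate; mixed dyads: inflated gaps, within-turn silence and
  intensity coupling).  Setting every multiplier to 1 yields the null
  world.

Output is fully deterministic given ``seed`` (NumPy ``default_rng``,
PCG64, with fixed per-dyad/per-task spawn keys).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from convosync.coordination import fill_missing
from convosync.errors import ConfigError, ValidationError
from convosync.io_formats import TASKS, AnnotationSet, ConversationRecord, ProsodyTrack
from convosync.prosody import segment_frame_mask

__all__ = ["EffectMultipliers", "GeneratorConfig", "GroundTruth", "generate_corpus",
           "planted_effect_report"]


@dataclass(frozen=True)
class EffectMultipliers:
    """Group-effect multipliers relative to the non-autistic baseline.

    A multiplier of 1 removes the corresponding effect; the defaults point
    in the directions reported for conversational speech in autism research
    (lower pitch/intensity variance and articulation rate in autistic
    speakers; more silence and stronger intensity coupling in mixed dyads).
    Magnitudes are configuration, not empirical claims.
    """

    autistic_pitch_sd: float = 0.7
    autistic_intensity_sd: float = 0.85
    autistic_articulation: float = 0.85
    mixed_gap_inflation: float = 1.4
    mixed_silence_inflation: float = 1.4
    mixed_intensity_coupling: float = 2.0

    @classmethod
    def null_world(cls) -> "EffectMultipliers":
        return cls(1.0, 1.0, 1.0, 1.0, 1.0, 1.0)

    @classmethod
    def strong(cls) -> "EffectMultipliers":
        return cls(0.45, 0.55, 0.6, 2.2, 2.0, 4.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """All tunable knobs of the synthetic corpus generator."""

    n_mixed_dyads: int = 10
    n_nonautistic_dyads: int = 10
    duration_s: float = 600.0
    tasks: tuple[str, ...] = TASKS
    frame_step_s: float = 0.01
    # turn skeleton (log-normal, parameterized by median + log-sd)
    turn_median_s: float = 1.8
    turn_log_sd: float = 0.6
    gap_median_s: float = 0.2
    gap_log_sd: float = 0.7
    within_turn_pause_rate: float = 0.15  # expected pauses per second of turn
    pause_median_s: float = 0.5
    pause_log_sd: float = 0.4
    # prosody baselines and frame noise
    pitch_base_ranges: tuple[tuple[float, float], tuple[float, float]] = (
        (100.0, 140.0),
        (180.0, 220.0),
    )
    pitch_sd_hz: float = 20.0
    intensity_base_db: float = 60.0
    intensity_base_sd_db: float = 3.0
    intensity_sd_db: float = 1.0
    articulation_rate_sps: float = 4.0
    ar_coef: float = 0.95
    syllable_bump_db: float = 6.0
    syllable_width_s: float = 0.20
    # turn-level dynamics (adaptation) and frame-level coupling (synchrony)
    turn_level_sd: tuple[float, float, float] = (10.0, 1.2, 0.35)  # pitch, intensity, artic
    adaptation_gain: tuple[float, float, float] = (0.3, 0.3, 0.3)
    coupling_lag_s: float = 1.0
    intensity_coupling_gain: float = 0.25
    pitch_coupling_gain: float = 0.15
    effects: EffectMultipliers = field(default_factory=EffectMultipliers)
    seed: int = 0

    def __post_init__(self) -> None:
        positives = [
            self.duration_s, self.frame_step_s, self.turn_median_s, self.turn_log_sd,
            self.gap_median_s, self.gap_log_sd, self.pause_median_s, self.pause_log_sd,
            self.pitch_sd_hz, self.intensity_sd_db, self.articulation_rate_sps,
        ]
        if any(v <= 0 for v in positives):
            raise ConfigError("durations, distribution parameters and rates must be positive")
        if self.coupling_lag_s < 0:
            raise ConfigError("coupling_lag_s must be >= 0")
        if self.within_turn_pause_rate < 0:
            raise ConfigError("within_turn_pause_rate must be >= 0")
        if not 0 <= self.ar_coef < 1:
            raise ConfigError("ar_coef must lie in [0, 1)")
        if self.n_mixed_dyads < 0 or self.n_nonautistic_dyads < 0:
            raise ConfigError("dyad counts must be non-negative")

    def with_effects(self, effects: EffectMultipliers) -> "GeneratorConfig":
        return replace(self, effects=effects)


@dataclass
class GroundTruth:
    """Planted per-participant groups, dyad types and realized parameters."""

    participants: pd.DataFrame  # participant_id, dyad_id, group, realized params
    dyads: pd.DataFrame  # dyad_id, dyad_type

    def dyad_types(self) -> dict[str, str]:
        return dict(zip(self.dyads["dyad_id"], self.dyads["dyad_type"]))

    def __post_init__(self) -> None:
        merged = self.participants.merge(self.dyads, on="dyad_id")
        counts = (
            merged.assign(aut=lambda d: d["group"] == "autistic")
            .groupby(["dyad_id", "dyad_type"])["aut"]
            .sum()
            .reset_index()
        )
        bad_mixed = counts[(counts["dyad_type"] == "mixed") & (counts["aut"] != 1)]
        bad_na = counts[(counts["dyad_type"] == "non_autistic") & (counts["aut"] != 0)]
        if len(bad_mixed) or len(bad_na):
            raise ValidationError("dyad composition violates mixed/non-autistic definition")


@dataclass
class _Speaker:
    participant_id: str
    group: str
    pitch_base_hz: float
    pitch_sd_hz: float
    intensity_base_db: float
    intensity_sd_db: float
    articulation_rate_sps: float


def _lognormal(rng: np.random.Generator, median: float, log_sd: float, size=None):
    return rng.lognormal(mean=math.log(median), sigma=log_sd, size=size)


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    innov = rng.normal(0.0, sd * math.sqrt(1.0 - phi * phi), size=n)
    prev = rng.normal(0.0, sd)
    y, _ = signal.lfilter([1.0], [1.0, -phi], innov, zi=np.asarray([phi * prev]))
    return y


def _draw_speakers(
    rng: np.random.Generator, cfg: GeneratorConfig, dyad_id: str, dyad_type: str
) -> list[_Speaker]:
    eff = cfg.effects
    groups = ["non_autistic", "non_autistic"]
    if dyad_type == "mixed":
        groups[int(rng.integers(2))] = "autistic"
    speakers = []
    for k, group in enumerate(groups):
        lo, hi = cfg.pitch_base_ranges[int(rng.integers(len(cfg.pitch_base_ranges)))]
        autistic = group == "autistic"
        speakers.append(
            _Speaker(
                participant_id=f"{dyad_id}_p{k + 1}",
                group=group,
                pitch_base_hz=float(rng.uniform(lo, hi)),
                pitch_sd_hz=cfg.pitch_sd_hz * (eff.autistic_pitch_sd if autistic else 1.0),
                intensity_base_db=float(
                    cfg.intensity_base_db + rng.normal(0.0, cfg.intensity_base_sd_db)
                ),
                intensity_sd_db=cfg.intensity_sd_db
                * (eff.autistic_intensity_sd if autistic else 1.0),
                articulation_rate_sps=cfg.articulation_rate_sps
                * (eff.autistic_articulation if autistic else 1.0),
            )
        )
    return speakers


def _turn_skeleton(
    rng: np.random.Generator, cfg: GeneratorConfig, mixed: bool
) -> list[tuple[int, float, float]]:
    """Alternating (speaker_index, start, end) turn spans filling the timeline."""
    eff = cfg.effects
    gap_median = cfg.gap_median_s * (eff.mixed_gap_inflation if mixed else 1.0)
    turns = []
    t = float(_lognormal(rng, gap_median, cfg.gap_log_sd))
    cur = int(rng.integers(2))
    while t < cfg.duration_s - 0.5:
        remaining = cfg.duration_s - t
        if remaining < 0.2:
            break
        length = float(_lognormal(rng, cfg.turn_median_s, cfg.turn_log_sd))
        length = min(max(length, 0.2), remaining)
        turns.append((cur, t, t + length))
        gap = float(_lognormal(rng, gap_median, cfg.gap_log_sd))
        t += length + gap
        cur = 1 - cur
    return turns


def _carve_pauses(
    rng: np.random.Generator, cfg: GeneratorConfig, start: float, end: float, mixed: bool
) -> list[tuple[float, float]]:
    """Split a turn span into speaking segments by carving out silent pauses."""
    eff = cfg.effects
    length = end - start
    n_pauses = int(rng.poisson(cfg.within_turn_pause_rate * length))
    if n_pauses == 0 or length < 1.0:
        return [(start, end)]
    pause_median = cfg.pause_median_s * (eff.mixed_silence_inflation if mixed else 1.0)
    cuts = []
    for pos in np.sort(rng.uniform(start + 0.2, end - 0.2, size=n_pauses)):
        dur = float(_lognormal(rng, pause_median, cfg.pause_log_sd))
        cuts.append((float(pos), min(float(pos) + dur, end - 0.1)))
    segments: list[tuple[float, float]] = []
    cursor = start
    for c0, c1 in cuts:
        if c0 > cursor + 0.08:
            segments.append((cursor, c0))
        cursor = max(cursor, c1)
    if end > cursor + 0.08:
        segments.append((cursor, end))
    return segments or [(start, end)]


def _simulate_conversation(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    dyad_id: str,
    dyad_type: str,
    task: str,
    speakers: list[_Speaker],
) -> ConversationRecord:
    mixed = dyad_type == "mixed"
    eff = cfg.effects
    step = cfg.frame_step_s
    n_frames = int(round(cfg.duration_s / step))
    skeleton = _turn_skeleton(rng, cfg, mixed)

    # per-turn prosody offsets with cross-turn adaptation (alternation makes
    # the previous turn the partner's, so the chain plants adaptation)
    g_pitch, g_int, g_artic = cfg.adaptation_gain
    s_pitch, s_int, s_artic = cfg.turn_level_sd
    prev = np.zeros(3)
    turn_devs = []
    for _ in skeleton:
        dev = np.array([g_pitch, g_int, g_artic]) * prev + rng.normal(
            0.0, [s_pitch, s_int, s_artic]
        )
        turn_devs.append(dev)
        prev = dev

    segments: dict[int, list[tuple[float, float]]] = {0: [], 1: []}
    turn_of_frame = {0: np.full(n_frames, -1), 1: np.full(n_frames, -1)}
    nuclei: dict[int, list[float]] = {0: [], 1: []}
    for ti, (spk, t0, t1) in enumerate(skeleton):
        segs = _carve_pauses(rng, cfg, t0, t1, mixed)
        segments[spk].extend(segs)
        mask = segment_frame_mask(n_frames, step, segs)
        turn_of_frame[spk][mask] = ti
        rate = max(0.8, speakers[spk].articulation_rate_sps + turn_devs[ti][2])
        for s0, s1 in segs:
            t = s0 + float(rng.uniform(0.2, 1.2)) / rate
            while t < s1 - 0.03:
                nuclei[spk].append(t)
                t += float(rng.uniform(0.7, 1.3)) / rate

    pitch: dict[int, np.ndarray] = {}
    intensity: dict[int, np.ndarray] = {}
    bump_half = max(1, int(round(cfg.syllable_width_s / step / 2)))
    for spk in (0, 1):
        sp = speakers[spk]
        # reduced intensity variability also flattens the syllabic modulation
        bump = (
            cfg.syllable_bump_db
            * (sp.intensity_sd_db / cfg.intensity_sd_db)
            * np.hanning(2 * bump_half + 1)
        )
        tof = turn_of_frame[spk]
        speaking = tof >= 0
        dev_pitch = np.zeros(n_frames)
        dev_int = np.zeros(n_frames)
        if skeleton:
            devs = np.asarray(turn_devs)
            dev_pitch[speaking] = devs[tof[speaking], 0]
            dev_int[speaking] = devs[tof[speaking], 1]
        p = sp.pitch_base_hz + dev_pitch + _ar1(rng, n_frames, cfg.ar_coef, sp.pitch_sd_hz)
        i = sp.intensity_base_db + dev_int + _ar1(rng, n_frames, cfg.ar_coef, sp.intensity_sd_db)
        for t in nuclei[spk]:
            c = int(round(t / step))
            lo, hi = max(0, c - bump_half), min(n_frames, c + bump_half + 1)
            i[lo:hi] += bump[lo - (c - bump_half) : hi - (c - bump_half)]
        p[~speaking] = np.nan
        i[~speaking] = np.nan
        np.clip(p, 40.0, None, out=p)
        pitch[spk] = p
        intensity[spk] = i

    # lagged cross-partner coupling planted on the gap-bridged partner series
    lag_frames = int(round(cfg.coupling_lag_s / step))
    gain_int = cfg.intensity_coupling_gain * (eff.mixed_intensity_coupling if mixed else 1.0)
    gain_pitch = cfg.pitch_coupling_gain

    def shifted_dev(x: np.ndarray, base: float) -> np.ndarray:
        if not np.isfinite(x).any():
            return np.zeros(n_frames)
        s = fill_missing(x) - base
        if lag_frames == 0:
            return s
        return np.concatenate([np.full(lag_frames, s[0]), s[:-lag_frames]])

    if skeleton:
        partner_int = {spk: shifted_dev(intensity[1 - spk], speakers[1 - spk].intensity_base_db)
                       for spk in (0, 1)}
        partner_pitch = {spk: shifted_dev(pitch[1 - spk], speakers[1 - spk].pitch_base_hz)
                         for spk in (0, 1)}
        for spk in (0, 1):
            speaking = turn_of_frame[spk] >= 0
            intensity[spk][speaking] += gain_int * partner_int[spk][speaking]
            pitch[spk][speaking] += gain_pitch * partner_pitch[spk][speaking]
            np.clip(pitch[spk], 40.0, None, out=pitch[spk])

    conv_id = f"{dyad_id}_{task}"
    annotations = AnnotationSet(
        conversation_id=conv_id,
        task=task,
        speakers=(speakers[0].participant_id, speakers[1].participant_id),
        segments={
            speakers[spk].participant_id: sorted(segments[spk]) for spk in (0, 1)
        },
        duration_s=cfg.duration_s,
    )
    tracks = {
        speakers[spk].participant_id: ProsodyTrack(
            frame_step_s=step, pitch_hz=pitch[spk], intensity_db=intensity[spk]
        )
        for spk in (0, 1)
    }
    return ConversationRecord(
        annotations=annotations,
        tracks=tracks,
        dyad_id=dyad_id,
        metadata={"dyad_type": dyad_type, "n_nuclei": {speakers[k].participant_id: len(nuclei[k]) for k in (0, 1)}},
    )


def generate_corpus(cfg: GeneratorConfig) -> tuple[list[ConversationRecord], GroundTruth]:
    """Generate one conversation per dyad and task, plus the ground truth.

    Deterministic given ``cfg.seed``: every dyad/task pair draws from its
    own PCG64 stream spawned from fixed keys, so corpora are reproducible
    and dyads are statistically independent.
    """
    records: list[ConversationRecord] = []
    part_rows = []
    dyad_rows = []
    dyad_types = ["mixed"] * cfg.n_mixed_dyads + ["non_autistic"] * cfg.n_nonautistic_dyads
    for d, dyad_type in enumerate(dyad_types):
        dyad_id = f"dyad{d:03d}"
        rng_traits = np.random.default_rng([cfg.seed, d, 10_000])
        speakers = _draw_speakers(rng_traits, cfg, dyad_id, dyad_type)
        dyad_rows.append({"dyad_id": dyad_id, "dyad_type": dyad_type})
        for sp in speakers:
            part_rows.append(
                {
                    "participant_id": sp.participant_id,
                    "dyad_id": dyad_id,
                    "group": sp.group,
                    "pitch_base_hz": sp.pitch_base_hz,
                    "pitch_sd_hz": sp.pitch_sd_hz,
                    "intensity_base_db": sp.intensity_base_db,
                    "intensity_sd_db": sp.intensity_sd_db,
                    "articulation_rate_sps": sp.articulation_rate_sps,
                }
            )
        for ti, task in enumerate(cfg.tasks):
            rng = np.random.default_rng([cfg.seed, d, ti])
            records.append(_simulate_conversation(rng, cfg, dyad_id, dyad_type, task, speakers))
    return records, GroundTruth(
        participants=pd.DataFrame(part_rows), dyads=pd.DataFrame(dyad_rows)
    )


#: planted effects checked by the recovery report: feature, level, contrast
_PLANTED = [
    ("articulation_rate_sps", "individual", ("autistic", "non_autistic")),
    ("var_pitch_hz2", "individual", ("autistic", "non_autistic")),
    ("var_intensity_db2", "individual", ("autistic", "non_autistic")),
    ("mean_turn_gap_s", "dyadic", ("mixed", "non_autistic")),
    ("silence_to_turn_ratio", "dyadic", ("mixed", "non_autistic")),
    ("sync_intensity", "dyadic", ("mixed", "non_autistic")),
]


def planted_effect_report(ground_truth: GroundTruth, feature_table: pd.DataFrame) -> pd.DataFrame:
    """Empirical standardized group differences for each planted effect.

    For individual features the contrast is autistic minus non-autistic
    participants; for dyadic features, mixed minus non-autistic dyads.
    Values are Cohen's d on per-participant (resp. per-dyad) means over
    tasks.  Raises on id mismatches between features and ground truth.
    """
    feats = feature_table.merge(
        ground_truth.participants[["participant_id", "group"]], on="participant_id", how="left"
    ).merge(ground_truth.dyads, on="dyad_id", how="left")
    if feats["group"].isna().any() or feats["dyad_type"].isna().any():
        raise ValidationError("feature table contains ids unknown to the ground truth")
    rows = []
    for feature, level, (pos, neg) in _PLANTED:
        if level == "individual":
            per = feats.groupby(["participant_id", "group"])[feature].mean().reset_index()
            key = "group"
        else:
            per = feats.groupby(["dyad_id", "dyad_type"])[feature].mean().reset_index()
            key = "dyad_type"
        a = per.loc[per[key] == pos, feature].to_numpy()
        b = per.loc[per[key] == neg, feature].to_numpy()
        pooled = math.sqrt(
            ((a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1))
            / (a.size + b.size - 2)
        )
        d = float((a.mean() - b.mean()) / pooled) if pooled > 0 else 0.0
        rows.append(
            {
                "feature": feature,
                "contrast": f"{pos} - {neg}",
                "cohens_d": d,
                "sign": int(np.sign(d)),
            }
        )
    return pd.DataFrame(rows)
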