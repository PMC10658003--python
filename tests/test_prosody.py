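import numpy as np
import pytest

from convosync.errors import UndefinedStatisticError
from convosync.io_formats import AnnotationSet, ProsodyTrack
from convosync.prosody import detect_syllable_nuclei, individual_features, turn_prosody
from convosync.synthetic_data import GeneratorConfig, generate_corpus
from convosync.turn_structure import segment_turns

STEP = 0.01


def bumpy_track(n=1000, base=60.0, bump_db=4.0, centers=(200, 500, 800), voiced=True):
    intensity = np.full(n, base)
    for c in centers:
        intensity[c - 8 : c + 9] += bump_db * np.hanning(17)
    pitch = np.full(n, 120.0) if voiced else np.full(n, np.nan)
    return ProsodyTrack(frame_step_s=STEP, pitch_hz=pitch, intensity_db=intensity)


def test_three_clear_bumps_give_three_nuclei():
    track = bumpy_track(bump_db=4.0)
    nuclei = detect_syllable_nuclei(track, [(0.0, 10.0)])
    assert len(nuclei) == 3
    assert nuclei == pytest.approx([2.0, 5.0, 8.0], abs=0.02)


def test_shallow_bumps_below_dip_criterion_are_rejected():
    track = bumpy_track(bump_db=1.0)
    assert detect_syllable_nuclei(track, [(0.0, 10.0)]) == []


def test_unvoiced_peaks_are_not_nuclei():
    track = bumpy_track(bump_db=4.0, voiced=False)
    assert detect_syllable_nuclei(track, [(0.0, 10.0)]) == []


def test_all_missing_intensity_gives_empty_list():
    track = ProsodyTrack(STEP, np.full(100, np.nan), np.full(100, np.nan))
    assert detect_syllable_nuclei(track, [(0.0, 1.0)]) == []


def test_generator_roundtrip_articulation_rate_within_ten_percent():
    """A synthetic speaker at 4.0 syll/s phonation is detected near 4.0."""
    cfg = GeneratorConfig(
        n_mixed_dyads=0, n_nonautistic_dyads=2, duration_s=120.0, tasks=("hobbies",),
        turn_level_sd=(0.0, 0.0, 0.0), adaptation_gain=(0.0, 0.0, 0.0), seed=3,
    )
    records, _ = generate_corpus(cfg)
    for rec in records:
        turns = segment_turns(rec.annotations)
        for spk in rec.annotations.speakers:
            feats = individual_features(rec.annotations, rec.tracks[spk], turns, spk)
            assert feats.articulation_rate_sps == pytest.approx(4.0, rel=0.10)


def test_phonation_pauses_and_variances():
    ann = AnnotationSet("c", "hobbies", ("A", "B"),
                        {"A": [(0.0, 2.0), (3.0, 4.0)], "B": []}, 10.0)
    n = 1000
    pitch = np.full(n, np.nan)
    intensity = np.full(n, np.nan)
    mask = np.zeros(n, bool)
    mask[0:200] = mask[300:400] = True
    pitch[mask] = 120.0
    intensity[mask] = 65.0
    track = ProsodyTrack(STEP, pitch, intensity)
    turns = segment_turns(ann)
    feats = individual_features(ann, track, turns, "A")
    assert feats.phonation_time_s == pytest.approx(3.0)
    assert feats.n_pauses == 1  # the 1 s silence inside A's single turn
    assert feats.var_pitch_hz2 == 0.0  # constant pitch
    assert feats.var_intensity_db2 == 0.0


def test_zero_phonation_is_an_error():
    ann = AnnotationSet("c", "hobbies", ("A", "B"), {"A": [(0.0, 1.0)], "B": []}, 10.0)
    track = ProsodyTrack(STEP, np.full(1000, np.nan), np.full(1000, np.nan))
    turns = segment_turns(ann)
    with pytest.raises(UndefinedStatisticError):
        individual_features(ann, track, turns, "B")


def test_turn_prosody_means_and_missing_pitch():
    ann = AnnotationSet("c", "hobbies", ("A", "B"),
                        {"A": [(0.0, 2.0)], "B": [(3.0, 5.0)]}, 6.0)
    n = 600
    pitch = np.full(n, np.nan)
    inten_a = np.full(n, np.nan)
    inten_b = np.full(n, np.nan)
    inten_a[0:200] = 70.0
    inten_b[300:500] = 64.0  # B fully unvoiced but speaking
    track_a = ProsodyTrack(STEP, pitch.copy(), inten_a)
    pitch_a = pitch.copy()
    pitch_a[0:200] = 110.0
    track_a = ProsodyTrack(STEP, pitch_a, inten_a)
    track_b = ProsodyTrack(STEP, pitch.copy(), inten_b)
    turns = segment_turns(ann)
    tp = turn_prosody(turns, {"A": track_a, "B": track_b})
    assert tp[0].mean_intensity_db == pytest.approx(70.0)
    assert tp[0].mean_pitch_hz == pytest.approx(110.0)
    assert np.isnan(tp[1].mean_pitch_hz)
    assert tp[1].mean_intensity_db == pytest.approx(64.0)


def test_turn_nucleus_counts_sum_to_individual_total(small_corpus):
    records, _ = small_corpus
    rec = records[0]
    turns = segment_turns(rec.annotations)
    tp = turn_prosody(turns, rec.tracks)
    for spk in rec.annotations.speakers:
        feats = individual_features(rec.annotations, rec.tracks[spk], turns, spk)
        per_turn = sum(t.n_syllables for t in tp if t.speaker_id == spk)
        assert per_turn == feats.n_syllables


def test_concatenated_turn_mean_is_duration_weighted_mean(small_corpus):
    records, _ = small_corpus
    rec = records[0]
    turns = segment_turns(rec.annotations)
    tp = turn_prosody(turns, rec.tracks)
    spk = turns.turns[0].speaker_id
    own = [(t, p) for t, p in zip(turns.turns, tp) if t.speaker_id == spk][:2]
    (t1, p1), (t2, p2) = own
    from convosync.prosody import segment_frame_mask

    track = rec.tracks[spk]
    w1 = np.sum(
        np.isfinite(track.intensity_db)
        & segment_frame_mask(track.n_frames, STEP, t1.segments)
    )
    w2 = np.sum(
        np.isfinite(track.intensity_db)
        & segment_frame_mask(track.n_frames, STEP, t2.segments)
    )
    merged_mask = segment_frame_mask(track.n_frames, STEP, t1.segments + t2.segments)
    merged_mean = np.nanmean(track.intensity_db[merged_mask])
    weighted = (w1 * p1.mean_intensity_db + w2 * p2.mean_intensity_db) / (w1 + w2)
    assert merged_mean == pytest.approx(weighted, rel=1e-10)


def test_features_invariant_to_time_translation():
    ann = AnnotationSet("c", "hobbies", ("A", "B"),
                        {"A": [(0.0, 2.0), (2.5, 3.5)], "B": [(4.0, 6.0)]}, 10.0)
    rng = np.random.default_rng(0)
    n = 1000
    pitch = np.full(n, np.nan)
    inten = np.full(n, np.nan)
    from convosync.prosody import segment_frame_mask

    mask = segment_frame_mask(n, STEP, ann.segments["A"])
    pitch[mask] = 120 + rng.normal(0, 5, mask.sum())
    inten[mask] = 60 + rng.normal(0, 1, mask.sum())
    track = ProsodyTrack(STEP, pitch, inten)
    feats = individual_features(ann, track, segment_turns(ann), "A")

    shift = 2.0
    k = int(shift / STEP)
    ann2 = AnnotationSet(
        "c", "hobbies", ("A", "B"),
        {s: [(a + shift, b + shift) for a, b in segs] for s, segs in ann.segments.items()},
        12.0,
    )
    track2 = ProsodyTrack(
        STEP,
        np.concatenate([np.full(k, np.nan), pitch]),
        np.concatenate([np.full(k, np.nan), inten]),
    )
    feats2 = individual_features(ann2, track2, segment_turns(ann2), "A")
    assert feats2.phonation_time_s == pytest.approx(feats.phonation_time_s)
    assert feats2.n_syllables == feats.n_syllables
    assert feats2.var_pitch_hz2 == pytest.approx(feats.var_pitch_hz2)
    assert feats2.var_intensity_db2 == pytest.approx(feats.var_intensity_db2)
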