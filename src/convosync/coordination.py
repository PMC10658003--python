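"""Interpersonal coordination: WCLC synchrony, turn adaptation, surrogate nulls.

Windowed cross-lagged correlation (WCLC) slides a window over two aligned
frame series and, per window, takes the peak Pearson correlation across
integer-frame lags within ``[-max_lag_s, +max_lag_s]``; the conversation's
synchrony summary is the mean of per-window peaks.  Defaults follow the
conventional 16 s window / 8 s step / 2 s lag parameterisation.

Chance-coordination ("pseudosynchrony"/"pseudoadaptation") nulls are built
by segment shuffling: one partner's series is cut into window-length
segments which are permuted in time (a trailing partial segment stays in
place), or — for turn-based adaptation — the partner's turn-feature
sequence is permuted.  The statistic is recomputed on each of the
``n_surrogates`` shuffles and the observed value is compared to the
surrogate mean with a one-sided paired Jeffreys–Zellner–Siow Bayes factor.

Missing frames (NaN) are handled pairwise-complete within each window; a
window-lag combination with fewer valid pairs than ``min_valid_fraction``
of the window is skipped.  For cross-partner prosody series, bridge missing
stretches first (see :func:`fill_missing`), otherwise alternating speech
leaves almost no pairwise-present frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from convosync.bayes_stats import jzs_log_bf10
from convosync.errors import ConfigError, UndefinedStatisticError
from convosync.prosody import TurnProsody

__all__ = [
    "WclcConfig",
    "WclcResult",
    "SurrogateResult",
    "fill_missing",
    "wclc_synchrony",
    "wclc_synchrony_reference",
    "turn_adaptation",
    "surrogate_null",
    "shuffle_segments",
    "pseudosynchrony",
    "pseudoadaptation",
    "compare_to_pseudo",
]

_VAR_REL_TOL = 1e-9  # relative floor below which a window-lag variance counts as zero


@dataclass
class WclcConfig:
    """Windowed cross-lagged correlation parameters (seconds)."""

    window_s: float = 16.0
    step_s: float = 8.0
    max_lag_s: float = 2.0
    min_valid_fraction: float = 0.5
    peak_rule: str = "max_signed"  # or "max_abs"

    def __post_init__(self) -> None:
        if self.window_s <= 2 * self.max_lag_s:
            raise ConfigError("window_s must exceed twice max_lag_s")
        if not 0 < self.step_s <= self.window_s:
            raise ConfigError("step_s must be in (0, window_s]")
        if not 0 < self.min_valid_fraction <= 1:
            raise ConfigError("min_valid_fraction must be in (0, 1]")
        if self.peak_rule not in ("max_signed", "max_abs"):
            raise ConfigError(f"unknown peak_rule {self.peak_rule!r}")


@dataclass
class WclcResult:
    per_window_peak: np.ndarray
    per_window_lag_s: np.ndarray
    window_start_s: np.ndarray
    summary: float


def fill_missing(x: np.ndarray) -> np.ndarray:
    """Bridge missing (NaN) stretches by linear interpolation, edges extended.

    Prosody series of a single speaker are undefined while the partner
    holds the floor; cross-partner correlation needs gap-free series, so
    gaps are bridged linearly and the first/last finite values are extended
    to the array edges.
    """
    x = np.asarray(x, dtype=float)
    finite = np.isfinite(x)
    if finite.all():
        return x.copy()
    if not finite.any():
        raise UndefinedStatisticError("cannot fill a series that is missing everywhere")
    idx = np.flatnonzero(finite)
    return np.interp(np.arange(x.size), idx, x[idx])


def _window_starts(n: int, w: int, s: int) -> range:
    return range(0, n - w + 1, s)


def wclc_synchrony(
    a: np.ndarray,
    b: np.ndarray,
    frame_step_s: float,
    cfg: WclcConfig | None = None,
) -> WclcResult:
    """Windowed cross-lagged correlation between two aligned frame series.

    For every window start ``0, step, 2*step, ...`` and every integer-frame
    lag ``l`` in ``[-max_lag_s, +max_lag_s]``, the Pearson correlation of
    ``a[i]`` against ``b[i + l]`` is computed over pairwise-present frames.
    The per-window peak follows ``cfg.peak_rule`` and the summary is the
    mean of per-window peaks.

    Raises
    ------
    UndefinedStatisticError
        If no window yields a valid correlation.
    """
    cfg = cfg or WclcConfig()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigError("series must be one-dimensional and equally long")
    n = a.size
    w = int(round(cfg.window_s / frame_step_s))
    s = int(round(cfg.step_s / frame_step_s))
    lag = int(round(cfg.max_lag_s / frame_step_s))
    if n < w:
        raise UndefinedStatisticError("series shorter than one window")

    # centre globally: correlations are shift-invariant, sums better conditioned
    a = a - np.nanmean(a)
    b = b - np.nanmean(b)
    va = np.isfinite(a).astype(float)
    vb = np.isfinite(b).astype(float)
    a0 = np.where(va > 0, a, 0.0)
    b0 = np.where(vb > 0, b, 0.0)

    pad = np.zeros(n + 2 * lag)
    b0p, vbp, b2p = pad.copy(), pad.copy(), pad.copy()
    b0p[lag : lag + n] = b0
    vbp[lag : lag + n] = vb
    b2p[lag : lag + n] = b0 * b0

    min_pairs = cfg.min_valid_fraction * w
    peaks, peak_lags, starts_s = [], [], []
    for start in _window_starts(n, w, s):
        aw = a0[start : start + w]
        vaw = va[start : start + w]
        a2w = aw * aw
        sl = slice(start, start + w + 2 * lag)
        npairs = np.correlate(vbp[sl], vaw, "valid")
        sab = np.correlate(b0p[sl], aw, "valid")
        sa = np.correlate(vbp[sl], aw, "valid")
        sb = np.correlate(b0p[sl], vaw, "valid")
        saa = np.correlate(vbp[sl], a2w, "valid")
        sbb = np.correlate(b2p[sl], vaw, "valid")
        cov = npairs * sab - sa * sb
        var_a = npairs * saa - sa * sa
        var_b = npairs * sbb - sb * sb
        ok = (
            (npairs >= min_pairs)
            & (var_a > _VAR_REL_TOL * npairs * saa)
            & (var_b > _VAR_REL_TOL * npairs * sbb)
        )
        if not ok.any():
            continue
        r = np.full(2 * lag + 1, -np.inf)
        r[ok] = cov[ok] / np.sqrt(var_a[ok] * var_b[ok])
        if cfg.peak_rule == "max_abs":
            r = np.where(np.isfinite(r), np.abs(r), -np.inf)
        k = int(np.argmax(r))
        peaks.append(r[k])
        peak_lags.append((k - lag) * frame_step_s)
        starts_s.append(start * frame_step_s)
    if not peaks:
        raise UndefinedStatisticError("synchrony undefined: no usable window")
    peaks_arr = np.asarray(peaks)
    return WclcResult(
        per_window_peak=peaks_arr,
        per_window_lag_s=np.asarray(peak_lags),
        window_start_s=np.asarray(starts_s),
        summary=float(peaks_arr.mean()),
    )


def wclc_synchrony_reference(
    a: np.ndarray,
    b: np.ndarray,
    frame_step_s: float,
    cfg: WclcConfig | None = None,
) -> WclcResult:
    """Naive reference WCLC: explicit loop over windows, lags and frames.

    Slow but transparent; used to validate :func:`wclc_synchrony`, whose
    results must agree with this loop to within floating-point noise.
    """
    cfg = cfg or WclcConfig()
    a = np.asarray(a, dtype=float) - np.nanmean(a)
    b = np.asarray(b, dtype=float) - np.nanmean(b)
    n = a.size
    w = int(round(cfg.window_s / frame_step_s))
    s = int(round(cfg.step_s / frame_step_s))
    lag = int(round(cfg.max_lag_s / frame_step_s))
    if n < w:
        raise UndefinedStatisticError("series shorter than one window")
    min_pairs = cfg.min_valid_fraction * w
    peaks, peak_lags, starts_s = [], [], []
    for start in _window_starts(n, w, s):
        best = -np.inf
        best_lag = 0.0
        for ell in range(-lag, lag + 1):
            xs, ys = [], []
            for j in range(w):
                i, k = start + j, start + j + ell
                if 0 <= k < n and math.isfinite(a[i]) and math.isfinite(b[k]):
                    xs.append(a[i])
                    ys.append(b[k])
            m = len(xs)
            if m < min_pairs:
                continue
            x = np.asarray(xs)
            y = np.asarray(ys)
            var_x = m * np.sum(x * x) - np.sum(x) ** 2
            var_y = m * np.sum(y * y) - np.sum(y) ** 2
            if var_x <= _VAR_REL_TOL * m * np.sum(x * x) or var_y <= _VAR_REL_TOL * m * np.sum(y * y):
                continue
            r = (m * np.sum(x * y) - np.sum(x) * np.sum(y)) / np.sqrt(var_x * var_y)
            if cfg.peak_rule == "max_abs":
                r = abs(r)
            if r > best:
                best = r
                best_lag = ell * frame_step_s
        if best > -np.inf:
            peaks.append(best)
            peak_lags.append(best_lag)
            starts_s.append(start * frame_step_s)
    if not peaks:
        raise UndefinedStatisticError("synchrony undefined: no usable window")
    peaks_arr = np.asarray(peaks)
    return WclcResult(
        per_window_peak=peaks_arr,
        per_window_lag_s=np.asarray(peak_lags),
        window_start_s=np.asarray(starts_s),
        summary=float(peaks_arr.mean()),
    )


# ---------------------------------------------------------------------------
# turn-based adaptation

_ADAPT_FIELDS = {
    "adapt_pitch": "mean_pitch_hz",
    "adapt_intensity": "mean_intensity_db",
    "adapt_articulation": "articulation_rate_sps",
}


def turn_adaptation(turn_prosody: Sequence[TurnProsody], speaker: str) -> dict[str, float]:
    """How much ``speaker`` adapted to the partner's immediately preceding turn.

    For pitch, intensity and articulation rate: the Pearson correlation,
    across the speaker's turns, between the own turn value and the
    partner's value in the directly preceding turn.  Pairs with a missing
    value are dropped; fewer than 3 valid pairs, or zero variance on either
    side, makes the statistic undefined.
    """
    out: dict[str, float] = {}
    for name, attr in _ADAPT_FIELDS.items():
        own, prev = [], []
        for k in range(1, len(turn_prosody)):
            cur, pre = turn_prosody[k], turn_prosody[k - 1]
            if cur.speaker_id != speaker or pre.speaker_id == speaker:
                continue
            x = getattr(cur, attr)
            y = getattr(pre, attr)
            if math.isfinite(x) and math.isfinite(y):
                own.append(x)
                prev.append(y)
        if len(own) < 3:
            raise UndefinedStatisticError(
                f"{speaker}/{name}: adaptation undefined with {len(own)} valid turn pairs"
            )
        own_a = np.asarray(own)
        prev_a = np.asarray(prev)
        if np.std(own_a) == 0 or np.std(prev_a) == 0:
            raise UndefinedStatisticError(f"{speaker}/{name}: zero variance across turns")
        out[name] = float(np.corrcoef(own_a, prev_a)[0, 1])
    return out


# ---------------------------------------------------------------------------
# surrogate (pseudo) nulls


@dataclass
class SurrogateResult:
    """Observed coordination value with its segment-shuffling null."""

    observed: float
    surrogates: np.ndarray
    surrogate_mean: float = field(init=False)
    log_bf10_vs_pseudo: float = float("nan")

    def __post_init__(self) -> None:
        self.surrogates = np.asarray(self.surrogates, dtype=float)
        self.surrogate_mean = float(np.nanmean(self.surrogates))


def shuffle_segments(x: np.ndarray, segment_frames: int, rng: np.random.Generator) -> np.ndarray:
    """Permute the full ``segment_frames``-long chunks of ``x`` in time.

    The trailing partial chunk, if any, stays in place — shuffling destroys
    cross-partner timing while preserving local signal structure.
    """
    x = np.asarray(x)
    n_full = x.size // segment_frames
    if n_full < 2:
        return x.copy()
    head = x[: n_full * segment_frames].reshape(n_full, segment_frames)
    order = rng.permutation(n_full)
    return np.concatenate([head[order].ravel(), x[n_full * segment_frames :]])


def surrogate_null(
    observed_fn: Callable[[object], float],
    shuffle_target: object,
    shuffler: Callable[[object, np.random.Generator], object],
    n_surrogates: int = 100,
    seed: int | None = None,
) -> SurrogateResult:
    """Generic segment-shuffling null for a coordination statistic.

    ``observed_fn`` maps the (possibly shuffled) target to the statistic;
    ``shuffler`` produces one shuffled copy per draw.  Surrogates on which
    the statistic is undefined are recorded as NaN; more than 50% undefined
    raises an error.  Deterministic given ``seed``.
    """
    if n_surrogates < 1:
        raise ConfigError("n_surrogates must be >= 1")
    rng = np.random.default_rng(seed)
    observed = float(observed_fn(shuffle_target))
    values = np.full(n_surrogates, np.nan)
    for i in range(n_surrogates):
        shuffled = shuffler(shuffle_target, rng)
        try:
            values[i] = float(observed_fn(shuffled))
        except UndefinedStatisticError:
            pass
    if np.sum(~np.isfinite(values)) > n_surrogates / 2:
        raise UndefinedStatisticError(
            "null construction failed: statistic undefined on most surrogates"
        )
    return SurrogateResult(observed=observed, surrogates=values)


def pseudosynchrony(
    a: np.ndarray,
    b: np.ndarray,
    frame_step_s: float,
    cfg: WclcConfig | None = None,
    n_surrogates: int = 100,
    seed: int | None = None,
) -> SurrogateResult:
    """WCLC synchrony with its pseudosynchrony null.

    One partner's series is shuffled in WCLC-window-length segments and the
    synchrony summary recomputed ``n_surrogates`` times.
    """
    cfg = cfg or WclcConfig()
    seg = int(round(cfg.window_s / frame_step_s))
    return surrogate_null(
        observed_fn=lambda bb: wclc_synchrony(a, bb, frame_step_s, cfg).summary,
        shuffle_target=np.asarray(b, dtype=float),
        shuffler=lambda bb, rng: shuffle_segments(bb, seg, rng),
        n_surrogates=n_surrogates,
        seed=seed,
    )


def pseudoadaptation(
    turn_prosody: Sequence[TurnProsody],
    speaker: str,
    feature: str,
    n_surrogates: int = 100,
    seed: int | None = None,
) -> SurrogateResult:
    """Turn-based adaptation with its pseudoadaptation null.

    The partner's turn-feature sequence is permuted across the partner's
    turn slots; the speaker's own sequence keeps its real order.
    ``feature`` is one of ``adapt_pitch``, ``adapt_intensity``,
    ``adapt_articulation``.
    """
    if feature not in _ADAPT_FIELDS:
        raise ConfigError(f"unknown adaptation feature {feature!r}")
    tps = list(turn_prosody)
    partner_slots = [i for i, tp in enumerate(tps) if tp.speaker_id != speaker]

    def shuffler(seq: list[TurnProsody], rng: np.random.Generator) -> list[TurnProsody]:
        order = rng.permutation(len(partner_slots))
        out = list(seq)
        for slot, j in zip(partner_slots, order):
            donor = seq[partner_slots[j]]
            out[slot] = TurnProsody(
                speaker_id=seq[slot].speaker_id,
                mean_pitch_hz=donor.mean_pitch_hz,
                mean_intensity_db=donor.mean_intensity_db,
                n_syllables=donor.n_syllables,
                articulation_rate_sps=donor.articulation_rate_sps,
            )
        return out

    return surrogate_null(
        observed_fn=lambda seq: turn_adaptation(seq, speaker)[feature],
        shuffle_target=tps,
        shuffler=shuffler,
        n_surrogates=n_surrogates,
        seed=seed,
    )


def compare_to_pseudo(
    observed_values: Sequence[float], pseudo_means: Sequence[float]
) -> float:
    """One-sided paired JZS Bayes factor: observed > matched pseudo values.

    Takes one observed coordination value and one surrogate mean per dyad
    (or per person) and returns the natural-log BF10 for the directional
    hypothesis that observed values exceed their chance-coordination nulls.
    Cauchy prior scale sqrt(2)/2 on the standardized effect.
    """
    obs = np.asarray(observed_values, dtype=float)
    pse = np.asarray(pseudo_means, dtype=float)
    if obs.shape != pse.shape or obs.size < 2:
        raise ConfigError("observed and pseudo lists must be matched with length >= 2")
    d = obs - pse
    n = d.size
    sd = float(np.std(d, ddof=1)) if n > 1 else 0.0
    if sd == 0.0:
        t = 0.0 if float(np.mean(d)) == 0.0 else math.inf * np.sign(float(np.mean(d)))
    else:
        t = float(np.mean(d)) / (sd / math.sqrt(n))
    if math.isinf(t):
        return math.inf if t > 0 else -math.inf
    return jzs_log_bf10(t, n_eff=n, df=n - 1, alternative="greater")
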