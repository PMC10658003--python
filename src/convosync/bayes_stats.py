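"""Bayes-factor group comparisons and evidence grading.

All Bayes factors are reported on the natural-log scale and graded with the
symmetric logarithmic thresholds of Jeffreys' scheme: ``|ln BF|`` below 1.1
is anecdotal, then moderate, strong (2.3), very strong (3.4) and — beyond
``ln(100) = 4.6`` — decisive; the sign says whether the evidence is for or
against.

Two approximate group-comparison routines are provided and labelled as
such:

* :func:`mixed_anova_bf` — a two-factor (within: task, between: group)
  repeated-measures model comparison using BIC-approximate marginal
  likelihoods, ``ln BF = (BIC_null - BIC_model) / 2``, with per-effect
  inclusion BFs across matched models.
* :func:`rank_group_bf` — a rank-approximate two-sample test: the JZS
  Bayes factor computed on rank-transformed pooled data, a stand-in for a
  sampling-based Bayesian Mann–Whitney test.

The exact JZS (Cauchy-prior) t-test Bayes factor used by both this module
and :mod:`convosync.coordination` is evaluated by numerical integration in
:func:`jzs_log_bf10`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

from convosync.errors import ConfigError, UndefinedStatisticError, ValidationError

__all__ = [
    "EvidenceGrade",
    "AnovaDesign",
    "grade_evidence",
    "jzs_log_bf10",
    "mixed_anova_bf",
    "rank_group_bf",
    "JZS_SCALE",
    "EVIDENCE_THRESHOLDS",
]

JZS_SCALE = math.sqrt(2.0) / 2.0

#: lower |ln BF| bounds of the evidence grades (closed lower bounds)
EVIDENCE_THRESHOLDS = (
    (4.6, "decisive"),
    (3.4, "very_strong"),
    (2.3, "strong"),
    (1.1, "moderate"),
    (0.0, "anecdotal"),
)


@dataclass(frozen=True)
class EvidenceGrade:
    log_bf: float
    strength: str  # anecdotal | moderate | strong | very_strong | decisive
    direction: str  # for | against

    @property
    def label(self) -> str:
        return f"{self.strength} evidence {self.direction}"


def grade_evidence(log_bf: float) -> EvidenceGrade:
    """Grade a natural-log Bayes factor on the symmetric Jeffreys scheme."""
    if not math.isfinite(log_bf):
        raise ValueError(f"log_bf must be finite, got {log_bf}")
    magnitude = abs(log_bf)
    for bound, strength in EVIDENCE_THRESHOLDS:
        if magnitude >= bound:
            return EvidenceGrade(
                log_bf=log_bf,
                strength=strength,
                direction="for" if log_bf >= 0 else "against",
            )
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# JZS t-test Bayes factor


def jzs_log_bf10(
    t: float,
    n_eff: float,
    df: int,
    r: float = JZS_SCALE,
    alternative: str = "two-sided",
) -> float:
    """Natural-log JZS Bayes factor for a t statistic.

    The alternative places a Cauchy(0, ``r``) prior on the standardized
    effect delta; the marginal likelihood is the noncentral-t density
    integrated against that prior, evaluated by adaptive quadrature after
    the substitution ``delta = r * tan(theta)`` (which maps the Cauchy
    measure to a uniform over theta, so the integrand is bounded and
    smooth).  ``alternative="greater"`` truncates the prior to delta > 0.

    ``n_eff`` is the effective sample size multiplying delta in the
    noncentrality (n for a paired test, n1*n2/(n1+n2) for two samples).
    """
    if df < 1 or n_eff <= 0 or r <= 0:
        raise ConfigError("need df >= 1, n_eff > 0 and r > 0")
    if alternative not in ("two-sided", "greater"):
        raise ConfigError(f"unknown alternative {alternative!r}")
    log_f0 = stats.t.logpdf(t, df)
    sqrt_n = math.sqrt(n_eff)

    def log_dens(theta: np.ndarray) -> np.ndarray:
        delta = r * np.tan(np.asarray(theta, dtype=float))
        with np.errstate(all="ignore"):
            ld = stats.nct.logpdf(t, df, delta * sqrt_n) - log_f0
        # the noncentral-t density underflows (or returns NaN) far in the
        # tails of the prior; the marginal contribution there is zero
        return np.where(np.isfinite(ld), ld, -np.inf)

    lo, hi = (0.0, math.pi / 2) if alternative == "greater" else (-math.pi / 2, math.pi / 2)
    weight = 2.0 / math.pi if alternative == "greater" else 1.0 / math.pi
    # shift by the grid maximum so quad works in a safe dynamic range
    grid = np.linspace(lo + 1e-9, hi - 1e-9, 201)
    shift = float(np.max(log_dens(grid)))
    val, _ = integrate.quad(
        lambda th: math.exp(float(log_dens(np.asarray(th))) - shift), lo, hi, limit=200
    )
    if val <= 0:
        return -math.inf
    return shift + math.log(val) + math.log(weight)


# ---------------------------------------------------------------------------
# BIC-approximate mixed (task x group) ANOVA


@dataclass
class AnovaDesign:
    """Balanced two-level within (task) x two-group between design.

    ``data`` needs columns ``subject``, ``task``, ``group``, ``value``;
    every subject must have exactly the two task levels and a constant
    group.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject", "task", "group", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"AnovaDesign missing column(s) {sorted(missing)}")
        tasks = sorted(self.data["task"].unique())
        if len(tasks) != 2:
            raise ValidationError(f"need exactly two task levels, got {tasks}")
        counts = self.data.groupby("subject")["task"].nunique()
        if (counts != 2).any() or len(self.data) != 2 * len(counts):
            raise ValidationError("every subject needs exactly one value per task level")
        g = self.data.groupby("subject")["group"].nunique()
        if (g != 1).any():
            raise ValidationError("group must be constant within subject")
        groups = sorted(self.data["group"].unique())
        if len(groups) != 2:
            raise ValidationError(f"need exactly two groups, got {groups}")
        per_group = self.data.drop_duplicates("subject").groupby("group")["subject"].count()
        if (per_group < 3).any():
            raise ValidationError("need at least 3 subjects per group")
        self.tasks = tasks
        self.groups = groups


def _gaussian_ml_ll(y: np.ndarray, X: np.ndarray | None, var_floor: float) -> tuple[float, int]:
    """Max log-likelihood and parameter count of y ~ N(X beta, sigma^2 I).

    ``X=None`` means a known zero mean.  The ML variance is floored to keep
    degenerate (zero-residual) fits finite.
    """
    n = y.size
    if X is None:
        rss = float(y @ y)
        p = 0
    else:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = float(resid @ resid)
        p = X.shape[1]
    sigma2 = max(rss / n, var_floor)
    ll = -0.5 * n * math.log(2 * math.pi * sigma2) - rss / (2 * sigma2)
    return ll, p


def mixed_anova_bf(design: AnovaDesign) -> dict:
    """BIC-approximate Bayes factors for the task x group candidate models.

    The compound-symmetry (random-intercept) repeated-measures likelihood
    factorizes exactly over per-subject sums and differences of the two
    task levels, so each candidate model is fitted in closed form by ML.
    Candidate set: null (subject only), +task, +group, +task+group, full
    (+interaction).  Per-model ``ln BF`` vs. the null uses
    ``(BIC_null - BIC_model)/2``; per-effect inclusion BFs compare matched
    models (e.g. for task: {task, task+group} vs. {null, group}; for the
    interaction: full vs. task+group).  Output is BIC-approximate, not a
    default-prior Bayes factor.
    """
    df = design.data
    wide = df.pivot_table(index="subject", columns="task", values="value")
    t0, t1 = design.tasks
    y0 = wide[t0].to_numpy(dtype=float)
    y1 = wide[t1].to_numpy(dtype=float)
    grp = (
        df.drop_duplicates("subject").set_index("subject").loc[wide.index, "group"]
        == design.groups[1]
    ).to_numpy(dtype=float)
    s = (y0 + y1) / 2.0  # between-subject component
    d = y1 - y0  # within-subject (task) component
    n_sub = s.size
    n_obs = 2 * n_sub
    var_floor = 1e-12 * (float(np.var(np.concatenate([y0, y1]))) + 1.0)

    ones = np.ones((n_sub, 1))
    with_g = np.column_stack([np.ones(n_sub), grp])
    models = {
        "null": (ones, None),
        "task": (ones, ones),
        "group": (with_g, None),
        "task_group": (with_g, ones),
        "full": (with_g, with_g),
    }
    bic: dict[str, float] = {}
    for name, (Xs, Xd) in models.items():
        ll_s, p_s = _gaussian_ml_ll(s, Xs, var_floor)
        ll_d, p_d = _gaussian_ml_ll(d, Xd, var_floor)
        k = p_s + p_d + 2  # two variance components
        bic[name] = -2.0 * (ll_s + ll_d) + k * math.log(n_obs)

    log_ml = {name: -b / 2.0 for name, b in bic.items()}  # BIC-approximate log marginals
    log_bf_model = {name: log_ml[name] - log_ml["null"] for name in models}

    def lse(*names: str) -> float:
        return float(special.logsumexp([log_ml[n] for n in names]))

    log_bf_incl = {
        "task": lse("task", "task_group") - lse("null", "group"),
        "group": lse("group", "task_group") - lse("null", "task"),
        "interaction": log_ml["full"] - log_ml["task_group"],
    }
    return {
        "log_bf_model": log_bf_model,
        "log_bf_incl": log_bf_incl,
        "method": "BIC-approximate",
    }


# ---------------------------------------------------------------------------
# rank-approximate two-sample Bayes factor


def rank_group_bf(values_a, values_b) -> float:
    """Rank-approximate two-sample Bayes factor (natural log).

    Pools both samples, rank-transforms them (average ranks for ties) and
    computes the two-sided JZS two-sample Bayes factor on the ranks — a
    deterministic stand-in for a sampling-based Bayesian Mann–Whitney
    test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 3 or n2 < 3:
        raise ConfigError("need at least 3 observations per group")
    ranks = stats.rankdata(np.concatenate([a, b]))
    ra, rb = ranks[:n1], ranks[n1:]
    sp2 = ((n1 - 1) * np.var(ra, ddof=1) + (n2 - 1) * np.var(rb, ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise UndefinedStatisticError("all values tied: rank BF undefined")
    t = (ra.mean() - rb.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    n_eff = n1 * n2 / (n1 + n2)
    return jzs_log_bf10(float(t), n_eff=n_eff, df=n1 + n2 - 2, alternative="two-sided")
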