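"""Mixed-design inference for pre/post VOR gains.

The study design is a 2x2 mixed (split-plot) layout: one within-subject
factor *time* (vHIT before vs. after a provocative ride) and one
between-subject factor *group* (symptomatic vs. asymptomatic, i.e. whether
the participant developed nausea). With exactly two repeated measures the
mixed ANOVA decomposes exactly into two independent one-way analyses:

* the **between** (group) effect lives on the subject means
  ``u_i = (pre_i + post_i) / 2``;
* the **within** (time) effect and the **time x group interaction** live on
  the change scores ``d_i = post_i - pre_i``.

With unbalanced groups the main effects use Type III (unweighted marginal
means) conventions; the interaction F equals the squared pooled-variance
two-sample t statistic on the change scores — an identity this module's
Monte-Carlo power analysis exploits to vectorize thousands of replicate
tests.

Bayes factors are computed with the BIC approximation
``BF10 = exp((BIC_null - BIC_alt) / 2)``, which corresponds to a unit-
information prior; they are labeled on the conventional evidence bands
(anecdotal / moderate / strong / ...).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import Cohort
from .errors import (
    ConstantInputError,
    DegenerateVarianceError,
    PowerSearchError,
    ValidationError,
)

SUSCEPTIBILITY_ANSWERS = frozenset(
    {"never", "rarely", "occasionally", "frequently", "almost always"}
)

_VAR_FLOOR = 1e-24  # below this an error variance is treated as exactly zero


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_participants(
    cohort: Cohort, susceptibility_answers: Mapping[str, str]
) -> tuple[Cohort, pd.DataFrame]:
    """Assign group labels from questionnaire answers and nausea scores.

    A participant is *susceptible* unless they answered "never" to the
    car-sickness frequency question, and *symptomatic* if their maximum
    nausea rating during the ride was above zero. Returns the relabeled
    cohort and the 2x2 subgroup count table.
    """
    relabeled = []
    for rec in cohort:
        try:
            answer = susceptibility_answers[rec.participant_id]
        except KeyError as exc:
            raise ValidationError(
                f"no susceptibility answer for participant {rec.participant_id!r}"
            ) from exc
        if answer not in SUSCEPTIBILITY_ANSWERS:
            raise ValidationError(
                f"unknown susceptibility answer {answer!r}; expected one of "
                f"{sorted(SUSCEPTIBILITY_ANSWERS)}"
            )
        rec = type(rec)(
            participant_id=rec.participant_id,
            susceptible=answer != "never",
            symptomatic=rec.nausea_max > 0,
            age=rec.age,
            mssq_short=rec.mssq_short,
            nausea_max=rec.nausea_max,
            gain_pre=rec.gain_pre,
            gain_post=rec.gain_post,
        )
        relabeled.append(rec)
    out = Cohort(relabeled)
    return out, out.subgroup_counts()


# ---------------------------------------------------------------------------
# mixed 2x2 ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectResult:
    """F test (and optional Bayes factor) for one model effect."""

    F: float
    df1: int
    df2: int
    p: float
    bf10: float | None = None
    evidence: str | None = None


@dataclass
class AnovaReport:
    """Results of the 2x2 mixed ANOVA: time, group and their interaction."""

    effects: dict[str, EffectResult] = field(default_factory=dict)
    n_per_group: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, e in self.effects.items():
            rows.append(
                {
                    "effect": name,
                    "F": e.F,
                    "df1": e.df1,
                    "df2": e.df2,
                    "p": e.p,
                    "BF10": e.bf10,
                    "evidence": e.evidence,
                }
            )
        return pd.DataFrame(rows)


def _split_pre_post(
    cohort: Cohort | pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = cohort.to_frame() if isinstance(cohort, Cohort) else cohort
    pre = df["gain_pre"].to_numpy(dtype=float)
    post = df["gain_post"].to_numpy(dtype=float)
    grp = df["symptomatic"].to_numpy(dtype=bool)
    n1, n2 = int(grp.sum()), int((~grp).sum())
    if min(n1, n2) < 2:
        raise ValidationError(
            f"need at least 2 participants per group; got symptomatic={n1}, "
            f"asymptomatic={n2}"
        )
    return pre, post, grp


def _one_df_f(y: np.ndarray, grp: np.ndarray) -> tuple[float, float, float, int]:
    """Type III F statistics on a per-subject score with a two-level factor.

    Returns (F_difference, F_unweighted_mean, pooled variance, df2) where
    F_difference tests equality of the group means and F_unweighted_mean
    tests whether the unweighted average of the two group means is zero.
    """
    y1, y2 = y[grp], y[~grp]
    n1, n2 = len(y1), len(y2)
    df2 = n1 + n2 - 2
    ss_res = float(np.sum((y1 - y1.mean()) ** 2) + np.sum((y2 - y2.mean()) ** 2))
    s2 = ss_res / df2
    if s2 < _VAR_FLOOR:
        raise DegenerateVarianceError(
            "zero residual variance; F statistics are undefined"
        )
    inv = 1.0 / n1 + 1.0 / n2
    f_diff = (y1.mean() - y2.mean()) ** 2 / (s2 * inv)
    m = 0.5 * (y1.mean() + y2.mean())
    f_mean = m**2 / (s2 * inv / 4.0)
    return float(f_diff), float(f_mean), s2, df2


def mixed_anova_2x2(
    cohort: Cohort | pd.DataFrame, *, with_bayes: bool = True
) -> AnovaReport:
    """2x2 mixed repeated-measures ANOVA on pre/post gains.

    The between factor is symptom group, the within factor time. Expects a
    :class:`~vhitkit.cohort.Cohort` or a DataFrame with ``symptomatic``,
    ``gain_pre`` and ``gain_post`` columns. Unbalanced groups are handled
    with Type III (unweighted-means) conventions; all effects are tested on
    (1, N-2) degrees of freedom.

    Raises
    ------
    DegenerateVarianceError
        If an error term is numerically zero (e.g. noiseless identical
        groups), rather than returning NaN statistics.
    """
    pre, post, grp = _split_pre_post(cohort)
    d = post - pre
    u = 0.5 * (post + pre)
    n = len(d)

    f_int, f_time, _, df2 = _one_df_f(d, grp)
    f_grp, _, _, _ = _one_df_f(u, grp)

    report = AnovaReport(
        n_per_group={"symptomatic": int(grp.sum()), "asymptomatic": int((~grp).sum())}
    )
    for name, F in (("time", f_time), ("group", f_grp), ("interaction", f_int)):
        p = f_p_value(F, 1, df2)
        bf = lab = None
        if with_bayes:
            bf = _bf10_from_f(F, 1, df2, n)
            lab = evidence_label(bf)
        report.effects[name] = EffectResult(
            F=F, df1=1, df2=df2, p=p, bf10=bf, evidence=lab
        )
    return report


def f_p_value(F: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the central F distribution."""
    if df1 < 1 or df2 < 1:
        raise ValidationError(f"invalid degrees of freedom ({df1}, {df2})")
    if F < 0:
        raise ValidationError("F must be non-negative")
    return float(sps.f.sf(F, df1, df2))


# ---------------------------------------------------------------------------
# Bayes factors (BIC approximation)
# ---------------------------------------------------------------------------

def bf10_from_bic(bic_null: float, bic_alt: float) -> float:
    """BIC-approximate Bayes factor of the alternative over the null."""
    return float(math.exp((bic_null - bic_alt) / 2.0))


def _bf10_from_f(F: float, df1: int, df2: int, n: int) -> float:
    # For nested OLS models differing by df1 parameters on n observations:
    # BIC_null - BIC_alt = n * ln(RSS_null / RSS_alt) - df1 * ln(n)
    # and RSS_null / RSS_alt = 1 + F * df1 / df2.
    delta = n * math.log1p(F * df1 / df2) - df1 * math.log(n)
    return float(math.exp(delta / 2.0))


_EVIDENCE_BANDS = [
    (100.0, "extreme evidence for the alternative"),
    (30.0, "very strong evidence for the alternative"),
    (10.0, "strong evidence for the alternative"),
    (3.0, "moderate evidence for the alternative"),
    (1.0, "anecdotal evidence for the alternative"),
    (1.0 / 3.0, "anecdotal evidence for the null"),
    (1.0 / 10.0, "moderate evidence for the null"),
    (1.0 / 30.0, "strong evidence for the null"),
    (1.0 / 100.0, "very strong evidence for the null"),
]


def evidence_label(bf10: float) -> str:
    """Conventional verbal band for a Bayes factor BF10."""
    if bf10 <= 0:
        raise ValidationError("BF10 must be positive")
    for cut, label in _EVIDENCE_BANDS:
        if bf10 > cut:
            return label
    return "extreme evidence for the null"


def bayes_factor_bic(cohort: Cohort | pd.DataFrame) -> dict[str, tuple[float, str]]:
    """BIC-approximate BF10 (with evidence label) per model effect."""
    report = mixed_anova_2x2(cohort, with_bayes=True)
    return {
        name: (e.bf10, e.evidence) for name, e in report.effects.items()
    }


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

_EXACT_PERM_MAX_N = 8


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ranks use midranks for ties; rho is the Pearson correlation of the
    ranks. The p-value is exact (full permutation enumeration) for n <= 8
    and otherwise uses the t approximation
    ``t = rho * sqrt((n - 2) / (1 - rho^2))`` on n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D and equal length")
    n = len(x)
    if n < 4:
        raise ValidationError(f"need at least 4 observations; got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= _EXACT_PERM_MAX_N:
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt(float(np.sum(rxc**2) * np.sum(ryc**2)))
        obs = abs(float(rxc @ ryc) / denom)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = abs(float(rxc[list(perm)] @ ryc) / denom)
            count += r >= obs - 1e-12
            total += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            tstat = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(sps.t.sf(abs(tstat), n - 2))
    return rho, p


# ---------------------------------------------------------------------------
# power / sample size
# ---------------------------------------------------------------------------

@dataclass
class PowerSpec:
    """Design assumptions for the interaction power analysis.

    Each subject contributes correlated (pre, post) gains with per-measure
    SD ``error_sd`` and correlation ``correlation``; symptomatic subjects
    change by ``change_symptomatic`` between sessions, asymptomatic ones by
    ``change_asymptomatic``. Defaults are the planning values of the study
    design this package emulates: a 0.1 gain change confined to the
    symptomatic group, SD 0.05, correlation 0.7, alpha 0.05, target power
    0.8.
    """

    alpha: float = 0.05
    target_power: float = 0.8
    correlation: float = 0.7
    change_symptomatic: float = 0.1
    change_asymptomatic: float = 0.0
    error_sd: float = 0.05
    baseline_mean: float = 1.0
    n_reps: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValidationError("target_power must lie in (0, 1)")
        if not abs(self.correlation) < 1:
            raise ValidationError("|correlation| must be < 1")
        if self.error_sd <= 0:
            raise ValidationError("error_sd must be positive")


@dataclass(frozen=True)
class PowerResult:
    total_n: int
    power: float
    ci_low: float
    ci_high: float
    n_reps: int


def split_groups(total_n: int) -> tuple[int, int]:
    """Even split of ``total_n`` into (symptomatic, asymptomatic); the larger
    half goes to the symptomatic group when odd."""
    n1 = (total_n + 1) // 2
    return n1, total_n - n1


def power_by_simulation(spec: PowerSpec, total_n: int) -> PowerResult:
    """Monte-Carlo power of the time x group interaction test.

    Simulates ``n_reps`` replicate cohorts of ``total_n`` subjects with
    bivariate-normal (pre, post) gains under the spec's assumptions and
    counts rejections of the mixed-ANOVA interaction test at ``alpha``. The
    interaction F is evaluated through its change-score t-squared identity,
    which is algebraically exact for the 2x2 design. The rejection
    proportion is returned with a 95% Wilson score interval.
    """
    if total_n < 4:
        raise ValidationError("total_n must be at least 4")
    if spec.n_reps < 100:
        raise ValidationError(
            f"n_reps={spec.n_reps} gives an unusably noisy power estimate; "
            "use at least 100"
        )
    n1, n2 = split_groups(total_n)
    rng = np.random.default_rng(spec.seed)
    rho, sd = spec.correlation, spec.error_sd
    reps = spec.n_reps

    z1 = rng.standard_normal((reps, total_n))
    z2 = rng.standard_normal((reps, total_n))
    pre = spec.baseline_mean + sd * z1
    change = np.r_[
        np.full(n1, spec.change_symptomatic),
        np.full(n2, spec.change_asymptomatic),
    ]
    post = (
        spec.baseline_mean
        + change
        + sd * (rho * z1 + math.sqrt(1.0 - rho * rho) * z2)
    )
    d = post - pre
    d1, d2 = d[:, :n1], d[:, n1:]
    m1, m2 = d1.mean(axis=1), d2.mean(axis=1)
    ss = ((d1 - m1[:, None]) ** 2).sum(axis=1) + ((d2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / (total_n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_int = (m1 - m2) ** 2 / (s2 * (1.0 / n1 + 1.0 / n2))
    crit = sps.f.isf(spec.alpha, 1, total_n - 2)
    k = int(np.sum(f_int > crit))
    power = k / reps
    lo, hi = _wilson_interval(k, reps)
    return PowerResult(total_n=total_n, power=power, ci_low=lo, ci_high=hi, n_reps=reps)


def _wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(k, n, alpha=1 - conf, method="wilson")
    return float(lo), float(hi)


def power_analytic(spec: PowerSpec, total_n: int) -> float:
    """Noncentral-F power for the interaction, for cross-checking.

    Uses the repeated-measures convention ``lambda = f^2 * N * m / (1 - rho)``
    with m = 2 measures and Cohen's f computed from the interaction
    deviations of the four cell means (with the default effect pattern the
    cell deviations are +-change/4, so f = change / (4 * error_sd) = 0.5),
    tested on (1, N - 2) degrees of freedom.
    """
    changes = np.array([spec.change_symptomatic, spec.change_asymptomatic])
    # interaction deviations of the 2x2 cell means after removing main effects
    dev = (changes - changes.mean()) / 2.0
    f2 = float(np.mean(np.r_[dev, -dev] ** 2)) / spec.error_sd**2
    lam = f2 * total_n * 2.0 / (1.0 - spec.correlation)
    crit = sps.f.isf(spec.alpha, 1, total_n - 2)
    return float(sps.ncf.sf(crit, 1, total_n - 2, lam))


def minimal_n(
    spec: PowerSpec, *, n_min: int = 4, n_cap: int = 100
) -> tuple[int, float]:
    """Smallest total sample size whose simulated power meets the target.

    Searches total_n upward from ``n_min`` (even split, larger half
    symptomatic), running :func:`power_by_simulation` with a per-n seed
    derived deterministically from the spec seed. Returns ``(n, power)``.

    Raises
    ------
    PowerSearchError
        If the target power is not reached by ``n_cap``.
    """
    from dataclasses import replace

    for n in range(n_min, n_cap + 1):
        child = int(np.random.SeedSequence([spec.seed, n]).generate_state(1)[0] % (2**31))
        res = power_by_simulation(replace(spec, seed=child), n)
        if res.power >= spec.target_power:
            return n, res.power
    raise PowerSearchError(
        f"power {spec.target_power} not reached by total_n={n_cap}"
    )
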