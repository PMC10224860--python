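"""Statistical layer tests: classification vocabulary, the 2x2 mixed ANOVA
against independent oracles (change-score t^2 identity, statsmodels Type III,
pingouin on balanced designs), the BIC Bayes-factor approximation, Spearman
correlation, and the Monte-Carlo power machinery."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vhitkit import (
    Cohort,
    CohortConfig,
    ParticipantRecord,
    PowerSpec,
    bayes_factor_bic,
    classify_participants,
    evidence_label,
    f_p_value,
    minimal_n,
    mixed_anova_2x2,
    power_by_simulation,
    simulate_cohort,
    spearman,
)
from vhitkit.errors import (
    ConstantInputError,
    DegenerateVarianceError,
    PowerSearchError,
    ValidationError,
)
from vhitkit.stats import bf10_from_bic, power_analytic, split_groups


def make_cohort(pre, post, grp):
    recs = []
    for i, (a, b, g) in enumerate(zip(pre, post, grp)):
        recs.append(
            ParticipantRecord(
                participant_id=f"s{i:03d}", susceptible=bool(g),
                symptomatic=bool(g), age=30.0, mssq_short=10.0,
                nausea_max=2 if g else 0, gain_pre=float(a), gain_post=float(b),
            )
        )
    return Cohort(recs)


def random_cohort(rng, n1, n2, delta=0.0):
    grp = np.r_[np.ones(n1, bool), np.zeros(n2, bool)]
    pre = 1.0 + 0.05 * rng.standard_normal(n1 + n2)
    post = (pre * 0.7 + 0.3 + 0.05 * rng.standard_normal(n1 + n2)
            + delta * grp)
    return pre, post, grp


class TestClassification:
    def test_study_structure_counts(self, default_cohort):
        answers = {}
        df = default_cohort.to_frame()
        for r in default_cohort:
            answers[r.participant_id] = "rarely" if r.susceptible else "never"
        cohort, counts = classify_participants(default_cohort, answers)
        out = cohort.to_frame()
        assert (~out.susceptible).sum() == 6
        assert out.susceptible.sum() == 11
        assert out.symptomatic.sum() == 8
        assert (~out.symptomatic).sum() == 9
        assert counts.to_numpy().sum() == 17

    def test_all_never_all_nausea_free(self):
        cohort = make_cohort([1.0, 1.1, 0.9, 1.0], [1.0, 1.1, 0.9, 1.0],
                             [0, 0, 0, 0])
        answers = {r.participant_id: "never" for r in cohort}
        out, _ = classify_participants(cohort, answers)
        assert not any(r.susceptible for r in out)
        assert not any(r.symptomatic for r in out)

    def test_unknown_answer_rejected(self, default_cohort):
        answers = {r.participant_id: "sometimes" for r in default_cohort}
        with pytest.raises(ValidationError, match="sometimes"):
            classify_participants(default_cohort, answers)


class TestMixedAnova:
    def test_interaction_equals_change_score_t_squared(self, rng):
        """Classical 2x2 identity on 1,000 random (possibly unbalanced)
        datasets: interaction F == pooled-t^2 on post-pre, to 1e-8."""
        for _ in range(1000):
            n1 = int(rng.integers(3, 12))
            n2 = int(rng.integers(3, 12))
            pre, post, grp = random_cohort(rng, n1, n2,
                                           delta=rng.normal(0, 0.05))
            rep = mixed_anova_2x2(make_cohort(pre, post, grp),
                                  with_bayes=False)
            d = post - pre
            t, _ = sps.ttest_ind(d[grp], d[~grp], equal_var=True)
            assert rep.effects["interaction"].F == pytest.approx(
                t**2, abs=1e-8, rel=1e-8
            )

    def test_matches_pingouin_balanced(self, rng):
        pg = pytest.importorskip("pingouin")
        pre, post, grp = random_cohort(rng, 8, 8, delta=0.05)
        rep = mixed_anova_2x2(make_cohort(pre, post, grp), with_bayes=False)
        long = pd.DataFrame({
            "sub": np.arange(16).repeat(2),
            "time": ["pre", "post"] * 16,
            "grp": grp.repeat(2),
            "y": np.c_[pre, post].ravel(),
        })
        ref = pg.mixed_anova(data=long, dv="y", within="time", subject="sub",
                             between="grp").set_index("Source")
        assert rep.effects["group"].F == pytest.approx(ref.loc["grp", "F"])
        assert rep.effects["time"].F == pytest.approx(ref.loc["time", "F"])
        assert rep.effects["interaction"].F == pytest.approx(
            ref.loc["Interaction", "F"]
        )

    def test_matches_statsmodels_type3_unbalanced(self, rng):
        """Unbalanced oracle: Type III OLS with sum contrasts on the change
        scores reproduces the time and interaction F."""
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        pre, post, grp = random_cohort(rng, 10, 5, delta=0.08)
        rep = mixed_anova_2x2(make_cohort(pre, post, grp), with_bayes=False)
        dd = pd.DataFrame({"d": post - pre, "g": grp})
        tab = anova_lm(smf.ols("d ~ C(g, Sum)", dd).fit(), typ=3)
        assert rep.effects["time"].F == pytest.approx(
            tab.loc["Intercept", "F"], abs=1e-10
        )
        assert rep.effects["interaction"].F == pytest.approx(
            tab.loc["C(g, Sum)", "F"], abs=1e-10
        )

    def test_degenerate_variance_raises(self):
        pre = [1.0, 1.0, 1.0, 1.0]
        post = [1.0, 1.0, 1.0, 1.0]
        with pytest.raises(DegenerateVarianceError):
            mixed_anova_2x2(make_cohort(pre, post, [1, 1, 0, 0]))

    def test_type_one_error_calibrated(self):
        """Null simulation (no effects, rho=0.7): interaction rejection rate
        at alpha=0.05 stays within [0.04, 0.06] over 10,000 replicates."""
        spec = PowerSpec(change_symptomatic=0.0, change_asymptomatic=0.0,
                         n_reps=10_000, seed=2023)
        res = power_by_simulation(spec, 16)
        assert 0.04 <= res.power <= 0.06

    def test_null_interaction_p_values_uniform(self):
        """Kolmogorov-Smirnov on 10,000 null interaction p-values does not
        reject uniformity at the 1% level."""
        rng = np.random.default_rng(77)
        reps, n1, n2 = 10_000, 8, 8
        n = n1 + n2
        pre = rng.standard_normal((reps, n))
        post = 0.7 * pre + math.sqrt(1 - 0.49) * rng.standard_normal((reps, n))
        d = post - pre
        m1 = d[:, :n1].mean(axis=1)
        m2 = d[:, n1:].mean(axis=1)
        ss = (((d[:, :n1] - m1[:, None]) ** 2).sum(axis=1)
              + ((d[:, n1:] - m2[:, None]) ** 2).sum(axis=1))
        f = (m1 - m2) ** 2 / (ss / (n - 2) * (1 / n1 + 1 / n2))
        pvals = sps.f.sf(f, 1, n - 2)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestFPValue:
    @pytest.mark.parametrize(
        "F,df1,df2,printed,tol",
        [
            (2.19, 1, 15, 0.16, 0.005),
            (0.03, 1, 15, 0.86, 0.005),
            (0.17, 1, 15, 0.69, 0.005),
            (0.619, 1, 33, 0.437, 0.0015),
            (0.311, 1, 15, 0.586, 0.002),
        ],
    )
    def test_reproduces_reported_p_values(self, F, df1, df2, printed, tol):
        """The reported (F, df) pairs of the study reproduce their p-values
        at printed precision (slack covers rounding of the printed F)."""
        assert f_p_value(F, df1, df2) == pytest.approx(printed, abs=tol)

    def test_zero_f_gives_p_one(self):
        assert f_p_value(0.0, 1, 15) == 1.0

    def test_invalid_df_rejected(self):
        with pytest.raises(ValidationError):
            f_p_value(1.0, 0, 15)

    def test_agrees_with_numerical_integration(self):
        from scipy.integrate import quad

        for F, df1, df2 in [(0.5, 1, 10), (2.0, 1, 15), (3.3, 2, 20),
                            (1.7, 3, 8)]:
            num, _ = quad(lambda x: sps.f.pdf(x, df1, df2), F, np.inf)
            assert f_p_value(F, df1, df2) == pytest.approx(num, abs=1e-6)


class TestBayesFactor:
    def test_identical_bic_gives_one(self):
        assert bf10_from_bic(123.4, 123.4) == pytest.approx(1.0)

    def test_bic_difference_two_gives_e(self):
        assert bf10_from_bic(102.0, 100.0) == pytest.approx(math.e)

    def test_strong_interaction_large_bf(self, rng):
        """A strong simulated interaction (change 0.1 vs 0, SD 0.01, n=40)
        yields interaction BF10 > 100."""
        n = 40
        grp = np.r_[np.ones(n // 2, bool), np.zeros(n // 2, bool)]
        pre = 1.0 + 0.01 * rng.standard_normal(n)
        post = pre + 0.1 * grp + 0.01 * rng.standard_normal(n)
        bfs = bayes_factor_bic(make_cohort(pre, post, grp))
        bf, label = bfs["interaction"]
        assert bf > 100
        assert "alternative" in label

    def test_null_cohort_evidence_labels(self, default_cohort):
        bfs = bayes_factor_bic(default_cohort)
        for bf, label in bfs.values():
            assert bf > 0
            assert "evidence" in label

    def test_anecdotal_band(self):
        assert evidence_label(0.77) == "anecdotal evidence for the null"
        assert evidence_label(2.0) == "anecdotal evidence for the alternative"

    def test_parameter_recovery_with_true_interaction(self, rng):
        """Cohorts simulated with a true interaction (change 0.1 vs 0,
        SD 0.05, rho 0.7, n=200) give interaction p < 0.001 and BF10 > 10 in
        >= 99% of runs."""
        hits = 0
        runs = 100
        for _ in range(runs):
            n = 200
            grp = np.r_[np.ones(n // 2, bool), np.zeros(n // 2, bool)]
            z1 = rng.standard_normal(n)
            z2 = rng.standard_normal(n)
            pre = 1.0 + 0.05 * z1
            post = (1.0 + 0.1 * grp
                    + 0.05 * (0.7 * z1 + math.sqrt(0.51) * z2))
            rep = mixed_anova_2x2(make_cohort(pre, post, grp))
            e = rep.effects["interaction"]
            hits += (e.p < 0.001) and (e.bf10 > 10)
        assert hits / runs >= 0.99


class TestSpearman:
    def test_monotone_pairs(self):
        assert spearman([1, 2, 3, 4, 5], [2, 4, 6, 9, 11])[0] == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4, 5], [5, 4, 3, 1, 0])[0] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        """10-point random instances (with ties): rho equals Pearson on
        midranks, p matches scipy's t-approximation implementation."""
        for _ in range(200):
            x = rng.integers(0, 6, size=12).astype(float)
            y = rng.integers(0, 6, size=12).astype(float) + 0.3 * x
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, p = spearman(x, y)
            rx, ry = sps.rankdata(x), sps.rankdata(y)
            assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)
            ref = sps.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_permutation_small_n(self):
        """For n <= 8 the p-value is the exact two-sided permutation tail
        (brute-force enumeration oracle)."""
        from itertools import permutations

        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        rho, p = spearman(x, y)
        assert rho == pytest.approx(sps.spearmanr(x, y).statistic)
        obs = abs(sps.spearmanr(x, y).statistic)
        tail = [
            abs(sps.spearmanr(x, np.array(perm)).statistic) >= obs - 1e-12
            for perm in permutations(y)
        ]
        assert p == pytest.approx(np.mean(tail), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ConstantInputError):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_cohort_mssq_nausea_positive(self, default_cohort):
        df = default_cohort.to_frame()
        rho, p = spearman(df.mssq_short, df.nausea_max)
        assert rho > 0


class TestPower:
    def test_null_effect_power_near_alpha(self):
        spec = PowerSpec(change_symptomatic=0.0, n_reps=5000, seed=5)
        res = power_by_simulation(spec, 16)
        assert abs(res.power - 0.05) < 0.01
        assert res.ci_low < 0.05 < res.ci_high

    def test_design_point_power_exceeds_target(self):
        """At the planning assumptions (change 0.1 vs 0, SD 0.05, rho 0.7)
        a total of 15 participants gives interaction power >= 0.8."""
        spec = PowerSpec(n_reps=5000, seed=1)
        res = power_by_simulation(spec, 15)
        assert res.power >= 0.8

    def test_agrees_with_noncentral_f(self):
        spec = PowerSpec(n_reps=20_000, seed=9)
        for n in (8, 12, 16):
            sim = power_by_simulation(spec, n).power
            ana = power_analytic(spec, n)
            assert sim == pytest.approx(ana, abs=0.02)

    def test_monotone_in_total_n(self):
        spec = PowerSpec(error_sd=0.12, n_reps=5000, seed=3)
        powers = [power_by_simulation(spec, n).power for n in (8, 12, 16, 24)]
        for a, b in zip(powers, powers[1:]):
            assert b >= a - 0.02  # within Monte-Carlo error

    def test_odd_split_favors_symptomatic(self):
        assert split_groups(15) == (8, 7)
        assert split_groups(16) == (8, 8)

    def test_underpowered_rep_count_refused(self):
        with pytest.raises(ValidationError, match="100"):
            power_by_simulation(PowerSpec(n_reps=50), 16)

    def test_minimal_n_floor(self):
        spec = PowerSpec(change_symptomatic=1.0, error_sd=0.01, n_reps=200,
                         seed=1)
        n, power = minimal_n(spec)
        assert n == 4
        assert power >= 0.8

    def test_minimal_n_cap_error_under_null(self):
        spec = PowerSpec(change_symptomatic=0.0, n_reps=200, seed=1)
        with pytest.raises(PowerSearchError):
            minimal_n(spec, n_cap=20)

    def test_minimal_n_monotone_in_error_sd(self):
        base = PowerSpec(error_sd=0.10, n_reps=2000, seed=8)
        doubled = PowerSpec(error_sd=0.20, n_reps=2000, seed=8)
        n1, _ = minimal_n(base)
        n2, _ = minimal_n(doubled)
        assert n2 >= n1
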