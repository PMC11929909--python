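"""Outcome-level statistics: ROC, contingency, aggregation, formulas."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import qpop


def outcomes_frame(ncv, recist):
    return pd.DataFrame(
        {
            "case_id": [f"C{i}" for i in range(len(ncv))],
            "therapy": ["x"] * len(ncv),
            "mean_ncv": ncv,
            "recist": recist,
        }
    )


def auc_pair_counting(ncv, is_resp):
    """Oracle: (concordant pairs + half ties) / (n_pos * n_neg), low NCV wins."""
    pos = [v for v, r in zip(ncv, is_resp) if r]
    neg = [v for v, r in zip(ncv, is_resp) if not r]
    total = 0.0
    for p in pos:
        for n in neg:
            if p < n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        out = outcomes_frame(
            [0.5, 0.55, 0.6, 0.9, 0.95, 1.0], ["PR", "SD", "PR", "PD", "PD", "PD"]
        )
        res = qpop.roc_analysis(out)
        assert res.auc == 1.0
        assert res.youden_j == pytest.approx(1.0)
        assert 0.6 < res.cutoff < 0.9

    def test_identical_distributions_auc_half(self):
        out = outcomes_frame([0.7, 0.8, 0.7, 0.8], ["PR", "PR", "PD", "PD"])
        assert qpop.roc_analysis(out).auc == pytest.approx(0.5)

    def test_auc_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(6, 25))
            ncv = np.round(rng.uniform(0.4, 1.0, size=n), 2)  # induce ties
            recist = rng.choice(["PR", "SD", "PD"], size=n)
            if not {"PD"} & set(recist) or not {"PR", "SD"} & set(recist):
                continue
            out = outcomes_frame(ncv, recist)
            expected = auc_pair_counting(ncv, [r in ("PR", "SD") for r in recist])
            assert qpop.roc_analysis(out).auc == pytest.approx(expected, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both responder"):
            qpop.roc_analysis(outcomes_frame([0.7, 0.8], ["PR", "SD"]))

    def test_cutoff_recovery_from_logistic_cohorts(self, panel, design):
        """Median recovered cutoff across seeded cohorts sits near the
        generative threshold c of the outcome link."""
        c = 0.8
        cutoffs = []
        for seed in range(200):
            cohort = qpop.simulate_cohort(
                8, panel, design,
                outcome_link=(c, 25.0, 0.05),
                n_outcomes=27,
                planted_pairs=(),
                with_plates=False,
                seed=seed,
            )
            resp = cohort.outcomes["recist"].isin(["PR", "SD"])
            if resp.all() or (~resp).all():
                continue
            cutoffs.append(qpop.roc_analysis(cohort.outcomes).cutoff)
        assert len(cutoffs) >= 150
        assert abs(float(np.median(cutoffs)) - c) <= 0.05

    def test_auc_monotone_in_link_slope(self, panel, design):
        """Sharper outcome links never reduce expected discrimination."""
        mean_auc = []
        for k in (2.0, 8.0, 25.0, 100.0):
            aucs = []
            for seed in range(30):
                cohort = qpop.simulate_cohort(
                    8, panel, design,
                    outcome_link=(0.8, k, 0.0),
                    n_outcomes=27,
                    planted_pairs=(),
                    with_plates=False,
                    seed=seed,
                )
                resp = cohort.outcomes["recist"].isin(["PR", "SD"])
                if resp.all() or (~resp).all():
                    continue
                aucs.append(qpop.roc_analysis(cohort.outcomes).auc)
            mean_auc.append(np.mean(aucs))
        assert np.all(np.diff(mean_auc) > 0)


def fisher_p_enumeration(a, b, c, d):
    """Oracle: enumerate all tables with the observed margins."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    def table_prob(x):
        return (
            math.comb(r1, x)
            * math.comb(n - r1, c1 - x)
            / math.comb(n, c1)
        )
    p_obs = table_prob(a)
    total = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        p = table_prob(x)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return total


class TestContingency:
    def test_responder_table_statistics(self):
        res = qpop.contingency_analysis(12, 2, 4, 9)
        assert res.odds_ratio == pytest.approx(13.5)
        assert res.fisher_p == pytest.approx(0.0063, abs=0.0002)
        assert res.tpv == pytest.approx(21 / 27)
        assert round(100 * res.tpv, 1) == 77.8

    def test_symmetric_table_is_null(self):
        res = qpop.contingency_analysis(5, 5, 5, 5)
        assert res.odds_ratio == 1.0
        assert res.fisher_p == pytest.approx(1.0)

    def test_fisher_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
            if a + b + c + d == 0:
                continue
            res = qpop.contingency_analysis(a, b, c, d)
            assert res.fisher_p == pytest.approx(
                fisher_p_enumeration(a, b, c, d), abs=1e-10
            )

    def test_fisher_matches_scipy(self):
        for cells in [(12, 2, 4, 9), (3, 7, 8, 2), (0, 5, 5, 0), (1, 1, 1, 1)]:
            res = qpop.contingency_analysis(*cells)
            _, p = stats.fisher_exact([[cells[0], cells[1]], [cells[2], cells[3]]])
            assert res.fisher_p == pytest.approx(p, rel=1e-9)

    def test_zero_denominator_gives_infinite_or(self):
        res = qpop.contingency_analysis(5, 0, 2, 3)
        assert math.isinf(res.odds_ratio)

    def test_conditional_ci_option(self):
        res = qpop.contingency_analysis(12, 2, 4, 9, or_ci_method="conditional")
        lo, hi = res.or_ci
        assert lo < res.odds_ratio < hi

    def test_invalid_cells_rejected(self):
        with pytest.raises(ValueError, match="nonnegative integers"):
            qpop.contingency_analysis(-1, 2, 3, 4)
        with pytest.raises(ValueError, match="empty"):
            qpop.contingency_analysis(0, 0, 0, 0)


class TestOutcomeProportions:
    def test_study_cohort_percentages(self):
        labels = ["PR"] * 7 + ["SD"] * 9 + ["PD"] * 11
        tbl = qpop.outcome_proportions(labels)
        assert tbl.set_index("recist")["pct"].to_dict() == {
            "PR": 25.9, "SD": 33.3, "PD": 40.7
        }

    def test_empty_list_flagged(self):
        tbl = qpop.outcome_proportions([])
        assert tbl["count"].sum() == 0
        assert tbl["pct"].isna().all()

    def test_single_class_is_100(self):
        tbl = qpop.outcome_proportions(["SD", "SD"])
        assert tbl.set_index("recist").loc["SD", "pct"] == 100.0


@pytest.fixture(scope="module")
def cohort_rankings(design, panel):
    singles, pairs = [], []
    for seed in range(6):
        truth = qpop.gen_ground_truth(
            12, planted_pairs=[(0, 1)], effect_scale=0.2, noise_sd=0.02, seed=seed
        )
        plate = qpop.simulate_plate(truth, design, seed=100 + seed)
        model = qpop.fit_quadratic(qpop.normalize(plate), design)
        singles.append(qpop.rank_combinations(model, order=1))
        pairs.append(qpop.rank_combinations(model, order=2))
    return singles, pairs


class TestCohortAggregation:
    def test_planted_pair_counted_in_every_sample(self, cohort_rankings):
        _, pairs = cohort_rankings
        agg = qpop.top_combo_frequencies(pairs, top_k=10)
        top_row = agg.pair_counts.iloc[0]
        assert tuple(top_row["pair"]) == (0, 1)
        assert top_row["count"] == len(pairs)

    def test_single_counts_match_brute_force_recount(self, cohort_rankings):
        _, pairs = cohort_rankings
        agg = qpop.top_combo_frequencies(pairs, top_k=10)
        recount = {}
        for ranking in pairs:
            for therapy in ranking.top(10)["therapy"]:
                for drug in therapy:
                    recount[drug] = recount.get(drug, 0) + 1
        assert dict(zip(agg.single_counts["drug"], agg.single_counts["count"])) == recount

    def test_pair_count_bounded_by_member_counts(self, cohort_rankings):
        _, pairs = cohort_rankings
        agg = qpop.top_combo_frequencies(pairs, top_k=10)
        singles = dict(zip(agg.single_counts["drug"], agg.single_counts["count"]))
        for _, row in agg.pair_counts.iterrows():
            i, j = row["pair"]
            assert row["count"] <= min(singles[i], singles[j])

    def test_correlation_matches_direct_formula(self, cohort_rankings):
        singles, pairs = cohort_rankings
        tbl = qpop.one_vs_two_drug_correlation(singles, pairs, top_k=20)
        assert not tbl.empty
        # recompute r for the first reported drug with the covariance formula
        drug = int(tbl.iloc[0]["drug"])
        pts = []
        for s, p in zip(singles, pairs):
            one = {t[0]: m for t, m in zip(s.summary["therapy"], s.summary["mean_ncv"])}
            for _, row in p.top(20).iterrows():
                if drug in row["therapy"]:
                    pts.append((one[drug], row["mean_ncv"]))
        x, y = np.array(pts).T
        r_direct = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert tbl.iloc[0]["r"] == pytest.approx(r_direct, abs=1e-12)
        assert tbl.iloc[0]["n"] == len(pts)

    def test_affine_relation_gives_r_one(self, cohort_rankings):
        # per sample, fake pairs anchored on drug 0 with two-drug NCV equal
        # to its one-drug NCV minus a constant: pooled r for drug 0 is 1
        import qpop.ranking as rk

        singles, _ = cohort_rankings
        fakes = []
        for single in singles:
            one = {
                t[0]: m
                for t, m in zip(single.summary["therapy"], single.summary["mean_ncv"])
            }
            entries = [
                {
                    "therapy": (0, j),
                    "mean_ncv": one[0] - 0.1,
                    "sd_ncv": 0.0,
                    "best_ncv": one[0] - 0.1,
                    "rank": j,
                    "best_rank": j,
                }
                for j in range(1, 4)
            ]
            fakes.append(
                rk.CombinationRanking(
                    order=2, entries=pd.DataFrame(), summary=pd.DataFrame(entries)
                )
            )
        tbl = qpop.one_vs_two_drug_correlation(singles, fakes, top_k=20)
        row = tbl[tbl["drug"] == 0].iloc[0]
        assert row["r"] == pytest.approx(1.0, abs=1e-9)
        assert row["n"] == 3 * len(singles)


class TestGroupComparison:
    def test_identical_groups_null(self):
        res = qpop.group_mean_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_pooled_t_formula(self):
        a = [0.63, 0.70, 0.58, 0.66, 0.61]
        b = [0.82, 0.79, 0.85, 0.80, 0.84]
        res = qpop.group_mean_comparison(a, b)
        na, nb = len(a), len(b)
        sa2, sb2 = np.var(a, ddof=1), np.var(b, ddof=1)
        sp2 = ((na - 1) * sa2 + (nb - 1) * sb2) / (na + nb - 2)
        t_direct = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
        p_direct = 2 * stats.t.sf(abs(t_direct), na + nb - 2)
        assert res.t == pytest.approx(t_direct, rel=1e-12)
        assert res.p == pytest.approx(p_direct, rel=1e-12)

    def test_paired_constant_difference_degenerate(self):
        res = qpop.group_mean_comparison(
            [1.0, 2.0, 3.0], [0.5, 1.5, 2.5], paired=True
        )
        assert res.degenerate
        assert res.p == 0.0


class TestInVivoFormulas:
    def test_tumor_volume_substitution(self):
        assert qpop.tumor_volume(1.0, 2.0) == pytest.approx(math.pi / 3)
        assert qpop.tumor_volume(1.0, 1.0) == pytest.approx(math.pi / 6)

    def test_cubic_scaling(self):
        assert qpop.tumor_volume(2.0, 4.0) == pytest.approx(8 * qpop.tumor_volume(1.0, 2.0))

    def test_diameter_order_enforced(self):
        with pytest.raises(ValueError, match="exceeds"):
            qpop.tumor_volume(3.0, 2.0)

    @pytest.mark.parametrize(
        "v0, v1, days, expected", [(100, 400, 15, 20.0), (250, 250, 10, 0.0), (300, 150, 10, -15.0)]
    )
    def test_growth_rate(self, v0, v1, days, expected):
        assert qpop.growth_rate(v0, v1, days) == expected

    def test_growth_rate_needs_positive_days(self):
        with pytest.raises(ValueError, match="positive"):
            qpop.growth_rate(100, 200, 0)
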