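"""Cell statistics: exact rank-test enumeration oracles, BH step-up by hand,
normal-equation oracles for the paired model, interaction recovery, and
baseline correlation contracts."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from bulkdecon import cellstats
from bulkdecon.stats import bh_adjust


def make_paired_cohort(n_subjects, rng, group="early-RA", responses=None):
    rows = []
    for i in range(n_subjects):
        resp = responses[i] if responses is not None else "responder"
        for tp in ("pre", "post"):
            rows.append({
                "sample": f"P{i}_{tp}", "subject": f"P{i}", "group": group,
                "timepoint": tp, "treatment": "MTX", "response": resp,
                "age": 50.0, "pct_dup": 0.2, "gc_score": rng.normal(),
            })
    return pd.DataFrame(rows).set_index("sample")


class TestWilcoxonContrast:
    def test_exact_p_matches_enumeration(self):
        """x=[1,2,3] vs y=[4,5,6]: enumeration of the C(6,3)=20 rank
        assignments gives two-sided p = 2/20 = 0.1."""
        pooled = [1, 2, 3, 4, 5, 6]
        observed_u = 0  # every x below every y
        count_extreme = 0
        for combo in itertools.combinations(range(6), 3):
            x = [pooled[i] for i in combo]
            y = [pooled[i] for i in range(6) if i not in combo]
            u = sum(1 for xi in x for yi in y if xi > yi)
            if min(u, 9 - u) <= min(observed_u, 9 - observed_u):
                count_extreme += 1
        expected = count_extreme / 20
        assert expected == 0.1

        scores = pd.DataFrame({"cell": [1.0, 2, 3, 4, 5, 6]},
                              index=[f"s{i}" for i in range(6)])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=scores.index)
        res = cellstats.wilcoxon_contrast(scores, groups)
        assert res["p"].iloc[0] == pytest.approx(expected)
        assert res["direction"].iloc[0] == "up"

    def test_identical_groups_p1(self):
        scores = pd.DataFrame({"cell": [1.0, 2, 3, 1, 2, 3]},
                              index=[f"s{i}" for i in range(6)])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=scores.index)
        res = cellstats.wilcoxon_contrast(scores, groups)
        assert res["p"].iloc[0] == 1.0

    def test_all_tied_warns(self):
        scores = pd.DataFrame({"cell": [2.0] * 6}, index=[f"s{i}" for i in range(6)])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=scores.index)
        with pytest.warns(UserWarning, match="tied"):
            res = cellstats.wilcoxon_contrast(scores, groups)
        assert res["p"].iloc[0] == 1.0

    def test_paired_mode_uses_signed_rank(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=8)
        scores = pd.DataFrame({"cell": np.concatenate([base, base + 1.0])},
                              index=[f"s{i}" for i in range(16)])
        groups = pd.Series(["pre"] * 8 + ["post"] * 8, index=scores.index)
        res = cellstats.wilcoxon_contrast(scores, groups, paired=True, order=("pre", "post"))
        from scipy.stats import wilcoxon

        assert res["p"].iloc[0] == pytest.approx(wilcoxon(base + 1.0, base).pvalue)
        assert res["direction"].iloc[0] == "up"


def test_bh_stepup_matches_hand_formula():
    """q_i = min_{j>=i} p_(j) * m / j on the sorted p-values."""
    p = np.array([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(bh_adjust(p), [0.04, 0.04, 0.04, 0.04])
    p2 = np.array([0.005, 0.04, 0.03, 0.9])
    order = np.argsort(p2)
    m = len(p2)
    raw = p2[order] * m / np.arange(1, m + 1)
    stepped = np.minimum.accumulate(raw[::-1])[::-1]
    expected = np.empty(m)
    expected[order] = np.minimum(stepped, 1.0)
    np.testing.assert_allclose(bh_adjust(p2), expected)


def test_bh_monotone_and_bounded():
    rng = np.random.default_rng(1)
    p = rng.random(50)
    q = bh_adjust(p)
    assert (q >= p - 1e-12).all() and (q <= 1.0).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


class TestTreatmentEffect:
    def test_no_change_gives_zero_coefficient(self):
        rng = np.random.default_rng(2)
        cohort = make_paired_cohort(6, rng)
        vals = rng.normal(size=6)
        scores = pd.DataFrame({"cell": np.repeat(vals, 2)}, index=cohort.index)
        res = cellstats.treatment_effect(scores, cohort)
        assert res["estimate"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_shift_recovered_exactly(self):
        rng = np.random.default_rng(3)
        cohort = make_paired_cohort(6, rng)
        cohort["gc_score"] = 0.0  # orthogonal to treatment
        base = rng.normal(size=6)
        vals = []
        for b in base:
            vals.extend([b, b + 2.5])  # pre, post
        scores = pd.DataFrame({"cell": vals}, index=cohort.index)
        res = cellstats.treatment_effect(scores, cohort, covariates=())
        assert res["estimate"].iloc[0] == pytest.approx(2.5, abs=1e-10)
        assert res["p"].iloc[0] < 1e-50  # saturated fit: p at machine floor

    def test_matches_normal_equations_oracle(self):
        """4-subject toy: coefficient equals the explicit (X'X)^-1 X'y
        solution on a hand-built design."""
        rng = np.random.default_rng(4)
        cohort = make_paired_cohort(4, rng)
        y = rng.normal(size=8)
        scores = pd.DataFrame({"cell": y}, index=cohort.index)

        X = np.zeros((8, 6))
        X[:, 0] = 1.0
        for s in range(1, 4):  # subject indicators (reference = subject 0)
            X[2 * s, 1 + (s - 1)] = 1.0
            X[2 * s + 1, 1 + (s - 1)] = 1.0
        X[:, 4] = cohort["gc_score"].to_numpy()
        X[:, 5] = (cohort["timepoint"] == "post").to_numpy(float)
        beta = np.linalg.inv(X.T @ X) @ X.T @ y
        res = cellstats.treatment_effect(scores, cohort)
        assert res["estimate"].iloc[0] == pytest.approx(beta[5], abs=1e-10)

    def test_equals_paired_differences_regression(self):
        """Fixed-effect model == regressing post-pre differences on an
        intercept and the GC change (within-transformation identity)."""
        rng = np.random.default_rng(5)
        cohort = make_paired_cohort(10, rng)
        scores = pd.DataFrame({"cell": rng.normal(size=20)}, index=cohort.index)
        res = cellstats.treatment_effect(scores, cohort)

        pre = cohort[cohort["timepoint"] == "pre"].sort_values("subject")
        post = cohort[cohort["timepoint"] == "post"].sort_values("subject")
        d = scores.loc[post.index, "cell"].to_numpy() - scores.loc[pre.index, "cell"].to_numpy()
        dgc = post["gc_score"].to_numpy() - pre["gc_score"].to_numpy()
        Xd = np.column_stack([np.ones_like(dgc), dgc])
        beta = np.linalg.lstsq(Xd, d, rcond=None)[0]
        assert res["estimate"].iloc[0] == pytest.approx(beta[0], abs=1e-8)

    def test_unpaired_subject_dropped(self):
        rng = np.random.default_rng(6)
        cohort = make_paired_cohort(4, rng)
        cohort = cohort.drop(index="P3_post")
        scores = pd.DataFrame({"cell": rng.normal(size=len(cohort))}, index=cohort.index)
        with pytest.warns(UserWarning, match="unpaired"):
            res = cellstats.treatment_effect(scores, cohort)
        assert len(res) == 1

    def test_rank_deficient_design_named(self):
        rng = np.random.default_rng(7)
        cohort = make_paired_cohort(4, rng)
        cohort["gc_score"] = (cohort["timepoint"] == "post").astype(float)  # aliases treatment
        scores = pd.DataFrame({"cell": rng.normal(size=8)}, index=cohort.index)
        with pytest.raises(ValueError, match="aliased"):
            cellstats.treatment_effect(scores, cohort)


class TestResponseInteraction:
    def _simulate(self, rng, n=40, responder_shift=0.0, common_shift=0.0):
        responses = ["responder" if i < n // 2 else "non-responder" for i in range(n)]
        cohort = make_paired_cohort(n, rng, responses=responses)
        vals = []
        for i in range(n):
            b = rng.normal()
            shift = common_shift + (responder_shift if responses[i] == "responder" else 0.0)
            vals.extend([b + rng.normal(0, 0.5), b + shift + rng.normal(0, 0.5)])
        scores = pd.DataFrame({"cell": vals}, index=cohort.index)
        return scores, cohort

    def test_null_interaction_unbiased(self):
        """Identical planted shift in both response classes: interaction
        coefficient centers on zero (mean |coef| < 2 SE over simulations)."""
        rng = np.random.default_rng(8)
        coefs, ses = [], []
        for _ in range(200):
            scores, cohort = self._simulate(rng, n=40, common_shift=1.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = cellstats.response_interaction(scores, cohort)
            row = res["model"][res["model"]["term"] == "treatment:response"].iloc[0]
            coefs.append(row["estimate"])
            ses.append(row["estimate"] / row["t"] if row["t"] != 0 else np.nan)
        assert np.mean(np.abs(coefs)) < 2 * np.nanmean(ses)
        assert abs(np.mean(coefs)) < 0.1

    def test_responder_only_shift_recovered(self):
        rng = np.random.default_rng(9)
        scores, cohort = self._simulate(rng, n=40, responder_shift=1.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = cellstats.response_interaction(scores, cohort)
        row = res["model"][res["model"]["term"] == "treatment:response"].iloc[0]
        se = row["estimate"] / row["t"]
        assert abs(row["estimate"] - 1.5) < 2 * se
        assert res["responder"]["significant"].iloc[0]

    def test_single_class_skipped_with_warning(self):
        rng = np.random.default_rng(10)
        scores, cohort = self._simulate(rng, n=10)
        cohort["response"] = "responder"
        with pytest.warns(UserWarning, match="single response class"):
            res = cellstats.response_interaction(scores, cohort)
        assert res["model"].empty


class TestBaselineCorrelations:
    def test_perfect_correlation(self, rng):
        cohort = make_paired_cohort(10, rng)
        scores = pd.DataFrame({"cellA": rng.normal(size=20)}, index=cohort.index)
        cohort["gc_score"] = scores["cellA"]
        res = cellstats.baseline_correlations(scores, cohort, variables=("gc_score",))
        assert res["rho"].iloc[0] == pytest.approx(1.0)

    def test_negated_ranks_give_minus_one(self, rng):
        cohort = make_paired_cohort(10, rng)
        scores = pd.DataFrame({"cellA": rng.normal(size=20)}, index=cohort.index)
        from scipy.stats import rankdata

        cohort["age"] = -rankdata(scores["cellA"])
        res = cellstats.baseline_correlations(scores, cohort, variables=("age",))
        assert res["rho"].iloc[0] == pytest.approx(-1.0)

    def test_constant_variable_reported_missing(self, rng):
        cohort = make_paired_cohort(5, rng)
        cohort["age"] = 50.0
        scores = pd.DataFrame({"cellA": rng.normal(size=10)}, index=cohort.index)
        res = cellstats.baseline_correlations(scores, cohort, variables=("age",))
        assert np.isnan(res["rho"].iloc[0])


def test_direction_table_shape():
    tbl = pd.DataFrame({
        "cell_type": ["a", "b"], "estimate": [1.0, -1.0],
        "p": [0.001, 0.5], "q": [0.002, 0.5], "direction": ["up", "down"],
    })
    out = cellstats.direction_table({"contrast1": tbl}, fdr=0.05)
    assert out.loc["a", "contrast1"] == "up"
    assert out.loc["b", "contrast1"] == "no-change"
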