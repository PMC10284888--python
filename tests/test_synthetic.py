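"""Generator contracts: marker construction, simplex fractions, paired
structure, planted directions, forward count model, flow noise model."""

import numpy as np
import pandas as pd
import pytest

from bulkdecon import synthetic as syn


class TestGenerateReference:
    def test_marker_construction_guarantees_fold(self):
        ref = syn.generate_reference(60, 3, markers_per_type=5, seed=1, marker_fold=8.0)
        sig = ref.to_numpy()
        for k in range(3):
            rows = sig[k * 5:(k + 1) * 5]
            others = np.delete(rows, k, axis=1)
            assert (rows[:, k] >= 8.0 * others.max(axis=1)).all()

    def test_infeasible_marker_budget(self):
        with pytest.raises(ValueError, match="infeasible"):
            syn.generate_reference(10, 5, markers_per_type=5)

    def test_seed_determinism(self):
        a = syn.generate_reference(50, 4, 5, seed=7)
        b = syn.generate_reference(50, 4, 5, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_no_degenerate_rows_or_columns(self):
        ref = syn.generate_reference(80, 5, 6, seed=3)
        assert (ref.to_numpy() >= 0).all()
        assert (ref.sum(axis=1) > 0).all()
        assert (ref.sum(axis=0) > 0).all()
        assert ref.index.is_unique


class TestSimulateFractions:
    def test_simplex_and_pairing(self):
        truth = syn.simulate_fractions(syn.CohortDesign(n_healthy=4, n_mtx=5, n_tnfi=4, seed=3))
        sums = truth.fractions.sum(axis=1).to_numpy()
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert (truth.fractions.to_numpy() >= 0).all()
        per_subject = truth.meta.groupby("subject")["timepoint"].agg(sorted)
        assert all(tp == ["post", "pre"] for tp in per_subject)

    def test_high_concentration_collapses_to_uniform(self):
        k = 8
        base = pd.Series(np.ones(k) / k, index=[f"c{i}" for i in range(k)])
        truth = syn.simulate_fractions(
            syn.CohortDesign(n_healthy=5, n_mtx=5, n_tnfi=5, seed=0),
            shift_spec={},
            response_spec={},
            base_mean=base,
            subject_concentration=1e6,
            sample_concentration=1e6,
        )
        assert np.abs(truth.fractions.to_numpy() - 1.0 / k).max() < 0.01

    def test_tilt_matches_analytic_dirichlet_mean(self):
        """Monocyte tilt x2 in RA: simulated group mean tracks the analytic
        tilted (renormalized) Dirichlet mean within Monte-Carlo error."""
        k = 5
        cells = [f"c{i}" for i in range(k)]
        base = pd.Series(np.full(k, 0.2), index=cells)
        spec = {("early-RA", "pre"): {"c0": 2.0}}
        truth = syn.simulate_fractions(
            syn.CohortDesign(n_healthy=250, n_mtx=250, n_tnfi=1, seed=5),
            shift_spec=spec,
            response_spec={},
            base_mean=base,
            subject_concentration=500.0,
            sample_concentration=5000.0,
        )
        pre = truth.meta["timepoint"] == "pre"
        ra = truth.fractions[pre & (truth.meta["group"] == "early-RA")]["c0"].mean()
        healthy = truth.fractions[pre & (truth.meta["group"] == "healthy")]["c0"].mean()
        analytic = 0.2 * 2.0 / (0.2 * 2.0 + 0.8)  # = 1/3
        assert healthy == pytest.approx(0.2, abs=0.01)
        assert ra == pytest.approx(analytic, abs=0.015)

    def test_negative_tilt_rejected(self):
        with pytest.raises(ValueError, match="negative tilt"):
            syn.simulate_fractions(
                syn.CohortDesign(seed=0),
                shift_spec={("early-RA", "pre"): {"Th1": -1.0}},
            )

    def test_determinism(self):
        d = syn.CohortDesign(n_healthy=3, n_mtx=3, n_tnfi=3, seed=9)
        a = syn.simulate_fractions(d)
        b = syn.simulate_fractions(d)
        pd.testing.assert_frame_equal(a.fractions, b.fractions)
        pd.testing.assert_frame_equal(a.meta, b.meta)

    def test_planted_disease_directions(self):
        """Default shifts: monocytes/Th1/Th2 up and mature NK down in RA
        group means relative to healthy."""
        truth = syn.simulate_fractions(
            syn.CohortDesign(n_healthy=60, n_mtx=60, n_tnfi=60, seed=2),
            subject_concentration=100.0,
            sample_concentration=2000.0,
        )
        pre = truth.meta["timepoint"] == "pre"
        mean = truth.fractions[pre].groupby(truth.meta.loc[pre.index[pre], "group"]).mean()
        for cell in ["classical monocyte", "non-classical monocyte", "Th1", "Th2"]:
            assert mean.loc["early-RA", cell] > mean.loc["healthy", cell]
            assert mean.loc["established-RA", cell] > mean.loc["healthy", cell]
        assert mean.loc["early-RA", "mature NK"] < mean.loc["healthy", "mature NK"]
        assert mean.loc["established-RA", "mature B"] < mean.loc["healthy", "mature B"]


class TestSimulateCounts:
    def test_pure_sample_proportional_to_signature(self):
        ref = syn.generate_reference(60, 3, 5, seed=1)
        cells = list(ref.columns)
        meta = pd.DataFrame(
            {
                "subject": ["s1"],
                "group": ["healthy"],
                "timepoint": ["pre"],
                "treatment": ["none"],
                "response": [""],
                "age": [50.0],
                "pct_dup": [0.2],
                "gc_exposure": [0.0],
            },
            index=pd.Index(["s1_pre"], name="sample"),
        )
        frac = pd.DataFrame([[1.0, 0.0, 0.0]], index=meta.index, columns=cells)
        truth = syn.SampleTruth(frac, meta, pd.DataFrame(columns=["gene", "lfc", "cell_types"]))
        counts = syn.simulate_counts(truth, ref, lib_size_mean=5e6, lib_size_sigma=0.0,
                                     dispersion=0.0, seed=4)
        r = np.corrcoef(counts["s1_pre"], ref[cells[0]])[0, 1]
        assert r > 0.999

    def test_intrinsic_effect_doubles_post_counts(self):
        """log2FC=1 on one gene in all cell types with frozen fractions:
        the post/pre mean count ratio is ~2 (NB mean model)."""
        ref = syn.generate_reference(50, 3, 5, seed=2)
        gene = ref.index[40]
        eff = pd.DataFrame({"gene": [gene], "lfc": [1.0], "cell_types": [("all",)]})
        truth = syn.simulate_fractions(
            syn.CohortDesign(n_healthy=2, n_mtx=150, n_tnfi=2, seed=3),
            base_mean=syn.default_base_mean(ref.columns),
            shift_spec={},
            response_spec={},
            intrinsic_effects=eff,
            freeze_pairs=True,
        )
        counts = syn.simulate_counts(truth, ref, lib_size_mean=2e5, lib_size_sigma=0.0,
                                     dispersion=0.05, seed=5)
        mtx = truth.meta["treatment"] == "MTX"
        pre = counts.loc[gene, (truth.meta["timepoint"] == "pre") & mtx]
        post = counts.loc[gene, (truth.meta["timepoint"] == "post") & mtx]
        assert post.mean() / pre.mean() == pytest.approx(2.0, rel=0.1)

    def test_zero_gc_exposure_leaves_expectation(self):
        """With every exposure at zero the GC scaling is exp(0)=1: counts
        of GC genes match a run without any GC set."""
        ref = syn.generate_reference(40, 3, 5, seed=6)
        truth = syn.simulate_fractions(
            syn.CohortDesign(n_healthy=5, n_mtx=2, n_tnfi=2, seed=6),
            base_mean=syn.default_base_mean(ref.columns),
            gc_lognorm_mean=-np.inf,  # lognormal -> 0
        )
        truth.meta["gc_exposure"] = 0.0
        gc_set = list(ref.index[30:35])
        a = syn.simulate_counts(truth, ref, gc_gene_set=gc_set, seed=8)
        b = syn.simulate_counts(truth, ref, gc_gene_set=None, seed=8)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_gc_gene_raises(self):
        ref = syn.generate_reference(30, 3, 5, seed=1)
        truth = syn.simulate_fractions(
            syn.CohortDesign(n_healthy=2, n_mtx=2, n_tnfi=2, seed=1),
            base_mean=syn.default_base_mean(ref.columns),
        )
        with pytest.raises(KeyError, match="absent from reference"):
            syn.simulate_counts(truth, ref, gc_gene_set=["NOT_A_GENE"])


class TestSimulateFlow:
    def test_zero_noise_equals_aggregated_truth(self):
        truth = syn.simulate_fractions(syn.CohortDesign(n_healthy=3, n_mtx=3, n_tnfi=3, seed=4))
        flow = syn.simulate_flow(truth, cv_noise=0.0, seed=0)
        for pop, members in syn.DEFAULT_FLOW_MAP.items():
            expected = truth.fractions[list(members)].sum(axis=1)
            np.testing.assert_allclose(flow[pop], expected)

    def test_noise_preserves_rank_tracking(self):
        truth = syn.simulate_fractions(syn.CohortDesign(n_healthy=34, n_mtx=33, n_tnfi=33, seed=5))
        flow = syn.simulate_flow(truth, cv_noise=0.2, seed=1)
        from scipy.stats import spearmanr

        for pop, members in syn.DEFAULT_FLOW_MAP.items():
            r = spearmanr(flow[pop], truth.fractions[list(members)].sum(axis=1)).statistic
            assert r > 0.9

    def test_empty_map_warns(self):
        truth = syn.simulate_fractions(syn.CohortDesign(n_healthy=2, n_mtx=2, n_tnfi=2, seed=6))
        with pytest.warns(UserWarning, match="empty aggregation map"):
            flow = syn.simulate_flow(truth, aggregation_map={}, cv_noise=0.1)
        assert flow.empty

    def test_unknown_population_member_raises(self):
        truth = syn.simulate_fractions(syn.CohortDesign(n_healthy=2, n_mtx=2, n_tnfi=2, seed=6))
        with pytest.raises(KeyError, match="unknown cell types"):
            syn.simulate_flow(truth, aggregation_map={"X": ("no-such-type",)})


def test_cohort_bundle_determinism():
    kw = dict(
        design=syn.CohortDesign(n_healthy=3, n_mtx=4, n_tnfi=3, seed=21),
        n_genes=300, n_cell_types=6, markers_per_type=5, seed=21,
    )
    a = syn.simulate_cohort(**kw)
    b = syn.simulate_cohort(**kw)
    pd.testing.assert_frame_equal(a.counts, b.counts)
    pd.testing.assert_frame_equal(a.flow, b.flow)
    assert a.gc_gene_set == b.gc_gene_set
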