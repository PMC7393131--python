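"""z-transform, regulation calls, pathway scores and sensitivity correlation."""

import numpy as np
import pandas as pd
import pytest

from radiometab.config import RunConfig
from radiometab.errors import (
    ConfigurationError,
    SampleSizeError,
    ValidationError,
)
from radiometab.msprep import FoldChangeTable
from radiometab.pathway_corr import (
    RegulationCalls,
    ResistanceScore,
    ZMatrix,
    correlate_pathways,
    pathway_scores,
    post_rt_pathway_analysis,
    regulation_calls,
    z_transform,
)
from radiometab.synthetic_data import (
    default_pathway_map,
    simulate_metabolite_panel,
)


def _matrix(rows, lines=None):
    lines = lines or [f"L{i}" for i in range(len(next(iter(rows.values()))))]
    return pd.DataFrame(rows, index=lines).T


class TestZTransform:
    def test_three_line_row_standardized(self):
        z = z_transform(_matrix({"m1": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(z.z.loc["m1"], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_constant_row_dropped_not_zeroed(self):
        z = z_transform(_matrix({"m1": [5.0, 5.0, 5.0],
                                 "m2": [1.0, 2.0, 3.0]}))
        assert z.dropped == ["m1"]
        assert "m1" not in z.z.index

    def test_idempotent_on_standardized_rows(self, rng):
        x = rng.standard_normal(8)
        x = (x - x.mean()) / x.std(ddof=1)
        z = z_transform(_matrix({"m": list(x)}))
        np.testing.assert_allclose(z.z.loc["m"], x, atol=1e-9)

    def test_rows_have_zero_mean_unit_sd(self, rng):
        mat = pd.DataFrame(rng.uniform(1, 100, size=(6, 10)))
        z = z_transform(mat).z.to_numpy()
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_pairwise_complete_with_missing(self):
        z = z_transform(_matrix({"m": [1.0, 2.0, 3.0, np.nan]}))
        assert z.n_effective.loc["m"] == 3
        np.testing.assert_allclose(z.z.loc["m"].iloc[:3], [-1, 0, 1],
                                   atol=1e-12)

    def test_too_few_units_rejected(self):
        with pytest.raises(SampleSizeError):
            z_transform(_matrix({"m": [1.0, 2.0]}))


class TestRegulationCalls:
    def test_strict_boundary_semantics(self):
        z = ZMatrix(z=_matrix({"m": [-1.5, -1.0, 0.0, 1.0, 1.1]}))
        calls = regulation_calls(z).calls.loc["m"]
        np.testing.assert_array_equal(calls, [-1, 0, 0, 0, 1])

    def test_interior_values_all_none(self):
        z = ZMatrix(z=_matrix({"m": [-0.99, 0.0, 0.99]}))
        assert (regulation_calls(z).calls.loc["m"] == 0).all()

    def test_thresholds_respected(self):
        z = ZMatrix(z=_matrix({"m": [-1.5, 0.0, 1.5]}))
        calls = regulation_calls(z, z_lower=-2.0, z_upper=2.0).calls.loc["m"]
        assert (calls == 0).all()

    def test_inverted_thresholds_rejected(self):
        z = ZMatrix(z=_matrix({"m": [-1.0, 0.0, 1.0]}))
        with pytest.raises(ConfigurationError):
            regulation_calls(z, z_lower=1.0, z_upper=-1.0)


class TestPathwayScores:
    def _calls(self, rows, lines=None):
        return RegulationCalls(calls=_matrix(rows, lines), z_lower=-1,
                               z_upper=1)

    def test_fraction_definition(self):
        calls = self._calls({"m1": [-1], "m2": [-1], "m3": [0], "m4": [1]},
                            lines=["A"])
        pmap = pd.DataFrame({"metabolite": ["m1", "m2", "m3", "m4"],
                             "pathway": ["p"] * 4})
        scores = pathway_scores(calls, pmap)
        assert scores.down.loc["p", "A"] == pytest.approx(0.5)
        assert scores.up.loc["p", "A"] == pytest.approx(0.25)
        assert scores.n_measured.loc["p", "A"] == 4

    def test_all_none_pathway_scores_zero(self):
        calls = self._calls({"m1": [0], "m2": [0]}, lines=["A"])
        pmap = pd.DataFrame({"metabolite": ["m1", "m2"], "pathway": ["p", "p"]})
        scores = pathway_scores(calls, pmap)
        assert scores.down.loc["p", "A"] == 0.0
        assert scores.up.loc["p", "A"] == 0.0

    def test_singleton_pathway(self):
        calls = self._calls({"m1": [-1]}, lines=["A"])
        pmap = pd.DataFrame({"metabolite": ["m1"], "pathway": ["p"]})
        assert pathway_scores(calls, pmap).down.loc["p", "A"] == 1.0

    def test_down_plus_up_bounded_by_one(self, rng):
        z = ZMatrix(z=pd.DataFrame(rng.standard_normal((20, 10)),
                                   index=[f"m{i}" for i in range(20)]))
        calls = regulation_calls(z)
        pmap = pd.DataFrame({"metabolite": [f"m{i}" for i in range(20)],
                             "pathway": [f"p{i % 4}" for i in range(20)]})
        scores = pathway_scores(calls, pmap)
        total = scores.down.to_numpy() + scores.up.to_numpy()
        assert np.all(total <= 1.0 + 1e-12)

    def test_duplicate_pathway_membership_rejected(self):
        calls = self._calls({"m1": [0]}, lines=["A"])
        pmap = pd.DataFrame({"metabolite": ["m1", "m1"],
                             "pathway": ["p", "q"]})
        with pytest.raises(ValidationError):
            pathway_scores(calls, pmap)

    def test_unmapped_metabolites_counted(self):
        calls = self._calls({"m1": [0], "zzz": [0]}, lines=["A"])
        pmap = pd.DataFrame({"metabolite": ["m1"], "pathway": ["p"]})
        assert pathway_scores(calls, pmap).unmapped == ["zzz"]


def _brute_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / (sxx * syy) ** 0.5
    from scipy import stats
    t = r * ((n - 2) / (1 - r * r)) ** 0.5
    return r, 2 * stats.t.sf(abs(t), n - 2)


class TestCorrelatePathways:
    def _scores(self, down_rows, lines):
        down = _matrix(down_rows, lines)
        return type("S", (), {})(), down

    def test_perfect_coupling_gives_r_one(self):
        lines = list("ABCDE")
        down = _matrix({"p": [0.1, 0.2, 0.3, 0.4, 0.5]}, lines)
        from radiometab.pathway_corr import PathwayScores
        scores = PathwayScores(down=down, up=down * 0.0,
                               n_measured=down * 0 + 4)
        dmid = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0], index=lines)
        out = correlate_pathways(scores, ResistanceScore(dmid), "down")
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_matches_textbook_oracle(self):
        lines = list("ABCDE")
        down_vals = [0.2, 0.4, 0.1, 0.5, 0.3]
        dmid_vals = [5.0, 3.5, 6.0, 2.0, 4.2]
        from radiometab.pathway_corr import PathwayScores
        down = _matrix({"p": down_vals}, lines)
        scores = PathwayScores(down=down, up=down * 0.0,
                               n_measured=down * 0 + 3)
        out = correlate_pathways(
            scores, ResistanceScore(pd.Series(dmid_vals, index=lines)), "down")
        r_ref, p_ref = _brute_pearson(down_vals, [-d for d in dmid_vals])
        assert out["r"].iloc[0] == pytest.approx(r_ref, abs=1e-9)
        assert out["p"].iloc[0] == pytest.approx(p_ref, abs=1e-9)

    def test_synthetic_coupled_pathway_ranks_first(self):
        panel, resistance, truth = simulate_metabolite_panel(seed=1)
        z = z_transform(panel)
        scores = pathway_scores(regulation_calls(z), default_pathway_map())
        out = correlate_pathways(scores, resistance, "down").dropna(
            subset=["r"])
        best = out.iloc[out["r"].abs().to_numpy().argmax()]
        assert best["pathway"] == truth.panel["coupled_pathway"]

    def test_zero_variance_pathway_reported_missing(self):
        lines = list("ABC")
        from radiometab.pathway_corr import PathwayScores
        down = _matrix({"p": [0.0, 0.0, 0.0], "q": [0.1, 0.5, 0.2]}, lines)
        scores = PathwayScores(down=down, up=down * 0.0,
                               n_measured=down * 0 + 3)
        out = correlate_pathways(
            scores, ResistanceScore(pd.Series([1.0, 2.0, 3.0], index=lines)),
            "down")
        assert np.isnan(out.set_index("pathway").loc["p", "r"])

    def test_mismatched_line_sets_rejected(self):
        from radiometab.pathway_corr import PathwayScores
        down = _matrix({"p": [0.1, 0.5, 0.2]}, list("ABC"))
        scores = PathwayScores(down=down, up=down * 0.0,
                               n_measured=down * 0 + 3)
        resistance = ResistanceScore(
            pd.Series([1.0, 2.0, 3.0, 4.0], index=list("ABCD")))
        with pytest.raises(ValidationError):
            correlate_pathways(scores, resistance, "down")


class TestPipelineInvariances:
    def _run(self, panel, resistance, pmap):
        z = z_transform(panel)
        scores = pathway_scores(regulation_calls(z), pmap)
        return correlate_pathways(scores, resistance, "down") \
            .set_index("pathway")["r"]

    def test_invariant_to_metabolite_and_line_permutation(self, rng):
        panel, resistance, _ = simulate_metabolite_panel(n_lines=8, seed=3)
        pmap = default_pathway_map()
        base = self._run(panel, resistance, pmap)
        shuffled = panel.data.sample(frac=1.0, random_state=5) \
            .reset_index(drop=True)
        from radiometab.msprep import MetabolitePanel
        perm = self._run(MetabolitePanel(shuffled), resistance, pmap)
        pd.testing.assert_series_equal(base.sort_index(), perm.sort_index())

    def test_invariant_to_per_metabolite_affine_rescaling(self, rng):
        panel, resistance, _ = simulate_metabolite_panel(n_lines=8, seed=4)
        pmap = default_pathway_map()
        base = self._run(panel, resistance, pmap)
        data = panel.data.copy()
        mets = data["metabolite"].unique()
        scale = dict(zip(mets, rng.uniform(0.5, 3.0, size=mets.size)))
        shift = dict(zip(mets, rng.uniform(0.0, 50.0, size=mets.size)))
        data["area"] = (data["area"] * data["metabolite"].map(scale)
                        + data["metabolite"].map(shift))
        from radiometab.msprep import MetabolitePanel
        rescaled = self._run(MetabolitePanel(data), resistance, pmap)
        pd.testing.assert_series_equal(base.sort_index(),
                                       rescaled.sort_index(),
                                       atol=1e-9, rtol=0)


class TestPostRT:
    def test_unit_fold_changes_yield_empty_result(self):
        lines = list("ABCD")
        fc = FoldChangeTable(values=pd.DataFrame(
            1.0, index=["m1", "m2"], columns=lines))
        resistance = ResistanceScore(
            pd.Series([1.0, 2.0, 3.0, 4.0], index=lines))
        pmap = pd.DataFrame({"metabolite": ["m1", "m2"], "pathway": ["p", "p"]})
        corr, scores, _ = post_rt_pathway_analysis(fc, resistance, pmap)
        assert corr.empty

    def test_resistant_only_upshift_couples_down_score_to_sensitivity(self):
        # 4 lines: the 2 radioresistant ones (large Dmid) raise the "pur"
        # pathway after irradiation; sensitive lines do not.
        # with 4 units a clean 2-vs-2 split peaks at |z| = 0.866, so each
        # metabolite is depleted markedly in one sensitive line only
        lines = ["R1", "R2", "S1", "S2"]
        dmid = pd.Series([5.0, 4.8, 1.5, 1.7], index=lines)
        values = {
            "pur_m0": [3.0, 2.8, 0.4, 1.5],
            "pur_m1": [2.9, 3.1, 1.4, 0.45],
            "pur_m2": [3.2, 2.7, 0.5, 1.4],
            "pur_m3": [2.8, 3.0, 1.5, 0.5],
        }
        gen = np.random.default_rng(11)
        for i in range(4):
            values[f"other_m{i}"] = list(gen.uniform(0.8, 1.2, size=4))
        fc = FoldChangeTable(values=pd.DataFrame(values, index=lines).T)
        pmap = pd.DataFrame({
            "metabolite": list(values),
            "pathway": ["pur"] * 4 + ["other"] * 4,
        })
        corr, _, _ = post_rt_pathway_analysis(
            fc, ResistanceScore(dmid), pmap)
        down = corr[corr["direction"] == "down"].set_index("pathway")
        # depleted purines in sensitive lines: down-score tracks sensitivity
        assert down.loc["pur", "r"] > 0.9

    def test_line_without_control_excluded_upstream(self):
        # pairing is enforced in fold_change; here missing values just
        # reduce the effective n
        lines = list("ABCD")
        vals = pd.DataFrame({"A": [2.0, 1.2], "B": [1.5, 0.9],
                             "C": [0.7, 1.1], "D": [np.nan, np.nan]},
                            index=["m1", "m2"])
        fc = FoldChangeTable(values=vals)
        resistance = ResistanceScore(
            pd.Series([1.0, 2.0, 3.0, 4.0], index=lines))
        pmap = pd.DataFrame({"metabolite": ["m1", "m2"], "pathway": ["p", "p"]})
        corr, _, _ = post_rt_pathway_analysis(fc, resistance, pmap)
        assert (corr["n"].dropna() <= 3).all()


class TestNullBehaviour:
    def test_null_coupling_estimates_center_on_zero(self):
        rs = []
        for seed in range(60):
            panel, resistance, _ = simulate_metabolite_panel(
                n_lines=10, r_true=0.0, seed=seed)
            z = z_transform(panel)
            scores = pathway_scores(regulation_calls(z),
                                    default_pathway_map())
            out = correlate_pathways(scores, resistance, "down") \
                .set_index("pathway")
            r = out.loc["guanylates", "r"]
            if np.isfinite(r):
                rs.append(r)
        assert abs(np.mean(rs)) < 0.08
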