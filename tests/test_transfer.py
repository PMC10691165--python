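import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import combosc as csc

from conftest import make_matrix


class TestIC50Scaling:
    def test_rank_normalised_and_bounded(self):
        ic50 = pd.DataFrame({"d": [-2.0, 0.0, 3.0, 5.0]},
                            index=list("abcd"))
        sens = csc.sensitivity_from_ic50(ic50)
        # most sensitive line (lowest IC50) gets 1, least gets 0
        assert sens["d"].tolist() == pytest.approx([1.0, 2 / 3, 1 / 3, 0.0])


class TestClusterProfile:
    def _setup(self, values, small_panel):
        genes = small_panel.gene_ids[:1]
        m = make_matrix(np.array(values).reshape(-1, 1),
                        gene_ids=genes, normalize=False)
        m.norm = np.array(values, dtype=float).reshape(-1, 1)
        meta = pd.DataFrame({"cell_id": m.cell_ids,
                             "cluster": [0] * len(values)})
        return m, meta

    def test_median_of_odd_cluster(self, small_panel):
        m, meta = self._setup([0, 1, 5], small_panel)
        prof = csc.cluster_profile(m, meta, 0, small_panel)
        assert prof.iloc[0] == 1

    def test_even_cluster_uses_midpoint(self, small_panel):
        m, meta = self._setup([0, 2], small_panel)
        prof = csc.cluster_profile(m, meta, 0, small_panel)
        assert prof.iloc[0] == 1

    def test_singleton_cluster_is_the_cell(self, small_panel):
        m, meta = self._setup([3], small_panel)
        prof = csc.cluster_profile(m, meta, 0, small_panel)
        assert prof.iloc[0] == 3


class TestSimilarity:
    def test_identical_profile_scores_one(self, small_panel):
        prof = small_panel.profiles.iloc[2]
        sims = csc.similarity(prof, small_panel)
        assert sims["L2"] == pytest.approx(1.0)
        assert sims.idxmax() == "L2"

    def test_negated_centered_profile_scores_minus_one(self, small_panel):
        centered = small_panel.profiles.iloc[1] - \
            small_panel.profiles.iloc[1].mean()
        # score against a centered copy of the line added to the panel
        panel = csc.ReferencePanel(
            profiles=pd.concat(
                [small_panel.profiles,
                 centered.to_frame("Lc").T]),
            sensitivity=pd.concat(
                [small_panel.sensitivity,
                 small_panel.sensitivity.iloc[[1]].set_axis(["Lc"])]),
        )
        sims = csc.similarity(-centered, panel)
        assert sims["Lc"] == pytest.approx(-1.0)

    def test_matches_brute_force_recomputation(self, small_panel):
        rng = np.random.default_rng(3)
        prof = pd.Series(rng.gamma(2, 2, size=40),
                         index=small_panel.gene_ids)
        sims = csc.similarity(prof, small_panel, n_features=25)
        feats = csc.transfer.select_features(small_panel, 25)
        x = prof[feats].to_numpy()
        for line in small_panel.line_ids:
            y = small_panel.profiles.loc[line, feats].to_numpy()
            cos = x @ y / (np.linalg.norm(x) * np.linalg.norm(y))
            rho = spearmanr(x, y).statistic
            assert sims[line] == pytest.approx((cos + rho) / 2, abs=1e-12)

    def test_zero_variance_profile_warns_zero(self, small_panel):
        prof = pd.Series(1.0, index=small_panel.gene_ids)
        with pytest.warns(UserWarning, match="zero variance"):
            sims = csc.similarity(prof, small_panel)
        assert (sims == 0).all()

    def test_gene_permutation_invariance(self, small_panel):
        rng = np.random.default_rng(5)
        prof = pd.Series(rng.gamma(2, 2, size=40),
                         index=small_panel.gene_ids)
        perm = rng.permutation(small_panel.gene_ids)
        shuffled = csc.ReferencePanel(
            profiles=small_panel.profiles[perm],
            sensitivity=small_panel.sensitivity,
        )
        s1 = csc.similarity(prof, small_panel)
        s2 = csc.similarity(prof[perm], shuffled)
        pd.testing.assert_series_equal(s1, s2)


class TestMaxCellSimilarity:
    def test_cell_equal_to_line_gives_one(self, small_panel):
        cells = small_panel.profiles.iloc[[0]].set_axis(["cell0"])
        assert csc.max_cell_similarity(cells, small_panel) == \
            pytest.approx(1.0)

    def test_matches_double_loop(self, small_panel):
        rng = np.random.default_rng(11)
        cells = pd.DataFrame(rng.gamma(2, 2, size=(10, 40)),
                             columns=small_panel.gene_ids)
        got = csc.max_cell_similarity(cells, small_panel, n_features=30)
        feats = csc.transfer.select_features(small_panel, 30)
        best = -np.inf
        for _, cell in cells.iterrows():
            for line in small_panel.line_ids:
                x = cell[feats].to_numpy()
                y = small_panel.profiles.loc[line, feats].to_numpy()
                cos = x @ y / (np.linalg.norm(x) * np.linalg.norm(y))
                rho = spearmanr(x, y).statistic
                best = max(best, (cos + rho) / 2)
        assert got == pytest.approx(best, abs=1e-12)


class TestAssignResponse:
    def _sims(self, best, small_panel):
        vals = np.full(5, min(best - 0.2, 0.1))
        sims = pd.Series(vals, index=small_panel.line_ids)
        sims["L1"] = best
        return sims

    @pytest.mark.parametrize("best,tier", [
        (0.9, "direct"), (0.5, "refined"), (0.3, "ignored"),
        (0.8, "refined"),   # 'above 0.8' is strict: 0.8 itself refines
        (0.4, "ignored"),   # 'above 0.4' is strict: 0.4 itself is ignored
        (0.81, "direct"), (0.41, "refined"),
    ])
    def test_tier_breakpoints(self, best, tier, small_panel):
        asg = csc.assign_response(self._sims(best, small_panel), small_panel)
        assert asg.tier == tier
        assert asg.best_similarity == pytest.approx(best)
        assert (asg.response is None) == (tier == "ignored")

    def test_direct_copies_best_line(self, small_panel):
        asg = csc.assign_response(self._sims(0.95, small_panel), small_panel)
        assert asg.best_line == "L1"
        pd.testing.assert_series_equal(
            asg.response, small_panel.sensitivity.loc["L1"],
            check_names=False,
        )

    def test_refined_is_convex_combination(self, small_panel):
        rng = np.random.default_rng(2)
        sims = pd.Series(rng.uniform(0.0, 0.7, size=5),
                         index=small_panel.line_ids)
        sims.iloc[0] = 0.7
        asg = csc.assign_response(sims, small_panel)
        assert asg.tier == "refined"
        lo = small_panel.sensitivity.min(axis=0)
        hi = small_panel.sensitivity.max(axis=0)
        assert ((asg.response >= lo - 1e-12) &
                (asg.response <= hi + 1e-12)).all()
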