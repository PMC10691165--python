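import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import combosc as csc
from combosc.expression import ValidationError
from combosc.trajectories import TrajectoryDef, TrajectoryResult

from conftest import make_matrix

TD = TrajectoryDef("active_t_exhaustion", "T_active", "T_exhausted")


def _meta(n_start, n_end, other=0):
    types = (["T_active"] * n_start + ["T_exhausted"] * n_end +
             ["B cell"] * other)
    return pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(len(types))],
        "sample_id": "s",
        "cell_type": types,
        "is_malignant": False,
    })


class TestTrajectoryScore:
    def test_ratio(self):
        assert csc.trajectory_score(_meta(100, 50), TD) == pytest.approx(0.5)

    def test_absent_start_is_na(self):
        assert np.isnan(csc.trajectory_score(_meta(0, 50), TD))

    def test_end_below_min_cells_is_na(self):
        assert np.isnan(csc.trajectory_score(_meta(100, 0), TD))
        assert np.isnan(csc.trajectory_score(_meta(100, 9), TD))

    def test_scale_free_under_cell_duplication(self):
        s1 = csc.trajectory_score(_meta(40, 20), TD)
        s2 = csc.trajectory_score(_meta(80, 40), TD)
        assert s1 == pytest.approx(s2)

    def test_same_start_and_end_label_rejected(self):
        with pytest.raises(ValidationError):
            TrajectoryDef("bad", "T_active", "T_active")


def _deg_matrix(shift, n_per_side=50, n_genes=30, seed=0):
    """Counts with gene 0 multiplied by 2**shift in the end cells."""
    rng = np.random.default_rng(seed)
    mu = np.full(n_genes, 20.0)
    start = rng.poisson(mu, size=(n_per_side, n_genes))
    mu_end = mu.copy()
    mu_end[0] *= 2.0 ** shift
    end = rng.poisson(mu_end, size=(n_per_side, n_genes))
    counts = np.vstack([start, end])
    m = make_matrix(counts, normalize=True)
    meta = _meta(n_per_side, n_per_side)
    return m, meta


class TestTrajectoryDEGs:
    def test_planted_shift_detected_with_positive_direction(self):
        m, meta = _deg_matrix(shift=3)
        degs = csc.trajectory_degs(m, meta, TD)
        assert "G0" in set(degs["gene"])
        row = degs.set_index("gene").loc["G0"]
        assert row["direction"] == 1 and row["p"] < 1e-5

    def test_direction_flips_when_endpoints_swap(self):
        m, meta = _deg_matrix(shift=3)
        rev = TrajectoryDef("rev", "T_exhausted", "T_active")
        fwd = csc.trajectory_degs(m, meta, TD).set_index("gene")
        back = csc.trajectory_degs(m, meta, rev).set_index("gene")
        shared = fwd.index.intersection(back.index)
        assert len(shared) > 0
        assert (fwd.loc[shared, "direction"] ==
                -back.loc[shared, "direction"]).all()

    def test_identical_groups_yield_no_signature(self):
        m, meta = _deg_matrix(shift=0)
        degs = csc.trajectory_degs(m, meta, TD)
        assert degs.empty

    def test_null_genes_rarely_pass(self):
        # 1000 null genes: the p < 1e-5 cut should admit ~none
        total = 0
        for seed in range(10):
            m, meta = _deg_matrix(shift=0, n_genes=100, seed=seed)
            total += len(csc.trajectory_degs(m, meta, TD))
        assert total <= 2

    def test_too_few_cells_per_side_rejected(self):
        m, meta = _deg_matrix(shift=1, n_per_side=2)
        with pytest.raises(ValidationError, match="at least 3"):
            csc.trajectory_degs(m, meta, TD)


def _degs(genes, directions):
    return pd.DataFrame({"gene": genes, "log2fc": directions,
                         "p": 1e-9, "adj_p": 1e-6,
                         "direction": directions})


def _lib(rows: dict):
    return csc.SignatureLibrary(signatures=pd.DataFrame(rows).T)


class TestReversalScore:
    query = _degs(["A", "B", "C"], [1, 1, -1])

    def test_exact_negation_scores_one(self):
        lib = _lib({"d": pd.Series({"A": -1.0, "B": -1.0, "C": 1.0})})
        assert csc.reversal_score(self.query, lib, "d") == pytest.approx(1.0)

    def test_mimicry_scores_minus_one(self):
        lib = _lib({"d": pd.Series({"A": 1.0, "B": 1.0, "C": -1.0})})
        assert csc.reversal_score(self.query, lib, "d") == pytest.approx(-1.0)

    def test_orthogonal_scores_zero(self):
        lib = _lib({"d": pd.Series({"A": 1.0, "B": -1.0})})
        assert csc.reversal_score(self.query, lib, "d") == pytest.approx(0.0)

    def test_no_overlap_warns_zero(self):
        lib = _lib({"d": pd.Series({"X": 1.0})})
        with pytest.warns(UserWarning, match="no overlap"):
            assert csc.reversal_score(self.query, lib, "d") == 0.0

    @given(st.lists(st.sampled_from([-1.0, 1.0]), min_size=3, max_size=3))
    def test_antisymmetric_under_signature_negation(self, signs):
        lib = _lib({
            "d": pd.Series(dict(zip("ABC", signs))),
            "neg": pd.Series(dict(zip("ABC", [-s for s in signs]))),
        })
        s1 = csc.reversal_score(self.query, lib, "d")
        s2 = csc.reversal_score(self.query, lib, "neg")
        assert s1 == pytest.approx(-s2)


class TestTrajectoryDrugMatrix:
    def test_perfect_reverser_maps_to_one(self):
        res = [TrajectoryResult("t1", 0.5, 20, 10,
                                _degs(["A", "B"], [1, -1]))]
        lib = _lib({"d": pd.Series({"A": -1.0, "B": 1.0})})
        W = csc.trajectory_drug_matrix(res, lib)
        assert W.loc["d", "t1"] == pytest.approx(1.0)

    def test_na_trajectory_dropped(self):
        res = [
            TrajectoryResult("t1", 0.5, 20, 10, _degs(["A"], [1])),
            TrajectoryResult("t2", float("nan"), 0, 10, None),
        ]
        lib = _lib({"d": pd.Series({"A": -1.0})})
        W = csc.trajectory_drug_matrix(res, lib)
        assert list(W.columns) == ["t1"]

    def test_all_na_is_an_error(self):
        res = [TrajectoryResult("t1", float("nan"), 0, 0, None)]
        lib = _lib({"d": pd.Series({"A": 1.0})})
        with pytest.raises(ValidationError, match="NA"):
            csc.trajectory_drug_matrix(res, lib)

    def test_entries_match_elementwise_recomputation(self):
        res = [
            TrajectoryResult("t1", 0.5, 20, 10, _degs(["A", "B"], [1, 1])),
            TrajectoryResult("t2", 2.0, 10, 20, _degs(["B", "C"], [-1, 1])),
        ]
        lib = _lib({
            "d1": pd.Series({"A": -1.0, "B": 1.0, "C": 0.5}),
            "d2": pd.Series({"A": 0.3, "C": -0.7}),
        })
        W = csc.trajectory_drug_matrix(res, lib)
        for r in res:
            for drug in lib.drug_ids:
                expected = (csc.reversal_score(r.degs, lib, drug) + 1) / 2
                assert W.loc[drug, r.name] == pytest.approx(expected)
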