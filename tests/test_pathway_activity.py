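"""Cell filtering, rank-AUC scoring, phase-grouped activity medians."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonesteer import GeneSet, aucell_score, aucell_scores, filter_cells, median_activity_by_group
from clonesteer.errors import EmptyMatrixError, InvalidParameterError
from conftest import make_adata
from oracles import recovery_curve_auc


class TestFilterCells:
    def test_boundary_at_min_features(self, rng):
        n_genes = 300
        X = np.zeros((3, n_genes))
        X[0, :199] = 1.0  # 199 detected -> removed
        X[1, :200] = 1.0  # 200 detected -> kept
        X[2, :] = 1.0
        kept = filter_cells(make_adata(X), min_features=200)
        assert list(kept.obs_names) == ["c1", "c2"]

    def test_all_zero_matrix_errors(self):
        with pytest.raises(EmptyMatrixError):
            filter_cells(make_adata(np.zeros((4, 50))), min_features=200)


class TestAucell:
    def test_saturated_and_absent_sets(self):
        # 100 genes, cell expresses g0 > g1 > ... ; threshold = top 5
        X = np.arange(100, 0, -1, dtype=float)[None, :]
        adata = make_adata(X)
        top_set = GeneSet("top", ("g0", "g1", "g2"))
        assert aucell_score(adata, top_set).iloc[0] == pytest.approx(1.0)
        bottom_set = GeneSet("bottom", ("g90", "g91"))
        assert aucell_score(adata, bottom_set).iloc[0] == 0.0

    def test_worked_example_two_members(self):
        # members at ranks 1 and 3 of 100, threshold 5:
        # hits per depth = 1,1,2,2,2 -> area 8; ideal = 1+2+2+2+2 = 9
        X = np.arange(100, 0, -1, dtype=float)[None, :]
        score = aucell_score(make_adata(X), GeneSet("s", ("g0", "g2")))
        assert score.iloc[0] == pytest.approx(8 / 9, rel=1e-12)

    def test_matches_bruteforce_oracle_on_random_fixtures(self, rng):
        for _ in range(20):
            n_genes = int(rng.integers(40, 300))
            n_cells = int(rng.integers(1, 6))
            X = rng.random((n_cells, n_genes))  # continuous -> no ties
            adata = make_adata(X)
            size = int(rng.integers(1, 15))
            genes = rng.choice(n_genes, size=size, replace=False)
            gs = GeneSet("s", tuple(f"g{g}" for g in genes))
            scores = aucell_score(adata, gs)
            top = int(np.ceil(0.05 * n_genes))
            member = np.zeros(n_genes, dtype=bool)
            member[genes] = True
            for i in range(n_cells):
                expected = recovery_curve_auc(X[i], member, top)
                assert scores.iloc[i] == pytest.approx(expected, abs=1e-12)

    def test_missing_set_warns_and_scores_zero(self, rng):
        adata = make_adata(rng.random((3, 50)))
        with pytest.warns(UserWarning, match="no member"):
            scores = aucell_score(adata, GeneSet("absent", ("nope1", "nope2")))
        assert (scores == 0).all()

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((4, 80))
        gs = GeneSet("s", tuple(f"g{g}" for g in rng.choice(80, 8, replace=False)))
        base = aucell_score(make_adata(X), gs)
        transformed = aucell_score(make_adata(np.exp(3 * X) + 7), gs)
        assert np.allclose(base.to_numpy(), transformed.to_numpy())

    def test_gene_order_permutation_invariance(self, rng):
        X = rng.random((5, 60))
        genes = [f"g{i}" for i in range(60)]
        gs = GeneSet("s", tuple(rng.choice(genes, 6, replace=False)))
        base = aucell_scores(make_adata(X, genes=genes), gs)
        perm = rng.permutation(60)
        shuffled = aucell_scores(
            make_adata(X[:, perm], genes=[genes[j] for j in perm]), gs
        )
        assert np.allclose(base.to_numpy(), shuffled.to_numpy())

    def test_scores_bounded(self, rng):
        X = rng.random((10, 100))
        gs = [GeneSet(f"s{j}", tuple(f"g{g}" for g in rng.choice(100, 10, replace=False)))
              for j in range(5)]
        scores = aucell_scores(make_adata(X), gs)
        assert ((scores >= 0) & (scores <= 1)).all().all()

    def test_invalid_top_fraction(self, rng):
        with pytest.raises(InvalidParameterError):
            aucell_scores(make_adata(rng.random((2, 10))), GeneSet("s", ("g0",)), top_fraction=0.0)


class TestGroupedMedians:
    def _fixture(self, rng, n=50):
        cells = [f"c{i}" for i in range(n)]
        activity = pd.DataFrame(
            {"pw1": rng.random(n), "pw2": rng.random(n)}, index=cells
        )
        ann = pd.DataFrame(
            {
                "cell_id": cells,
                "cell_line": rng.choice(["L1", "L2"], n),
                "clone_id": "x",
                "phase": rng.choice(["G0G1", "S", "G2M"], n),
            }
        )
        return activity, ann

    def test_matches_sort_and_middle_oracle(self, rng):
        activity, ann = self._fixture(rng)
        for grouping in ("G0G1", "S", "G2M", "all"):
            med = median_activity_by_group(activity, ann, grouping)
            for line in med.index:
                mask = ann["cell_line"] == line
                if grouping != "all":
                    mask &= ann["phase"] == grouping
                ids = ann.loc[mask, "cell_id"]
                for pw in ("pw1", "pw2"):
                    vals = np.sort(activity.loc[ids, pw].to_numpy())
                    k = len(vals)
                    oracle = vals[k // 2] if k % 2 else (vals[k // 2 - 1] + vals[k // 2]) / 2
                    assert med.loc[line, pw] == pytest.approx(oracle, rel=1e-12)

    def test_single_cell_group_and_odd_median(self):
        activity = pd.DataFrame({"pw": [0.1, 0.2, 0.9, 0.5]},
                                index=["a", "b", "c", "d"])
        ann = pd.DataFrame(
            {
                "cell_id": ["a", "b", "c", "d"],
                "cell_line": ["L1", "L1", "L1", "L2"],
                "clone_id": "x",
                "phase": ["G0G1", "G0G1", "G0G1", "S"],
            }
        )
        med = median_activity_by_group(activity, ann, "G0G1")
        assert med.loc["L1", "pw"] == pytest.approx(0.2)
        with pytest.warns(UserWarning, match="L1"):
            med_s = median_activity_by_group(activity, ann, "S")
        assert list(med_s.index) == ["L2"]
        assert med_s.loc["L2", "pw"] == pytest.approx(0.5)

    def test_invalid_grouping(self):
        with pytest.raises(InvalidParameterError):
            median_activity_by_group(pd.DataFrame(), pd.DataFrame(), "M")
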