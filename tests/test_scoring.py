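"""Signature derivation, GSVA/ssGSEA/preranked GSEA, overlap statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from episig import (
    GeneSet,
    GeneSetCollection,
    gsva_scores,
    overlap_stats,
    preranked_gsea,
    ssgsea_scores,
    top_n_signature,
)

from _oracles import gsva_oracle, gsea_walk_oracle, hypergeom_upper_tail, ssgsea_oracle


def _expr(arr, genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=samples)


class TestTopNSignature:
    @staticmethod
    def _de(logfc, p, q):
        return pd.DataFrame(
            {"logFC_e": logfc, "p": p, "q": q},
            index=[f"g{i}" for i in range(len(logfc))],
        )

    def test_short_set_flagged(self):
        de = self._de([2.0, 1.5, 1.0, -3.0], [1e-5] * 4, [1e-4] * 4)
        with pytest.warns(UserWarning):
            gs = top_n_signature(de, n=50)
        assert len(gs) == 3 and gs.short_set

    def test_tie_broken_by_smaller_p(self):
        de = self._de([2.0, 2.0], [0.002, 0.001], [0.005, 0.005])
        gs = top_n_signature(de, n=1)
        assert gs.genes == ("g1",)

    def test_down_direction(self):
        de = self._de([2.0, -1.0, -4.0], [1e-4] * 3, [1e-3] * 3)
        gs = top_n_signature(de, n=2, direction="down")
        assert gs.genes == ("g2", "g1")

    def test_no_qualifying_genes_raises(self):
        de = self._de([1.0], [0.5], [0.5])
        with pytest.raises(ValueError, match="no genes"):
            top_n_signature(de)


class TestGSVA:
    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            e = _expr(rng.normal(size=(12, 5)))
            gs = GeneSet("s", "", tuple(rng.choice(e.index, 4, replace=False)))
            es = gsva_scores(e, gs)
            assert (es.to_numpy() >= -1 - 1e-12).all()
            assert (es.to_numpy() <= 1 + 1e-12).all()

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        e = _expr(rng.normal(size=(10, 6)))
        gs = GeneSet("s", "", ("g0", "g3", "g7"))
        es = gsva_scores(e, gs)
        perm = ["s4", "s0", "s5", "s2", "s1", "s3"]
        es_perm = gsva_scores(e[perm], gs)
        assert es_perm[perm].columns.tolist() == perm
        assert np.allclose(es[perm].to_numpy(), es_perm.to_numpy())

    def test_matches_independent_oracle(self):
        """Vectorized GSVA equals the step-by-step reference on random input."""
        rng = np.random.default_rng(2)
        for trial in range(50):
            e = _expr(rng.normal(size=(10, 6)))
            members = tuple(rng.choice(e.index, 3, replace=False))
            es = gsva_scores(e, GeneSet("s", "", members)).to_numpy()[0]
            oracle = gsva_oracle(
                {g: list(e.loc[g]) for g in e.index}, members
            )
            assert np.max(np.abs(es - np.array(oracle))) < 1e-9

    def test_upshifted_set_scores_higher(self):
        rng = np.random.default_rng(3)
        e = _expr(rng.normal(size=(30, 8)))
        e.iloc[:5, 4:] += 3.0  # shift set genes up in samples 4..7
        gs = GeneSet("s", "", tuple(e.index[:5]))
        es = gsva_scores(e, gs).to_numpy()[0]
        assert es[4:].mean() > es[:4].mean()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            gsva_scores(_expr(np.eye(4)[:, :2]), GeneSet("s", "", ("g0",)))

    def test_empty_intersection_gives_nan_row(self):
        rng = np.random.default_rng(4)
        e = _expr(rng.normal(size=(6, 4)))
        sets = GeneSetCollection(
            [GeneSet("hit", "", ("g0", "g1")), GeneSet("miss", "", ("zz", "yy"))]
        )
        with pytest.warns(UserWarning):
            es = gsva_scores(e, sets)
        assert es.loc["miss"].isna().all()
        assert es.loc["hit"].notna().all()


class TestSsGSEA:
    def test_single_top_gene_closed_form(self):
        """Set = top-ranked of 4 genes, alpha=0: ES = 1 + 2/3 + 1/3 + 0 = 2."""
        e = _expr([[4.0], [3.0], [2.0], [1.0]])
        es = ssgsea_scores(e, GeneSet("s", "", ("g0",)), alpha=0.0, normalize=False)
        assert es.iloc[0, 0] == pytest.approx(2.0)

    def test_single_bottom_gene_mirror(self):
        e = _expr([[4.0], [3.0], [2.0], [1.0]])
        es = ssgsea_scores(e, GeneSet("s", "", ("g3",)), alpha=0.0, normalize=False)
        assert es.iloc[0, 0] == pytest.approx(-2.0)

    def test_identical_samples_identical_scores(self):
        e = _expr(np.tile([[5.0], [1.0], [3.0], [2.0]], (1, 3)))
        es = ssgsea_scores(e, GeneSet("s", "", ("g0", "g2")))
        assert es.iloc[0].nunique() == 1

    def test_monotone_transform_invariance(self):
        """Rank-based: any strictly increasing transform leaves scores fixed."""
        rng = np.random.default_rng(5)
        e = _expr(rng.normal(size=(15, 4)))
        gs = GeneSet("s", "", tuple(e.index[[2, 5, 11]]))
        es1 = ssgsea_scores(e, gs, normalize=False)
        es2 = ssgsea_scores(np.exp(e * 3) + 7, gs, normalize=False)
        assert np.allclose(es1.to_numpy(), es2.to_numpy())

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(6)
        for trial in range(50):
            e = _expr(rng.normal(size=(10, 6)))
            members = tuple(rng.choice(e.index, 3, replace=False))
            es = ssgsea_scores(e, GeneSet("s", "", members), normalize=False).to_numpy()[0]
            oracle = ssgsea_oracle({g: list(e.loc[g]) for g in e.index}, members)
            assert np.max(np.abs(es - np.array(oracle))) < 1e-9

    def test_full_universe_set_rejected(self):
        e = _expr(np.random.default_rng(7).normal(size=(4, 3)))
        with pytest.raises(ValueError, match="complement"):
            ssgsea_scores(e, GeneSet("s", "", tuple(e.index)))


class TestPrerankedGSEA:
    def test_toy_walk(self):
        """Scores (3,2,1,-1), set {g1,g2}: walk (0.6, 1.0, 0.5, 0.0), ES=1."""
        ranked = pd.Series([3.0, 2.0, 1.0, -1.0], index=["g1", "g2", "g3", "g4"])
        res = preranked_gsea(ranked, GeneSet("s", "", ("g1", "g2")), n_perm=100, seed=0)
        assert res.loc["s", "ES"] == pytest.approx(1.0)
        walk, es = gsea_walk_oracle([3, 2, 1, -1], [True, True, False, False])
        assert walk == pytest.approx([0.6, 1.0, 0.5, 0.0])

    def test_front_loaded_set_maximal(self):
        rng = np.random.default_rng(8)
        scores = np.sort(rng.normal(size=30))[::-1]
        ranked = pd.Series(scores, index=[f"g{i}" for i in range(30)])
        res = preranked_gsea(ranked, GeneSet("s", "", tuple(f"g{i}" for i in range(5))),
                             n_perm=50, seed=0)
        assert res.loc["s", "ES"] == pytest.approx(1.0)

    def test_reversed_ranking_negates_es(self):
        """For a sign-symmetric score vector, reversing ranks flips the ES."""
        scores = np.array([3.0, 2.0, 1.0, -1.0, -2.0, -3.0])
        genes = [f"g{i}" for i in range(6)]
        gs = GeneSet("s", "", ("g0", "g2"))
        es_fwd = preranked_gsea(pd.Series(scores, index=genes), gs, n_perm=10, seed=0)
        es_rev = preranked_gsea(pd.Series(-scores, index=genes), gs, n_perm=10, seed=0)
        assert es_rev.loc["s", "ES"] == pytest.approx(-es_fwd.loc["s", "ES"])

    def test_null_p_approximately_uniform(self):
        """Random rankings: empirical p-values pass a KS uniformity check."""
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(80)]
        gs = GeneSet("s", "", tuple(genes[:10]))
        pvals = []
        for trial in range(100):
            scores = rng.normal(size=80)
            ranked = pd.Series(scores, index=rng.permutation(genes))
            res = preranked_gsea(ranked, gs, n_perm=400, seed=trial)
            pvals.append(res.loc["s", "p"])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_nes_sign_matches_es(self):
        rng = np.random.default_rng(10)
        ranked = pd.Series(rng.normal(size=50), index=[f"g{i}" for i in range(50)])
        sets = GeneSetCollection(
            [GeneSet(f"s{k}", "", tuple(rng.choice(ranked.index, 8, replace=False)))
             for k in range(5)]
        )
        res = preranked_gsea(ranked, sets, n_perm=200, seed=0)
        ok = res["NES"].notna()
        assert (np.sign(res.loc[ok, "NES"]) == np.sign(res.loc[ok, "ES"])).all()
        assert (res.loc[ok, "p"] >= 1 / 201).all()

    def test_degenerate_set_gets_error_record(self):
        ranked = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        res = preranked_gsea(ranked, GeneSet("s", "", ("zz",)), n_perm=10, seed=0)
        assert res.loc["s", "error"] != ""
        assert np.isnan(res.loc["s", "ES"])


class TestOverlapStats:
    def test_one_third_of_reference(self):
        """19 of a 57-gene reference overlap: 33% of the reference set."""
        universe = [f"u{i}" for i in range(20_000)]
        reference = universe[:57]
        query = universe[:19] + universe[1000:2232]  # 1251-gene query, 19 shared
        res = overlap_stats(query, reference, universe)
        assert res["k"] == 19
        assert round(res["percent_of_reference"]) == 33

    def test_at_expectation_fold_one(self):
        """|q|=4, |r|=5, N=20, k=1: expected overlap is exactly 1, fold 1.0."""
        universe = [f"u{i}" for i in range(20)]
        res = overlap_stats(universe[4:8], universe[:5], universe)
        assert res["expected"] == pytest.approx(1.0)
        assert res["k"] == 1 and res["fold_enrichment"] == pytest.approx(1.0)

    def test_exact_enumeration_small_universe(self):
        """p equals exact hypergeometric enumeration: 155/4845 for k=3."""
        universe = [f"u{i}" for i in range(20)]
        reference = universe[:5]
        query = universe[:3] + [universe[10]]
        res = overlap_stats(query, reference, universe)
        assert res["k"] == 3 and res["fold_enrichment"] == pytest.approx(3.0)
        assert res["p_hyper"] == pytest.approx(155 / 4845)
        assert res["p_hyper"] == pytest.approx(hypergeom_upper_tail(20, 5, 4, 3))

    def test_exhaustive_agreement_with_enumeration(self):
        rng = np.random.default_rng(11)
        universe = [f"u{i}" for i in range(25)]
        for _ in range(30):
            nq, nr = rng.integers(1, 12, 2)
            q = list(rng.choice(universe, nq, replace=False))
            r = list(rng.choice(universe, nr, replace=False))
            res = overlap_stats(q, r, universe)
            assert res["p_hyper"] == pytest.approx(
                hypergeom_upper_tail(25, len(r), len(q), res["k"])
            )

    def test_membership_violation_names_ids(self):
        with pytest.raises(ValueError, match="zz"):
            overlap_stats(["zz"], ["a"], ["a", "b"])
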