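import numpy as np
import pandas as pd
import pytest

import scellintegrate as sci
from scellintegrate.datatypes import IntegrityError
from scellintegrate.integrate import parse_unit, unit_name


def _marker_table(cluster_specs):
    """Tiny synthetic MarkerTable: {cluster: [(gene, log2fc, p_adj, marker)]}"""
    rows = []
    for c, genes in cluster_specs.items():
        for g, fc, padj, mk in genes:
            rows.append(
                {
                    "cluster": c, "gene": g, "log2fc": fc, "p_wilcoxon": padj,
                    "p_fisher": padj, "p_combined": padj, "p_adj": padj,
                    "freq_in": 0.9, "freq_out": 0.05,
                    "rank_score": fc * -np.log10(max(padj, 1e-300)),
                    "is_marker": mk,
                }
            )
    return pd.DataFrame(rows)


class TestGeneSetDB:
    def test_counts_and_bijective_names(self):
        tables = {
            f"s{s}": _marker_table(
                {c: [(f"s{s}c{c}g{i}", 3.0, 1e-4, True) for i in range(8)] for c in range(3)}
            )
            for s in (1, 2)
        }
        db = sci.build_cluster_geneset_db(tables)
        assert len(db) == 6
        seen = {parse_unit(n) for n in db.names}
        assert len(seen) == 6
        assert unit_name("s1", 0) in db.names

    def test_small_cluster_excluded_with_warning(self):
        tables = {
            "a": _marker_table(
                {
                    0: [(f"g{i}", 3.0, 1e-4, True) for i in range(8)],
                    1: [(f"h{i}", 3.0, 1e-4, True) for i in range(3)],
                }
            )
        }
        with pytest.warns(UserWarning, match="a\\|1"):
            db = sci.build_cluster_geneset_db(tables)
        assert db.names == ["a|0"]

    def test_sample_without_usable_cluster_raises(self):
        tables = {"bad": _marker_table({0: [("g1", 3.0, 1e-4, True)]})}
        with pytest.raises(IntegrityError, match="bad"):
            sci.build_cluster_geneset_db(tables)

    def test_negative_fold_change_markers_excluded(self):
        genes = [(f"g{i}", 3.0, 1e-4, True) for i in range(6)] + [
            ("neg", -5.0, 1e-9, True)
        ]
        db = sci.build_cluster_geneset_db({"s": _marker_table({0: genes})})
        assert "neg" not in db["s|0"]


def _per_sample_markers(matrix, truth, samples):
    out = {}
    for s in samples:
        mask = matrix.sample_of_cell == s
        norm = sci.normalize(sci.filter_genes(matrix.subset_cells(mask), 10))
        types = truth.type_of_cell[mask]
        _, labels = np.unique(types, return_inverse=True)
        out[s] = (sci.find_markers(norm, labels), np.unique(types))
    return out


class TestMatchMatrix:
    @pytest.fixture()
    def duplicated_sample_match(self, small_sim):
        matrix, truth = small_sim
        per = _per_sample_markers(matrix, truth, ["batch1"])
        table, names = per["batch1"]
        tables = {"copyA": table, "copyB": table.copy()}
        db = sci.build_cluster_geneset_db(tables)
        match = sci.compute_match_matrix(tables, db, n_perm=200, seed=0)
        return match, names

    def test_nonnegative_and_square(self, duplicated_sample_match):
        match, _ = duplicated_sample_match
        assert (match.to_numpy() >= 0).all()
        assert match.shape[0] == match.shape[1]

    def test_duplicated_sample_argmax_is_true_counterpart(self, duplicated_sample_match):
        match, _ = duplicated_sample_match
        for row in match.index:
            s, c = parse_unit(row)
            other = "copyB" if s == "copyA" else "copyA"
            cross = match.loc[row, [col for col in match.columns if col.startswith(other)]]
            assert parse_unit(cross.idxmax())[1] == c

    def test_disjoint_cell_types_zero_cross_scores(self):
        # two samples simulated with completely disjoint types and markers
        cfg = sci.SimConfig(
            n_batches=2, cells_per_batch=300, n_types=4,
            types_per_batch=[[0, 1], [2, 3]], seed=8, batch_effect_sd=0.0,
        )
        matrix, truth = sci.simulate(cfg)
        tables = {}
        for s in ("batch1", "batch2"):
            mask = matrix.sample_of_cell == s
            norm = sci.normalize(sci.filter_genes(matrix.subset_cells(mask), 10))
            _, labels = np.unique(truth.type_of_cell[mask], return_inverse=True)
            tables[s] = sci.find_markers(norm, labels)
        db = sci.build_cluster_geneset_db(tables)
        match = sci.compute_match_matrix(tables, db, n_perm=200, seed=0)
        for row in match.index:
            s, _ = parse_unit(row)
            other = "batch2" if s == "batch1" else "batch1"
            cross = match.loc[row, [c for c in match.columns if c.startswith(other)]]
            assert (cross == 0).all()


class TestMatchClusters:
    def test_planted_meta_structure(self, small_sim):
        matrix, truth = small_sim
        tables = {}
        type_names = {}
        for s in ("batch1", "batch2", "batch3"):
            mask = matrix.sample_of_cell == s
            norm = sci.normalize(sci.filter_genes(matrix.subset_cells(mask), 10))
            names, labels = np.unique(truth.type_of_cell[mask], return_inverse=True)
            tables[s] = sci.find_markers(norm, labels)
            type_names[s] = names
        db = sci.build_cluster_geneset_db(tables)
        match = sci.compute_match_matrix(tables, db, n_perm=300, seed=5)
        meta = sci.match_clusters(match)
        assert meta.n_meta == 5
        assert sorted(meta.status.values()).count("common") == 4
        # every meta-cluster groups exactly the units of one truth type
        by_type = {}
        for u, m in meta.assignment.items():
            s, c = parse_unit(u)
            by_type.setdefault(m, set()).add(str(type_names[s][int(c)]))
        assert all(len(v) == 1 for v in by_type.values())
        unique_meta = [m for m, st in meta.status.items() if st == "unique"]
        assert [next(iter(by_type[m])) for m in unique_meta] == ["type4"]

    def test_all_zero_matrix_every_cluster_unique(self):
        match = pd.DataFrame(
            0.0, index=["a|0", "a|1", "b|0"], columns=["a|0", "a|1", "b|0"]
        )
        with pytest.warns(UserWarning, match="all-zero"):
            meta = sci.match_clusters(match)
        assert meta.n_meta == 3
        assert set(meta.status.values()) == {"unique"}

    def test_block_structured_matrix_cut_correctly(self):
        # 2 samples x 2 clusters; units 0 of both samples match each other,
        # units 1 likewise; zero mutual score within a sample
        names = ["a|0", "a|1", "b|0", "b|1"]
        X = pd.DataFrame(0.0, index=names, columns=names)
        for u in names:
            X.loc[u, u] = 3.0
        X.loc["a|0", "b|0"] = X.loc["b|0", "a|0"] = 2.5
        X.loc["a|1", "b|1"] = X.loc["b|1", "a|1"] = 2.5
        meta = sci.match_clusters(X)
        assert meta.assignment["a|0"] == meta.assignment["b|0"]
        assert meta.assignment["a|1"] == meta.assignment["b|1"]
        assert meta.assignment["a|0"] != meta.assignment["a|1"]


class TestPriorMatrix:
    def _meta(self, M=5):
        return sci.MetaClusterMap(
            assignment={f"s|{i}": i for i in range(M)},
            status={i: "common" for i in range(M)},
        )

    def test_concentrated_row(self):
        prior = sci.build_prior_matrix(
            self._meta(), np.array(["s|0", "s|3"], dtype=object), confidence=0.9
        )
        assert prior.probs[0] == pytest.approx([0.9, 0.025, 0.025, 0.025, 0.025])
        assert prior.probs[1][3] == pytest.approx(0.9)

    def test_uninformative_prior_is_uniform(self):
        prior = sci.build_prior_matrix(
            self._meta(), np.array(["s|1"], dtype=object), confidence=1 / 5
        )
        assert prior.probs[0] == pytest.approx([0.2] * 5)

    def test_rows_sum_to_one(self, rng):
        units = np.array([f"s|{i}" for i in rng.integers(0, 5, size=40)], dtype=object)
        prior = sci.build_prior_matrix(self._meta(), units, confidence=0.8)
        assert prior.probs.sum(axis=1) == pytest.approx(np.ones(40))

    def test_unmapped_cell_raises(self):
        with pytest.raises(IntegrityError, match="unmapped"):
            sci.build_prior_matrix(self._meta(), np.array(["x|9"], dtype=object))


class TestHarmonyCorrect:
    def _two_batch_offset(self, rng, n=300, d=10, offset=6.0):
        coords = np.vstack(
            [rng.normal(size=(n, d)), rng.normal(size=(n, d)) + np.eye(d)[0] * offset]
        )
        batch = np.array(["a"] * n + ["b"] * n, dtype=object)
        return sci.Embedding(coords=coords), batch

    def test_single_batch_is_identity(self, rng):
        emb = sci.Embedding(coords=rng.normal(size=(100, 5)))
        batch = np.full(100, "only", dtype=object)
        out = sci.harmony_correct(emb, batch, params=sci.HarmonyParams(n_clusters=3, seed=0))
        assert np.allclose(out.coords, emb.coords, atol=1e-6)

    def test_constant_offset_removed(self, rng):
        emb, batch = self._two_batch_offset(rng)
        out = sci.harmony_correct(emb, batch, params=sci.HarmonyParams(n_clusters=2, seed=1))
        def centroid_gap(c):
            return np.linalg.norm(c[:300].mean(0) - c[300:].mean(0))
        assert centroid_gap(out.coords) <= 0.05 * centroid_gap(emb.coords)

    def test_shape_and_order_preserved(self, rng):
        emb, batch = self._two_batch_offset(rng, n=100)
        out = sci.harmony_correct(emb, batch, params=sci.HarmonyParams(n_clusters=2, seed=1))
        assert out.coords.shape == emb.coords.shape

    def test_translation_equivariance(self, rng):
        emb, batch = self._two_batch_offset(rng, n=120)
        params = sci.HarmonyParams(n_clusters=2, seed=2)
        out1 = sci.harmony_correct(emb, batch, params=params)
        shifted = sci.Embedding(coords=emb.coords + 7.5)
        out2 = sci.harmony_correct(shifted, batch, params=params)
        assert np.allclose(out2.coords, out1.coords + 7.5, atol=1e-8)

    def test_uninformative_prior_equals_unsupervised(self, rng):
        emb, batch = self._two_batch_offset(rng, n=150)
        M = 4
        units = np.array(
            [f"s|{i}" for i in rng.integers(0, M, size=300)], dtype=object
        )
        meta = sci.MetaClusterMap(
            assignment={f"s|{i}": i for i in range(M)},
            status={i: "common" for i in range(M)},
        )
        flat = sci.build_prior_matrix(meta, units, confidence=1 / M)
        params = sci.HarmonyParams(n_clusters=M, seed=3, prior_weight=0.9)
        sup = sci.harmony_correct(emb, batch, prior=flat, params=params)
        unsup = sci.harmony_correct(emb, batch, prior=None, params=params)
        assert np.allclose(sup.coords, unsup.coords, atol=1e-10)

    def test_deterministic(self, rng):
        emb, batch = self._two_batch_offset(rng, n=80)
        params = sci.HarmonyParams(n_clusters=2, seed=9)
        a = sci.harmony_correct(emb, batch, params=params)
        b = sci.harmony_correct(emb, batch, params=params)
        assert np.array_equal(a.coords, b.coords)


class TestRunSupervisedIntegration:
    def test_single_sample_is_error(self, small_sim):
        matrix, _ = small_sim
        sub = matrix.subset_cells(matrix.sample_of_cell == "batch1")
        with pytest.raises(ValueError, match="requires >= 2 samples"):
            sci.run_supervised_integration(sub)

    def test_end_to_end_small(self, small_sim):
        matrix, truth = small_sim
        res = sci.run_supervised_integration(
            matrix, sci.IntegrationConfig(seed=3, n_perm=200)
        )
        assert res.corrected.coords.shape[0] == matrix.n_cells
        assert res.meta.n_meta == 5
        assert list(res.meta.status.values()).count("unique") == 1
        # the batch-unique type stays its own meta-cluster: the cells of the
        # unique meta-cluster are overwhelmingly the planted unique type
        unique_meta = [m for m, s in res.meta.status.items() if s == "unique"][0]
        unit_meta = np.array([res.meta.assignment[u] for u in res.unit_of_cell])
        cells = unit_meta == unique_meta
        assert (truth.type_of_cell[cells] == "type4").mean() > 0.9

    def test_deterministic_manifest(self, small_sim):
        matrix, _ = small_sim
        cfg = sci.IntegrationConfig(seed=4, n_perm=150)
        r1 = sci.run_supervised_integration(matrix, cfg)
        r2 = sci.run_supervised_integration(matrix, cfg)
        assert np.array_equal(r1.corrected.coords, r2.corrected.coords)
        assert r1.meta.assignment == r2.meta.assignment
        assert r1.manifest["n_meta_clusters"] == r2.manifest["n_meta_clusters"]
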