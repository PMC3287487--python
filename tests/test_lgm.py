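"""Log-linear graphical model: IPF, deviance tests, elimination, star tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from comotif.enrichment import OccurrenceMatrix
from comotif.lgm import (
    BinaryTable,
    backward_eliminate,
    chi2_model_pvalue,
    count_genes_with_motif,
    design_matrix_rank,
    deviance_test,
    extract_combinations,
    ipf_fit,
    load_star_table,
    model_df,
    normalize_generators,
    star_table,
    table5_fixture_path,
    tabulate,
)
from comotif.synthetic_data import SimulationConfig, sample_presence_patterns


def _occ(patterns: list[tuple[int, ...]], names=None, groups=None) -> OccurrenceMatrix:
    names = names or [f"m{i}" for i in range(len(patterns[0]))]
    genes = [f"g{i}" for i in range(len(patterns))]
    df = pd.DataFrame(patterns, index=pd.Index(genes, name="gene"), columns=names)
    grp = pd.Series(groups or ["down"] * len(genes), index=df.index, name="group")
    return OccurrenceMatrix(df, grp)


class TestTabulate:
    def test_counts_patterns(self):
        occ = _occ([(2, 2), (2, 2), (1, 2), (1, 1)])
        t = tabulate(occ)
        # cell index: m0 least significant bit
        assert t.counts[0b00] == 1  # (1,1)
        assert t.counts[0b10] == 1  # (1,2)
        assert t.counts[0b11] == 2  # (2,2)
        assert t.n == 4

    def test_empty_matrix_errors(self):
        df = pd.DataFrame(columns=["m0"], dtype=int)
        df.index.name = "gene"
        occ = OccurrenceMatrix(df, pd.Series(dtype=object))
        with pytest.raises(ValueError, match="empty"):
            tabulate(occ)

    def test_total_equals_gene_count(self, rng):
        patterns = [tuple(rng.integers(1, 3, size=4)) for _ in range(37)]
        assert tabulate(_occ(patterns)).n == 37


class TestIpfFit:
    def test_saturated_model_reproduces_observed(self, rng):
        counts = rng.integers(1, 20, size=8).astype(float)
        t = BinaryTable(["a", "b", "c"], counts)
        fit = ipf_fit(t, [{0, 1, 2}])
        assert np.abs(fit.deviance) < 1e-9
        assert fit.df == 0
        assert np.allclose(fit.fitted, counts)

    def test_independence_closed_form(self):
        t = BinaryTable(["a", "b"], np.array([40.0, 10.0, 40.0, 10.0]))
        fit = ipf_fit(t, [{0}, {1}])
        # fitted = row x col / n
        assert np.allclose(fit.fitted, [40, 10, 40, 10])
        assert fit.deviance == pytest.approx(0.0, abs=1e-9)
        assert fit.df == 1

    def test_decomposable_closed_form(self, rng):
        counts = rng.integers(1, 30, size=8).astype(float)
        t = BinaryTable(["a", "b", "c"], counts)
        fit = ipf_fit(t, [{0, 1}, {1, 2}])
        obs = t.tensor()
        nab = obs.sum(axis=2, keepdims=True)
        nbc = obs.sum(axis=0, keepdims=True)
        nb = obs.sum(axis=(0, 2), keepdims=True)
        closed = nab * nbc / nb
        assert np.abs(fit.fitted.reshape((2, 2, 2), order="F") - closed).max() < 1e-6

    def test_fitted_margins_match_observed_on_generators(self, rng):
        counts = rng.integers(0, 25, size=16).astype(float)
        t = BinaryTable(list("abcd"), counts)
        gens = [{0, 1}, {1, 2}, {2, 3}, {0, 3}]  # 4-cycle: non-decomposable
        fit = ipf_fit(t, gens)
        assert fit.converged
        obs = t.tensor()
        fitted = fit.fitted.reshape((2,) * 4, order="F")
        for g in fit.generators:
            axes = tuple(v for v in range(4) if v not in g)
            assert np.abs(obs.sum(axis=axes) - fitted.sum(axis=axes)).max() < 1e-6
        assert fitted.sum() == pytest.approx(t.n)

    def test_model_df_matches_design_rank(self):
        for k, gens in [(3, [{0, 1}, {1, 2}]), (4, [{0, 1, 2}, {2, 3}]), (2, [{0}, {1}])]:
            norm = normalize_generators(gens, k)
            assert model_df(norm, k) == (2**k - 1) - design_matrix_rank(norm, k)


class TestDevianceTest:
    def test_identical_models(self):
        t = BinaryTable(["a", "b"], np.array([30.0, 10.0, 10.0, 30.0]))
        fit = ipf_fit(t, [{0, 1}])
        assert deviance_test(fit, fit) == (0.0, 0, 1.0)

    def test_two_by_two_closed_form(self):
        t = BinaryTable(["a", "b"], np.array([30.0, 10.0, 10.0, 30.0]))
        indep = ipf_fit(t, [{0}, {1}])
        sat = ipf_fit(t, [{0, 1}])
        g2, df, p = deviance_test(indep, sat)
        assert g2 == pytest.approx(2 * (60 * np.log(1.5) - 20 * np.log(2)), abs=1e-9)
        assert df == 1
        assert p < 0.001

    def test_printed_final_model_statistics(self):
        # deviance 122.806 at 1001 degrees of freedom -> p = 1.000 (3 dp)
        assert round(chi2_model_pvalue(122.806, 1001), 3) == 1.000

    def test_non_nested_models_rejected(self):
        t = BinaryTable(["a", "b", "c"], np.arange(1.0, 9.0))
        fit_ab = ipf_fit(t, [{0, 1}, {2}])
        fit_bc = ipf_fit(t, [{1, 2}, {0}])
        with pytest.raises(ValueError, match="nested"):
            deviance_test(fit_ab, fit_bc)

    def test_pvalue_agrees_with_numerical_integration(self):
        g2, df = 7.3, 3
        p = chi2_model_pvalue(g2, df)
        quad, _ = integrate.quad(lambda x: stats.chi2.pdf(x, df), g2, np.inf)
        assert p == pytest.approx(quad, abs=1e-6)


class TestBackwardElimination:
    def test_independent_data_yields_empty_graph(self):
        t = BinaryTable(["a", "b"], np.array([40.0, 10.0, 40.0, 10.0]))
        graph, trace = backward_eliminate(t)
        assert graph.edges == []
        assert len(trace.steps) == 1

    def test_strong_association_retains_edge(self):
        t = BinaryTable(["a", "b"], np.array([30.0, 10.0, 10.0, 30.0]))
        graph, trace = backward_eliminate(t)
        assert graph.edges == [("a", "b")]
        assert trace.steps == []

    def test_deviance_vs_fm_monotone_along_trace(self, rng):
        patterns = [tuple(rng.integers(1, 3, size=4)) for _ in range(60)]
        t = tabulate(_occ(patterns))
        _, trace = backward_eliminate(t, alpha=0.9)  # force a long trace
        cums = [s.cumulative_g2 for s in trace.steps]
        assert all(b >= a - 1e-9 for a, b in zip(cums, cums[1:]))

    def test_recovers_planted_structure(self):
        edges = [(0, 1, 1.5), (2, 3, 1.5), (4, 5, 1.5)]
        planted = {("m0", "m1"), ("m2", "m3"), ("m4", "m5")}
        sens, fps = [], []
        for rep in range(20):
            cfg = SimulationConfig(seed=1000 + rep, k_motifs=6, planted_edges=edges, n_down=400)
            pres = sample_presence_patterns(cfg)
            idx = pres.astype(np.int64) @ (1 << np.arange(6))
            t = BinaryTable([f"m{i}" for i in range(6)], np.bincount(idx, minlength=64))
            graph, _ = backward_eliminate(t, alpha=0.001)
            found = set(graph.edges)
            sens.append(len(found & planted) / len(planted))
            fps.append(len(found - planted))
        assert np.mean(sens) >= 0.8
        assert np.mean(fps) <= 1.0


class TestCombinationsAndStars:
    def test_empty_graph_gives_no_combinations(self):
        t = BinaryTable(["a", "b"], np.array([40.0, 10.0, 40.0, 10.0]))
        graph, _ = backward_eliminate(t)
        assert extract_combinations(graph) == []

    def test_triangle_neighborhoods(self):
        import networkx as nx

        from comotif.lgm import IndependenceGraph

        g = nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])
        graph = IndependenceGraph(g)
        combos = extract_combinations(graph)
        assert len(combos) == 3
        by_pair = {c["motifs"]: c for c in combos}
        assert by_pair[("A", "B")]["linked"]["A"] == ["B", "C"]

    def test_star_table_rule(self):
        occ = _occ(
            [(2, 2, 2), (1, 1, 1), (2, 1, 2)],
            names=["a", "b", "c"],
            groups=["down", "down", "nonreg"],
        )
        stars = star_table(occ, [("a", "b"), ("a", "c")])
        # only down-regulated genes appear
        assert list(stars.index) == ["g0", "g1"]
        assert stars.loc["g0"].all()
        assert not stars.loc["g1"].any()

    def test_star_table_unknown_motif_errors(self):
        occ = _occ([(2, 2)])
        with pytest.raises(KeyError):
            star_table(occ, [("m0", "zzz")])


class TestStarMatrixFixture:
    def test_gata1_bearing_columns_count_15_genes(self):
        assert count_genes_with_motif(table5_fixture_path(), "GATA-1") == 15

    def test_ap2_bearing_columns_hand_count(self):
        # hand count over the printed matrix: columns 4, 6, 7 -> 9 genes
        assert count_genes_with_motif(table5_fixture_path(), "AP2") == 9

    def test_empty_star_table_counts_zero(self):
        empty = pd.DataFrame(columns=["GATA-1|MZF1"], dtype=bool)
        empty.index.name = "gene"
        assert count_genes_with_motif(empty, "GATA-1") == 0

    def test_fully_starred_table_saturates(self):
        fixture = load_star_table(table5_fixture_path())
        full = fixture.copy()
        full[:] = True
        assert count_genes_with_motif(full, "GATA-1") == len(full)

    def test_unknown_motif_errors(self):
        with pytest.raises(KeyError, match="unknown"):
            count_genes_with_motif(table5_fixture_path(), "NOSUCH")
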