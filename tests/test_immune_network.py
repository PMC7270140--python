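"""Cell-cytokine networks: edges, thresholding, connectivity and centrality
against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from menimm import synthetic
from menimm.deconvolve import CellFractions, SignatureMatrix, estimate_fractions, prepare_mixture
from menimm.errors import DegenerateInputError, ValidationError
from menimm.immune_network import (NetworkSummary, build_network,
                                   cell_cytokine_edges, compare_locations,
                                   connectivity, eigenvector_centrality,
                                   summarize_location)


def edge_table(rows, location="convexity"):
    return pd.DataFrame(rows, columns=["cell_type", "cytokine", "rho", "p"]) \
        .assign(n=40, location=location, degenerate=False)


def random_edge_table(rng, n_cells=6, n_cyts=8):
    rows = []
    for c in range(n_cells):
        for g in range(n_cyts):
            rows.append((f"cell{c}", f"cyt{g}",
                         float(rng.uniform(-1, 1)), float(rng.uniform(0, 1))))
    return edge_table(rows)


class TestEdges:
    @pytest.fixture(scope="class")
    def planted(self):
        cfg = synthetic.SimulationConfig(
            n_genes=400, samples_per_study=(400,), skull_base_fraction=(0.5,),
            n_studies=1, module_sizes=(),
            couplings=(("Mast cells activated", "IL6", "convexity", 0.7),),
            gene_drop_rate=0.0, batch_shift_range=(0.0, 0.0),
            batch_scale_range=(1.0, 1.0), gene_shift_sd=0.0, seed=17)
        mats, meta, truth = synthetic.generate_cohort(cfg)
        fractions = CellFractions(
            list(truth.true_fractions.index),
            list(truth.true_fractions.columns),
            truth.true_fractions.to_numpy(),
            pd.DataFrame(index=truth.true_fractions.index))
        return mats[0], meta, truth, fractions

    def test_planted_coupling_appears_only_in_target_location(self, planted):
        matrix, meta, truth, fractions = planted
        conv, _ = cell_cytokine_edges(fractions, matrix, truth.cytokine_panel,
                                      meta, "convexity")
        sb, _ = cell_cytokine_edges(fractions, matrix, truth.cytokine_panel,
                                    meta, "skull_base")
        row = conv[(conv.cell_type == "Mast cells activated") & (conv.cytokine == "IL6")]
        assert row["rho"].iloc[0] == pytest.approx(0.7, abs=0.1)
        row_sb = sb[(sb.cell_type == "Mast cells activated") & (sb.cytokine == "IL6")]
        assert abs(row_sb["rho"].iloc[0]) < 0.2

    def test_cardinality_is_cells_times_panel(self, planted):
        matrix, meta, truth, fractions = planted
        edges, missing = cell_cytokine_edges(fractions, matrix,
                                             truth.cytokine_panel, meta,
                                             "convexity")
        assert len(edges) == 22 * (35 - len(missing))

    def test_constant_fraction_flagged_degenerate(self, planted):
        matrix, meta, truth, fractions = planted
        vals = fractions.values.copy()
        vals[:, 0] = 1.0 / 22  # constant across samples (row sums re-fixed below)
        vals = vals / vals.sum(axis=1, keepdims=True)
        vals[:, 0] = vals[0, 0]
        vals[:, 1:] *= ((1 - vals[0, 0]) / vals[:, 1:].sum(axis=1))[:, None]
        frac2 = CellFractions(fractions.sample_ids, fractions.cell_type_names,
                              vals, pd.DataFrame(index=fractions.sample_ids))
        edges, _ = cell_cytokine_edges(frac2, matrix, truth.cytokine_panel,
                                       meta, "convexity")
        first_cell = fractions.cell_type_names[0]
        sub = edges[edges.cell_type == first_cell]
        assert sub["degenerate"].all()
        assert (sub["rho"] == 0).all() and (sub["p"] == 1).all()

    def test_too_few_samples_rejected(self, planted):
        matrix, meta, truth, fractions = planted
        tiny_meta = meta.iloc[:2]
        frac = CellFractions(fractions.sample_ids[:2], fractions.cell_type_names,
                             fractions.values[:2], pd.DataFrame())
        with pytest.raises(DegenerateInputError):
            cell_cytokine_edges(frac, matrix, truth.cytokine_panel, tiny_meta,
                                tiny_meta["location"].iloc[0])


class TestBuildNetwork:
    def test_threshold_rules(self):
        edges = edge_table([
            ("neutrophils", "IL1R2", 0.74, 2e-7),   # kept
            ("mast", "IL6", 0.59, 1e-3),            # effect size too small
            ("mono", "BTK", 0.90, 0.2),             # not significant
            ("plasma", "CCL3", -0.80, 1e-5),        # negative: one-sided rule
        ])
        g = build_network(edges)
        assert g.has_edge("neutrophils", "IL1R2")
        assert g.number_of_edges() == 1
        g2 = build_network(edges, two_sided=True)
        assert g2.has_edge("plasma", "CCL3")

    def test_edge_set_invariant_to_row_order(self, rng):
        edges = random_edge_table(rng)
        g1 = build_network(edges)
        g2 = build_network(edges.sample(frac=1.0, random_state=0))
        assert set(g1.edges) == set(g2.edges)


class TestConnectivity:
    def test_hand_example_signed_and_absolute(self):
        edges = edge_table([
            ("A", "x", 0.7, 0.01), ("A", "y", -0.5, 0.02), ("A", "z", 0.9, 0.5),
            ("B", "x", 0.4, 0.8),
        ])
        assert connectivity(edges, mode="signed")["A"] == pytest.approx(0.2)
        assert connectivity(edges, mode="absolute")["A"] == pytest.approx(1.2)
        assert connectivity(edges)["B"] == 0.0

    def test_matches_bruteforce_on_random_tables(self, rng):
        for _ in range(100):
            edges = random_edge_table(rng)
            got = connectivity(edges)
            for cell in edges["cell_type"].unique():
                expected = sum(r.rho for r in edges.itertuples()
                               if r.cell_type == cell and r.p < 0.05)
                assert got[cell] == pytest.approx(expected, abs=1e-12)

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(ValidationError):
            connectivity(random_edge_table(rng), mode="rms")


class TestEigenvectorCentrality:
    def test_path_graph(self):
        edges = edge_table([
            ("c1", "x", 0.5, 0.01), ("c2", "x", 0.5, 0.01),
            ("c1", "y", 0.5, 0.9), ("c2", "y", 0.5, 0.9),
        ])
        cent = eigenvector_centrality(edges)
        # path c1 - x - c2: eigenvector (1, sqrt2, 1)/2
        assert cent["x"] == pytest.approx(np.sqrt(2) / 2, abs=1e-9)
        assert cent["c1"] == pytest.approx(0.5, abs=1e-9)
        assert cent["y"] == 0.0  # isolated

    def test_matches_dense_eigendecomposition(self, rng):
        for _ in range(20):
            edges = random_edge_table(rng, n_cells=8, n_cyts=10)
            cent = eigenvector_centrality(edges)
            nodes = list(cent.index)
            A = np.zeros((len(nodes), len(nodes)))
            idx = {v: i for i, v in enumerate(nodes)}
            for r in edges.itertuples():
                if r.p < 0.05:
                    A[idx[r.cell_type], idx[r.cytokine]] = 1
                    A[idx[r.cytokine], idx[r.cell_type]] = 1
            if A.sum() == 0:
                assert (cent == 0).all()
                continue
            # oracle: dense eigendecomposition per connected component, then
            # the same principal-component rule (largest eigenvalue, ties by
            # smallest member index)
            import networkx as nx
            comps = [sorted(c) for c in
                     nx.connected_components(nx.from_numpy_array(A))
                     if len(c) > 1]
            best = None
            for comp in comps:
                w, V = np.linalg.eigh(A[np.ix_(comp, comp)])
                lam, vec = w[-1], np.abs(V[:, -1])
                if best is None or lam > best[0] + 1e-9 or \
                        (abs(lam - best[0]) <= 1e-9 and comp[0] < best[1][0]):
                    best = (lam, comp, vec / np.linalg.norm(vec))
            v = np.zeros(len(nodes))
            v[best[1]] = best[2]
            assert np.abs(cent.to_numpy() - v).max() < 1e-8

    def test_empty_graph_all_zero(self):
        edges = edge_table([("A", "x", 0.9, 0.9)])
        assert (eigenvector_centrality(edges) == 0).all()


class TestCompareLocations:
    def _summary(self, conn, cent, location):
        return NetworkSummary(location=location,
                              connectivity=pd.Series(conn),
                              centrality=pd.Series(cent),
                              mode="signed", alpha=0.05)

    def test_identical_summaries_give_zero(self):
        s = self._summary({"A": 1.0, "B": 0.5}, {"A": 0.3, "B": 0.1}, "convexity")
        t = self._summary({"A": 1.0, "B": 0.5}, {"A": 0.3, "B": 0.1}, "skull_base")
        diff = compare_locations(s, t)
        assert (diff["delta_connectivity"] == 0).all()

    def test_antisymmetry(self):
        s = self._summary({"A": 1.0, "B": 0.2}, {"A": 0.4, "B": 0.0}, "convexity")
        t = self._summary({"A": 0.1, "B": 0.9}, {"A": 0.1, "B": 0.3}, "skull_base")
        d1 = compare_locations(s, t)["delta_connectivity"]
        d2 = compare_locations(t, s)["delta_connectivity"]
        assert np.allclose(d1.sort_index(), -d2.sort_index())

    def test_mismatched_cells_rejected(self):
        s = self._summary({"A": 1.0}, {"A": 0.4}, "convexity")
        t = self._summary({"B": 1.0}, {"B": 0.4}, "skull_base")
        with pytest.raises(ValidationError):
            compare_locations(s, t)


class TestEndToEndScenario:
    def test_planted_design_dominates_both_locations(self):
        """Default planted couplings, one seed, full deconvolution path."""
        cfg = synthetic.SimulationConfig(
            n_genes=400, samples_per_study=(72,), skull_base_fraction=(0.5,),
            n_studies=1, module_sizes=(), gene_drop_rate=0.0,
            batch_shift_range=(0.0, 0.0), batch_scale_range=(1.0, 1.0),
            gene_shift_sd=0.0, seed=5)
        mats, meta, truth = synthetic.generate_cohort(cfg)
        sig = SignatureMatrix.from_frame(truth.signature)
        fr = estimate_fractions(prepare_mixture(mats[0]), sig)
        summaries = {}
        for loc in ("convexity", "skull_base"):
            edges, _ = cell_cytokine_edges(fr, mats[0], truth.cytokine_panel,
                                           meta, loc)
            summaries[loc] = summarize_location(edges)
        assert summaries["convexity"].connectivity.idxmax() == "Mast cells activated"
        assert summaries["skull_base"].connectivity.idxmax() == "T cells gamma delta"
        diff = compare_locations(summaries["convexity"], summaries["skull_base"])
        assert diff.loc["Mast cells activated", "delta_connectivity"] > 0
        assert diff.loc["T cells gamma delta", "delta_connectivity"] < 0
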