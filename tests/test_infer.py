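import numpy as np
import pandas as pd
import pytest

import scregnet as sr
from scregnet.infer import _network_from_rows


GENES = [f"g{i}" for i in range(6)]


def _empty_links(genes=GENES):
    return sr.GenePeakLinks({g: [] for g in genes})


class TestFitTargetModel:
    def test_zero_linked_peaks_still_fits_expression(self, rng):
        expr = rng.normal(size=(20, 6))
        s = sr.fit_target_model("g0", np.arange(20), expr, GENES, None, [], None,
                                n_trees=20, seed=0)
        assert len(s.p) == 0
        assert set(s.z.index) == set(GENES) - {"g0"}

    def test_perfect_copy_regulator_dominates(self, rng):
        expr = rng.normal(size=(20, 6))
        expr[:, 0] = expr[:, 3]
        s = sr.fit_target_model("g0", np.arange(20), expr, GENES, None, [], None,
                                n_trees=100, seed=0)
        assert s.z.idxmax() == "g3"

    def test_constant_target_warns_and_zeroes(self, rng):
        expr = rng.normal(size=(20, 6))
        expr[:, 0] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            s = sr.fit_target_model("g0", np.arange(20), expr, GENES, None, [], None,
                                    n_trees=10, seed=0)
        assert (s.z == 0).all()

    def test_too_small_neighborhood_rejected(self, rng):
        expr = rng.normal(size=(4, 6))
        with pytest.raises(ValueError, match="small"):
            sr.fit_target_model("g0", np.arange(4), expr, GENES, None, [], None)

    def test_importances_clipped_nonnegative(self, rng):
        expr = rng.normal(size=(15, 6))
        s = sr.fit_target_model("g0", np.arange(15), expr, GENES, None, [], None,
                                n_trees=30, seed=1, importance="permutation")
        assert (s.z >= 0).all() and (s.p >= 0).all()


class TestAggregateWeights:
    def _links(self, indicator):
        links = sr.GenePeakLinks({"g0": [("l1", 0.5), ("l2", 0.4), ("l3", 0.3), ("l4", 0.2)]})
        links.indicator = {"g0": indicator}
        return links

    def test_direct_arithmetic(self):
        s = sr.ImportanceScores("g0", pd.Series({"t1": 0.5}),
                                pd.Series({"l1": 0.2, "l2": 0.3}))
        w = sr.aggregate_weights(s, self._links({"t1": {"l1", "l2"}}))
        assert w["t1"] == pytest.approx(1.0)

    def test_non_tf_gets_bare_importance(self):
        s = sr.ImportanceScores("g0", pd.Series({"x": 0.37}), pd.Series({"l1": 0.2}))
        w = sr.aggregate_weights(s, self._links({}))
        assert w["x"] == pytest.approx(0.37)

    def test_matches_double_loop_oracle(self, rng):
        regs = [f"r{j}" for j in range(6)]
        peaks = [f"l{j}" for j in range(4)]
        z = pd.Series(rng.random(6), index=regs)
        p = pd.Series(rng.random(4), index=peaks)
        indicator = {
            r: {pk for pk in peaks if rng.random() < 0.4} for r in regs[:4]
        }
        links = sr.GenePeakLinks({"g0": [(pk, 0.5) for pk in peaks]})
        links.indicator = {"g0": indicator}
        w = sr.aggregate_weights(sr.ImportanceScores("g0", z.copy(), p), links)
        for r in regs:  # oracle: explicit double loop over (regulator, peak)
            expect = z[r]
            for pk in peaks:
                if pk in indicator.get(r, set()):
                    expect += p[pk]
            assert w[r] == pytest.approx(expect, abs=1e-12)


class TestCellNetworks:
    def test_identical_rows_and_seed_identical_network(self, rng):
        expr = rng.normal(size=(30, 6)) ** 2
        rows = np.arange(12)
        a = _network_from_rows("cellX", rows, expr, GENES, None, None,
                               _empty_links(), None, 30, 7, "impurity", None)
        b = _network_from_rows("cellX", rows, expr, GENES, None, None,
                               _empty_links(), None, 30, 7, "impurity", None)
        pd.testing.assert_frame_equal(a.edges, b.edges)

    def test_relabeling_storage_order_preserves_network(self, small_sim, rng):
        """Permuting how cells are stored must not change any cell's network."""
        ds = small_sim["dataset"]
        links = _empty_links(ds.rna.genes)
        graph = sr.rna_only_neighbors(ds.rna, k=8, seed=0)
        expr = sr.prepare_layers(ds)[0]
        net = sr.infer_cell_network(0, graph, expr, ds.rna.genes, None, None, links,
                                    targets=ds.rna.genes[:3], n_trees=20, seed=3)
        perm = rng.permutation(ds.n_cells)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(ds.n_cells)
        graph_p = sr.NeighborGraph(
            [ds.rna.cells[i] for i in perm], graph.k,
            inv[graph.neighbors[perm]], graph.affinities[perm],
        )
        net_p = sr.infer_cell_network(
            int(inv[0]), graph_p, expr[perm], ds.rna.genes, None, None, links,
            targets=ds.rna.genes[:3], n_trees=20, seed=3)
        pd.testing.assert_frame_equal(
            net.edges.sort_values(["regulator", "target"]).reset_index(drop=True),
            net_p.edges.sort_values(["regulator", "target"]).reset_index(drop=True),
        )

    def test_no_self_loops_and_edge_bound(self, multiome_networks, sim):
        g = len(sim["dataset"].rna.genes)
        for net in list(multiome_networks.values())[:5]:
            assert (net.edges["regulator"] != net.edges["target"]).all()
            assert len(net.edges) <= g * (g - 1)
            assert (net.edges["weight"] >= 0).all()

    def test_top1_regulator_recovery_beats_chance(self, multiome_networks, sim):
        """Restricted to TFs, the strongest regulator of a target is a planted
        one far more often than the ~15% a random TF pick would give."""
        truth, tfs = sim["truth"], set(sim["annot"].tf_ids)
        regs_of = {}
        for tf, tg, _, _ in truth.edges:
            regs_of.setdefault(tg, set()).add(tf)
        rates = []
        for net in list(multiome_networks.values())[:10]:
            e = net.edges[net.edges["regulator"].isin(tfs)]
            top1 = e.sort_values("weight", ascending=False).groupby("target").first()
            hit = sum(1 for tg, row in top1.iterrows()
                      if tg in regs_of and row["regulator"] in regs_of[tg])
            rates.append(hit / len(regs_of))
        assert np.mean(rates) >= 0.4


class TestCellTypeNetworks:
    def _net(self, cell_id, weights):
        return sr.CellNetwork(cell_id, pd.DataFrame(
            [(r, t, w) for (r, t), w in weights.items()],
            columns=["regulator", "target", "weight"]))

    def test_indirect_is_arithmetic_mean(self):
        a = self._net("a", {("t1", "g1"): 0.2})
        b = self._net("b", {("t1", "g1"): 0.4, ("t2", "g1"): 0.6})
        out = sr.infer_cell_type_network([], "indirect", None, GENES, None, None,
                                         _empty_links(), cell_networks=[a, b])
        w = out.edges.set_index(["regulator", "target"])["weight"]
        assert w[("t1", "g1")] == pytest.approx(0.3)
        assert w[("t2", "g1")] == pytest.approx(0.3)  # absent edge counts as 0

    def test_indirect_of_identical_networks_is_identity(self):
        a = self._net("a", {("t1", "g1"): 0.2, ("t2", "g2"): 0.8})
        out = sr.infer_cell_type_network([], "indirect", None, GENES, None, None,
                                         _empty_links(), cell_networks=[a, a, a])
        w = out.edges.set_index(["regulator", "target"])["weight"]
        assert w[("t1", "g1")] == pytest.approx(0.2)
        assert w[("t2", "g2")] == pytest.approx(0.8)

    def test_direct_mode_uses_exactly_the_type_cells(self, small_sim, monkeypatch):
        ds = small_sim["dataset"]
        expr = sr.prepare_layers(ds)[0]
        seen = {}
        import scregnet.infer as infer_mod

        orig = infer_mod.fit_target_model

        def spy(target, rows, *a, **k):
            seen["rows"] = len(rows)
            return orig(target, rows, *a, **k)

        monkeypatch.setattr(infer_mod, "fit_target_model", spy)
        cells = list(range(10))
        sr.infer_cell_type_network(cells, "direct", expr, ds.rna.genes, None, None,
                                   _empty_links(ds.rna.genes),
                                   targets=ds.rna.genes[:1], n_trees=10)
        assert seen["rows"] == len(cells)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            sr.infer_cell_type_network([], "sideways", None, GENES, None, None,
                                       _empty_links())


class TestTopPairs:
    def _net(self):
        return sr.CellNetwork("c", pd.DataFrame({
            "regulator": ["b", "a", "c", "a"],
            "target": ["g1", "g2", "g3", "g1"],
            "weight": [0.9, 0.5, 0.5, 0.1],
        }))

    def test_n1_returns_max(self):
        top = sr.top_pairs(self._net(), 1)
        assert top.iloc[0]["regulator"] == "b" and top.iloc[0]["weight"] == 0.9

    def test_equal_weights_lexicographic(self):
        net = sr.CellNetwork("c", pd.DataFrame({
            "regulator": ["b", "a", "a"], "target": ["g1", "g2", "g1"],
            "weight": [0.5, 0.5, 0.5]}))
        top = sr.top_pairs(net, 3)
        assert list(zip(top["regulator"], top["target"])) == [
            ("a", "g1"), ("a", "g2"), ("b", "g1")]

    def test_matches_full_sort_oracle(self, rng):
        edges = pd.DataFrame({
            "regulator": rng.choice([f"r{i}" for i in range(20)], 500),
            "target": rng.choice([f"t{i}" for i in range(30)], 500),
            "weight": rng.random(500).round(2),
        }).drop_duplicates(["regulator", "target"])
        net = sr.CellNetwork("c", edges)
        top = sr.top_pairs(net, 100)
        oracle = sorted(edges.itertuples(index=False),
                        key=lambda e: (-e.weight, e.regulator, e.target))[:100]
        assert [(e.regulator, e.target) for e in oracle] == \
            list(zip(top["regulator"], top["target"]))

    def test_oversized_n_warns_and_returns_all(self):
        with pytest.warns(UserWarning, match="returning all"):
            top = sr.top_pairs(self._net(), 99)
        assert len(top) == 4

    def test_seed_derivation_is_stable_and_bounded(self):
        s = sr.derive_seed(1, "cell0001", "TG07")
        assert s == sr.derive_seed(1, "cell0001", "TG07")
        assert 0 <= s < 2**31
        assert s != sr.derive_seed(2, "cell0001", "TG07")


class TestUnpairedInference:
    def test_donor_rows_feed_peak_predictors(self, sim):
        """Unpaired data: each RNA cell's neighborhood uses donor ATAC rows,
        and the resulting networks still rank planted edges highly."""
        import scregnet as sr_mod

        ds = sim["dataset"]
        unp = sr_mod.split_unpaired(ds, 0.5, seed=1)
        emb = sr_mod.preprocess_and_embed(unp, annot=sim["annot"], seed=1)
        graph, donors = sr_mod.unpaired_neighbors_and_pairing(emb, k=15)
        atac_pos = {c: i for i, c in enumerate(unp.atac.cells)}
        donor_rows = np.array([atac_pos[donors[c]] for c in unp.rna.cells])

        links = sr_mod.build_links(
            sim["annot"], sim["peaks"], unp.rna,
            unp.atac.values[donor_rows],
            unp.atac.peak_ids, sim["motif_hits"])
        dataset = sr_mod.MultiomeDataset(unp.rna, unp.atac, paired=False,
                                         cell_types=unp.cell_types)
        nets = sr_mod.infer_networks_for_cells(
            [0, 1], graph, dataset, links, sim["annot"], mode="multiome",
            donor_rows=donor_rows, n_trees=25, seed=1)
        genes = ds.rna.genes
        aupr = np.mean([sr_mod.aupr_vs_truth(n, sim["truth"].edge_pairs, genes)
                        for n in nets.values()])
        density = len(sim["truth"].edge_pairs) / (len(genes) * (len(genes) - 1))
        assert aupr >= 3 * density
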