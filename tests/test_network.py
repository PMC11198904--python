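"""Strong-pair table, multi-evidence network assembly, summaries."""

import numpy as np
import pandas as pd
import pytest

from lncreg.network import (Network, NetworkEdge, annotate_external_support,
                            assemble_network, coexpression_baseline,
                            network_summary, sign_bias_test, strong_pairs)
from lncreg.regress import ModelFit, ols_fit


def _fit(target, predictors, coefs, pvals, r2=0.5, n=100):
    return ModelFit(target, predictors, 0.0, np.asarray(coefs, float),
                    np.asarray(pvals, float), r2, n)


def _expr(rows: dict, n=60, seed=0):
    rng = np.random.default_rng(seed)
    data = {k: (v if v is not None else rng.standard_normal(n))
            for k, v in rows.items()}
    df = pd.DataFrame(data).T
    return df.sub(df.mean(axis=1), axis=0).div(df.std(axis=1), axis=0)


class TestStrongPairs:
    def test_ols_gate_is_inclusive_at_1e_minus_10(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(60)
        expr = _expr({"T": x + 0.1 * rng.standard_normal(60), "L1": x,
                      "L2": None})
        fits = {"T": _fit("T", ["L1", "L2"], [1.0, 0.0], [1e-9, 0.5])}
        table, _ = strong_pairs(fits, {"T": 0.5}, {"T": 0.0}, expr,
                                pd.DataFrame())
        assert table.empty  # 1e-9 > 1e-10 gate
        fits = {"T": _fit("T", ["L1"], [1.0], [1e-11])}
        table, _ = strong_pairs(fits, {"T": 0.5}, {"T": 0.0}, expr,
                                pd.DataFrame())
        assert len(table) == 1 and table.loc[0, "positive"]

    def test_r2_and_empirical_gates(self):
        expr = _expr({"T": None, "L1": None}, seed=2)
        expr.loc["L1"] = expr.loc["T"]
        fits = {"T": _fit("T", ["L1"], [1.0], [1e-20])}
        t1, _ = strong_pairs(fits, {"T": 0.1}, {"T": 0.0}, expr,
                             pd.DataFrame())
        t2, _ = strong_pairs(fits, {"T": 0.5}, {"T": 0.05}, expr,
                             pd.DataFrame())
        t3, _ = strong_pairs(fits, {"T": 0.5}, {"T": 0.0}, expr,
                             pd.DataFrame())
        assert t1.empty and t2.empty and len(t3) == 1

    def test_empty_fits(self):
        table, summary = strong_pairs({}, {}, {}, pd.DataFrame(),
                                      pd.DataFrame())
        assert table.empty and (summary["n_pairs"] == 0).all()


class TestAssembleNetwork:
    def test_insignificant_coefficient_makes_no_edge(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(80)
        expr = _expr({"T": None, "L1": None}, n=80, seed=3)
        ev = pd.DataFrame([{"target_id": "T", "lncrna_id": "L1",
                            "overlapping": True}])
        net = assemble_network(ev, expr, r2_min=0.0, coef_p_max=1e-6)
        assert net.edges == []  # L1 independent of T

    def test_planted_edge_recovered_with_sign(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(100)
        t = -1.2 * x + 0.3 * rng.standard_normal(100)
        expr = _expr({"T": t, "L1": x}, n=100, seed=4)
        ev = pd.DataFrame([{"target_id": "T", "lncrna_id": "L1",
                            "cerna": True}])
        net = assemble_network(ev, expr)
        assert len(net.edges) == 1
        e = net.edges[0]
        assert e.sign == -1 and e.evidence["cerna"]

    def test_no_evidence_no_network(self):
        net = assemble_network(pd.DataFrame(), pd.DataFrame())
        assert net.edges == []

    def test_flipping_target_flips_signs(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(100)
        t = x + 0.3 * rng.standard_normal(100)
        ev = pd.DataFrame([{"target_id": "T", "lncrna_id": "L1",
                            "proximal": True}])
        e1 = assemble_network(ev, _expr({"T": t, "L1": x}, 100, 5)).edges[0]
        e2 = assemble_network(ev, _expr({"T": -t, "L1": x}, 100, 5)).edges[0]
        assert e1.sign == -e2.sign


class TestCoexpressionBaseline:
    def test_top_pair_and_ties(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(50)
        expr = _expr({"L1": x, "L2": -x, "G1": x, "G2": None}, 50, 6)
        top = coexpression_baseline(expr, ["L1", "L2"], ["G1", "G2"], 1)
        # |r|=1 tie between (L1,G1) and (L2,G1): lexicographic winner
        assert top.iloc[0]["lncrna_id"] == "L1" and top.iloc[0]["target_id"] == "G1"

    def test_k_too_large(self):
        expr = _expr({"L1": None, "G1": None}, 30, 7)
        with pytest.raises(ValueError):
            coexpression_baseline(expr, ["L1"], ["G1"], 5)


class TestExternalSupport:
    @staticmethod
    def _net():
        return Network([NetworkEdge("L1", "G1", 1, 0.5, 1e-3,
                                    {"proximal": True})])

    @staticmethod
    def _ann():
        from tests.test_genomics import make_annotation
        return make_annotation([
            ("L1", "lncRNA", "chr1", 0, 1_000, "+"),
            ("G1", "mRNA", "chr1", 5_000_000, 5_010_000, "+")])

    def test_site_in_gene_body_supported(self):
        sites = pd.DataFrame([{"lncrna_id": "L1", "chrom": "chr1",
                               "start": 5_001_000, "end": 5_001_100}])
        net, counts = annotate_external_support(self._net(), sites, self._ann())
        assert net.edges[0].external_support and counts["n_supported"] == 1

    def test_one_basepair_beyond_window_unsupported(self):
        sites = pd.DataFrame([{"lncrna_id": "L1", "chrom": "chr1",
                               "start": 6_010_001 + 1, "end": 6_010_002 + 1}])
        net, counts = annotate_external_support(self._net(), sites, self._ann())
        assert not net.edges[0].external_support


class TestSummary:
    @staticmethod
    def _bipartite(n_edges, n_lnc, n_tgt, n_activating, seed=0):
        rng = np.random.default_rng(seed)
        pairs = [(l, t) for l in range(n_lnc) for t in range(n_tgt)]
        idx = rng.choice(len(pairs), size=n_edges, replace=False)
        edges = []
        for rank, i in enumerate(idx):
            l, t = pairs[i]
            edges.append(NetworkEdge(f"L{l:04d}", f"G{t:04d}",
                                     1 if rank < n_activating else -1,
                                     1.0, 1e-4, {"proximal": True}))
        return Network(edges)

    def test_cohort_scale_degree_arithmetic(self):
        """1157 edges over 508 regulators and 232 targets: 2.3 targets per
        lncRNA and 5.0 regulators per mRNA at one-decimal rounding."""
        edges = []
        seen = set()
        i = 0
        while len(edges) < 1157:
            pair = (f"L{i % 508:04d}", f"G{(i + i // 508) % 232:04d}")
            i += 1
            if pair in seen:
                continue
            seen.add(pair)
            edges.append(NetworkEdge(pair[0], pair[1],
                                     1 if len(edges) < 782 else -1,
                                     1.0, 1e-4, {"proximal": True}))
        s = network_summary(Network(edges))
        assert s["n_edges"] == 1157
        assert s["n_lncrnas"] == 508 and s["n_targets"] == 232
        assert s["mean_targets_per_lncrna"] == 2.3
        assert s["mean_regulators_per_target"] == 5.0
        assert s["n_activating"] == 782 and s["n_inhibitory"] == 375

    def test_exact_degree_means(self):
        edges = [NetworkEdge(f"L{i % 5}", f"G{i}", 1, 1.0, 1e-4,
                             {"cerna": True}) for i in range(10)]
        s = network_summary(Network(edges))
        assert s["mean_targets_per_lncrna"] == 2.0
        assert s["mean_regulators_per_target"] == 1.0

    def test_single_edge(self):
        s = network_summary(Network([NetworkEdge("L", "G", 1, 1.0, 1e-4,
                                                 {"cerna": True})]))
        assert s["mean_targets_per_lncrna"] == 1.0
        assert s["mean_regulators_per_target"] == 1.0

    def test_degree_accounting(self):
        net = self._bipartite(200, 40, 50, 150, seed=2)
        assert int(net.out_degree().sum()) == len(net.edges)
        assert int(net.in_degree().sum()) == len(net.edges)

    def test_empty_network_errors(self):
        with pytest.raises(ValueError):
            network_summary(Network([]))

    def test_duplicate_edges_rejected(self):
        e = NetworkEdge("L", "G", 1, 1.0, 1e-4, {"cerna": True})
        with pytest.raises(ValueError):
            Network([e, NetworkEdge("L", "G", -1, -1.0, 1e-3, {})])


class TestSignBias:
    @staticmethod
    def _network_with(lnc_act, lnc_inh, other_act, other_inh):
        edges = []
        k = 0
        for sign, count, lnc in ((1, lnc_act, "LX"), (-1, lnc_inh, "LX")):
            for _ in range(count):
                edges.append(NetworkEdge(lnc, f"G{k}", sign, float(sign),
                                         1e-4, {"cerna": True}))
                k += 1
        for sign, count in ((1, other_act), (-1, other_inh)):
            for i in range(count):
                edges.append(NetworkEdge(f"L{i}_{sign}", f"G{k}", sign,
                                         float(sign), 1e-4, {"cerna": True}))
                k += 1
        return Network(edges)

    def test_strong_activator_bias(self):
        """18 of 19 activating against a ~69% global activating fraction is
        significant below 0.01 (exact tail checked against a 3-line oracle)."""
        net = self._network_with(18, 1, 782 - 18, 355 - 1)
        direction, p = sign_bias_test(net, "LX")
        assert direction == 1 and p < 0.01
        from math import comb
        p_global = 782 / 1137
        oracle = sum(comb(19, j) * p_global**j * (1 - p_global)**(19 - j)
                     for j in range(18, 20))
        assert p == pytest.approx(oracle, rel=1e-10)

    def test_conforming_lncrna_not_significant(self):
        net = self._network_with(7, 3, 63, 27)  # exactly the global 70%
        direction, p = sign_bias_test(net, "LX")
        assert p > 0.5

    def test_degenerate_global_ratio(self):
        net = self._network_with(10, 0, 50, 0)
        assert sign_bias_test(net, "LX") is None

    def test_min_edges(self):
        net = self._network_with(2, 1, 30, 20)
        assert sign_bias_test(net, "LX", min_edges=5) is None
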