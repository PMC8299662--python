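import numpy as np
import pandas as pd
import pytest

from cernet.data_io import DataValidationError, ExpressionMatrix, InteractionTable
from cernet.network import (
    CeRNANetwork,
    CeRNATriplet,
    build_cerna_network,
    correlation_filter,
    host_gene_overlap,
    network_summary,
    subnetwork_by_circ,
)

from _oracles import brute_force_triplets, rank_average, spearman_rho_enum


def _de(rows: dict[str, str], kind: str = "x") -> pd.DataFrame:
    """Build a DE call table from {feature: direction} (none = not DE)."""
    return pd.DataFrame(
        {
            "feature_id": list(rows),
            "log2fc": [2.0 if d == "up" else -2.0 if d == "down" else 0.0 for d in rows.values()],
            "p_value": [1e-4 if d != "none" else 0.9 for d in rows.values()],
            "adj_p": [1e-3 if d != "none" else 0.95 for d in rows.values()],
            "direction": list(rows.values()),
            "dataset_id": kind,
        }
    )


def _pairs(kind, *pairs):
    return InteractionTable(kind=kind, pairs=frozenset(pairs))


class TestBuildCernaNetwork:
    def test_empty_interactions_give_empty_network(self):
        net = build_cerna_network(
            _de({"c1": "up"}), _de({"m1": "down"}), _de({"g1": "up"}),
            _pairs("miRNA_circRNA"), _pairs("miRNA_mRNA"),
        )
        assert len(net) == 0

    def test_sign_rule_excludes_concordant_mirna_gene(self):
        """circA down + miR1 up admits only the down gene; the up gene breaks
        the sign rule.  Verified against exhaustive enumeration of the
        1x1x2 cross-product."""
        de_c = _de({"circA": "down"})
        de_m = _de({"miR1": "up"})
        de_g = _de({"gene1": "down", "gene2": "up"})
        mc = _pairs("miRNA_circRNA", ("miR1", "circA"))
        mg = _pairs("miRNA_mRNA", ("miR1", "gene1"), ("miR1", "gene2"))
        net = build_cerna_network(de_c, de_m, de_g, mc, mg)
        assert [(t.circ_id, t.mirna_id, t.gene_id) for t in net.triplets] == [
            ("circA", "miR1", "gene1")
        ]
        oracle = brute_force_triplets(
            {"circA": "down"}, {"miR1": "up"}, {"gene1": "down", "gene2": "up"},
            set(mc.pairs), set(mg.pairs),
        )
        assert {(t.circ_id, t.mirna_id, t.gene_id) for t in net.triplets} == oracle

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_on_random_instances(self, seed):
        """Random DE calls + random pair tables (<=50 features per kind):
        the join must equal full cross-product enumeration."""
        rng = np.random.default_rng(seed)
        circs = [f"c{i}" for i in range(rng.integers(5, 50))]
        mirnas = [f"m{i}" for i in range(rng.integers(5, 50))]
        genes = [f"g{i}" for i in range(rng.integers(5, 50))]
        dirs = np.array(["up", "down", "none"])
        cd = {c: str(rng.choice(dirs)) for c in circs}
        md = {m: str(rng.choice(dirs)) for m in mirnas}
        gd = {g: str(rng.choice(dirs)) for g in genes}
        mc = {(m, c) for m in mirnas for c in circs if rng.random() < 0.15}
        mg = {(m, g) for m in mirnas for g in genes if rng.random() < 0.15}
        net = build_cerna_network(
            _de(cd), _de(md), _de(gd),
            InteractionTable(kind="miRNA_circRNA", pairs=frozenset(mc)),
            InteractionTable(kind="miRNA_mRNA", pairs=frozenset(mg)),
        )
        assert {(t.circ_id, t.mirna_id, t.gene_id) for t in net.triplets} == brute_force_triplets(
            cd, md, gd, mc, mg
        )
        # every output node is a DE feature and every triplet sign-consistent
        for t in net.triplets:
            assert cd[t.circ_id] != "none" and md[t.mirna_id] != "none" and gd[t.gene_id] != "none"
            assert t.gene_direction == t.circ_direction
            assert t.gene_direction != t.mirna_direction

    def test_planted_triplets_recovered_exactly_no_decoys(self, bundle):
        """With perfect DE calls injected from the manifest, the network is
        exactly the planted triplets; every decoy candidate is excluded."""
        truth = bundle.manifest.de_features
        net = build_cerna_network(
            _de(truth["circRNA"]), _de(truth["miRNA"]), _de(truth["mRNA"]),
            bundle.mc_pairs, bundle.mg_pairs,
        )
        assert set(net.triplets) == set(bundle.manifest.planted_triplets)
        admitted = {(t.circ_id, t.mirna_id, t.gene_id) for t in net.triplets}
        for decoy in bundle.manifest.decoy_candidates:
            assert (decoy["circ"], decoy["mirna"], decoy["gene"]) not in admitted, decoy

    def test_correlation_mode_requires_expression(self):
        with pytest.raises(DataValidationError, match="correlation"):
            build_cerna_network(
                _de({"c": "up"}), _de({"m": "down"}), _de({"g": "up"}),
                _pairs("miRNA_circRNA"), _pairs("miRNA_mRNA"), mode="correlation",
            )

    def test_mismatched_pair_kinds_rejected(self):
        with pytest.raises(DataValidationError, match="kind"):
            build_cerna_network(
                _de({"c": "up"}), _de({"m": "down"}), _de({"g": "up"}),
                _pairs("miRNA_mRNA"), _pairs("miRNA_mRNA"),
            )


class TestCeRNANetworkContainer:
    def test_sign_violating_triplet_rejected_on_construction(self):
        bad = CeRNATriplet("c", "m", "g", "up", "up", "up")
        with pytest.raises(DataValidationError, match="sign rule"):
            CeRNANetwork(triplets=(bad,))

    def test_canonical_lexicographic_order(self):
        t1 = CeRNATriplet("c2", "m", "g", "up", "down", "up")
        t2 = CeRNATriplet("c1", "m", "g", "up", "down", "up")
        net = CeRNANetwork(triplets=(t1, t2, t1))
        assert [t.circ_id for t in net.triplets] == ["c1", "c2"]


class TestCorrelationFilter:
    def _expr(self, rows: dict, kind="miRNA"):
        data = pd.DataFrame(rows).T
        data.columns = [f"s{i}" for i in range(data.shape[1])]
        return ExpressionMatrix(data=data, feature_kind=kind)

    def test_perfect_anti_monotone_retained(self):
        x = list(np.arange(10.0))
        ex = self._expr({"m1": x})
        ey = self._expr({"p1": [-v for v in x]}, kind="mRNA")
        out = correlation_filter(ex, ey, _pairs("miRNA_mRNA", ("m1", "p1")), 0.5, "negative")
        assert ("m1", "p1") in out.pairs

    def test_constant_partner_dropped(self):
        ex = self._expr({"m1": list(np.arange(8.0))})
        ey = self._expr({"p1": [3.0] * 8}, kind="mRNA")
        out = correlation_filter(ex, ey, _pairs("miRNA_mRNA", ("m1", "p1")), 0.5, "negative")
        assert len(out) == 0

    def test_six_sample_rho_matches_hand_rank_formula(self):
        x = [2.0, 9.0, 4.0, 4.0, 7.0, 1.0]
        y = [5.0, 1.0, 8.0, 2.0, 3.0, 9.0]
        ex = self._expr({"m1": x})
        ey = self._expr({"p1": y}, kind="mRNA")
        rho = spearman_rho_enum(x, y)
        assert rho < 0  # sanity of the hand computation itself
        out = correlation_filter(
            ex, ey, _pairs("miRNA_mRNA", ("m1", "p1")), abs(rho) - 1e-9, "negative"
        )
        assert ("m1", "p1") in out.pairs
        out2 = correlation_filter(
            ex, ey, _pairs("miRNA_mRNA", ("m1", "p1")), abs(rho) + 1e-9, "negative"
        )
        assert ("m1", "p1") not in out2.pairs

    def test_too_few_shared_samples_rejected(self):
        ex = self._expr({"m1": [1.0, 2.0, 3.0, 4.0]})
        ey = self._expr({"p1": [1.0, 2.0, 3.0, 4.0]}, kind="mRNA")
        with pytest.raises(DataValidationError, match="5 shared"):
            correlation_filter(ex, ey, _pairs("miRNA_mRNA", ("m1", "p1")), 0.5, "negative")


class TestSummaries:
    def _net(self, *specs):
        return CeRNANetwork(
            triplets=tuple(CeRNATriplet(c, m, g, "up", "down", "up") for c, m, g in specs)
        )

    def test_percentages_to_two_decimals(self):
        net = self._net(("c1", "m1", "g1"), ("c2", "m2", "g2"), ("c3", "m3", "g3"))
        summary = network_summary(
            net, {"circRNA": 10, "miRNA": 147, "mRNA": 4222}
        ).set_index("kind")
        assert summary.loc["circRNA", "percent"] == 30.00
        # 3 of 147 = 2.04; the reference composition 6/147 = 4.08
        assert summary.loc["miRNA", "percent"] == 2.04
        assert network_summary(
            self._net(*[(f"c{i}", f"m{i}", f"g{i}") for i in range(6)]),
            {"circRNA": 10, "miRNA": 147, "mRNA": 4222},
        ).set_index("kind").loc["miRNA", "percent"] == 4.08

    def test_empty_network_all_zero(self):
        summary = network_summary(CeRNANetwork(), {"circRNA": 10, "miRNA": 147, "mRNA": 4222})
        assert (summary["n_network"] == 0).all()
        assert (summary["percent"] == 0.0).all()

    def test_subnetworks_partition_the_whole(self):
        net = self._net(("c1", "m1", "g1"), ("c1", "m1", "g2"), ("c2", "m2", "g3"))
        s1 = subnetwork_by_circ(net, "c1")
        s2 = subnetwork_by_circ(net, "c2")
        assert set(s1.triplets) | set(s2.triplets) == set(net.triplets)
        assert set(s1.triplets) & set(s2.triplets) == set()

    def test_absent_circ_gives_empty_subnetwork(self):
        net = self._net(("c1", "m1", "g1"))
        assert len(subnetwork_by_circ(net, "nope")) == 0

    def test_subnetwork_genes_match_manifest(self, bundle):
        truth_by_circ: dict[str, set] = {}
        for t in bundle.manifest.planted_triplets:
            truth_by_circ.setdefault(t.circ_id, set()).add(t.gene_id)
        net = CeRNANetwork(triplets=tuple(bundle.manifest.planted_triplets))
        for circ, genes in truth_by_circ.items():
            assert subnetwork_by_circ(net, circ).gene_ids == genes


class TestHostGeneOverlap:
    def _degs(self, n):
        return _de({f"g{i}": "up" for i in range(n)})

    def test_disjoint_sets(self):
        assert host_gene_overlap(["h1", "h2"], self._degs(100)) == (0, 0.0)

    @pytest.mark.parametrize(("n_shared", "expected_pct"), [(42, 0.99), (7, 0.17)])
    def test_shared_host_genes_percentage(self, n_shared, expected_pct):
        degs = self._degs(4222)
        hosts = [f"g{i}" for i in range(n_shared)] + ["absent1", "absent2"]
        assert host_gene_overlap(hosts, degs) == (n_shared, expected_pct)
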