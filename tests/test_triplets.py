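"""Triplet assembly, seed-site filtering, and network export."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cerna import assemble_triplets, export_network, filter_by_seed_sites, triplet_network
from cerna.seedmatch import NO_SITE

from conftest import make_pair_table


def brute_force_triplets(mi_lnc, mi_mrna, lnc_mrna):
    """Exhaustive triple loop over all (L, M, G) combinations."""
    ml = set(zip(mi_lnc["id_a"], mi_lnc["id_b"]))
    mg = set(zip(mi_mrna["id_a"], mi_mrna["id_b"]))
    lg = set(zip(lnc_mrna["id_a"], lnc_mrna["id_b"]))
    lncs = {l for _, l in ml} | {l for l, _ in lg}
    mis = {m for m, _ in ml} | {m for m, _ in mg}
    gs = {g for _, g in mg} | {g for _, g in lg}
    out = set()
    for l, m, g in itertools.product(lncs, mis, gs):
        if (m, l) in ml and (m, g) in mg and (l, g) in lg:
            out.add((l, m, g))
    return out


def random_pair_lists(rng, n_lnc=8, n_mi=5, n_g=8, density=0.3):
    lncs = [f"L{i}" for i in range(n_lnc)]
    mis = [f"M{i}" for i in range(n_mi)]
    gs = [f"G{i}" for i in range(n_g)]

    def sample(a_ids, b_ids):
        rows = [
            (a, b, round(rng.uniform(-0.7, 0.7), 2))
            for a in a_ids for b in b_ids if rng.random() < density
        ]
        return rows

    return (
        make_pair_table(sample(mis, lncs), "miRNA", "lncRNA", "miRNA-lncRNA"),
        make_pair_table(sample(mis, gs), "miRNA", "mRNA", "miRNA-mRNA"),
        make_pair_table(sample(lncs, gs), "lncRNA", "mRNA", "lncRNA-mRNA"),
    )


class TestAssembly:
    def test_published_pair_lists_give_sixteen_triplets(self, ovarian_pairs):
        t = assemble_triplets(
            ovarian_pairs["miRNA-lncRNA"],
            ovarian_pairs["miRNA-mRNA"],
            ovarian_pairs["lncRNA-mRNA"],
        )
        assert len(t) == 16
        counts = t["mirna_id"].value_counts()
        assert counts["miR-203a"] == 15 and counts["miR-148a"] == 1
        # supporting rho values travel with the triplet
        row = t.set_index(["lncrna_id", "mirna_id", "mrna_id"]).loc[
            ("OIP5-AS1", "miR-203a", "ZEB2")
        ]
        assert (row["rho_mi_lnc"], row["rho_mi_mrna"], row["rho_lnc_mrna"]) == (
            -0.42, -0.41, 0.65,
        )

    def test_empty_pair_list_gives_no_triplets(self, ovarian_pairs):
        empty = ovarian_pairs["lncRNA-mRNA"].iloc[0:0]
        t = assemble_triplets(
            ovarian_pairs["miRNA-lncRNA"], ovarian_pairs["miRNA-mRNA"], empty
        )
        assert len(t) == 0

    def test_matches_brute_force_on_random_lists(self, rng):
        for _ in range(25):
            ml, mg, lg = random_pair_lists(rng)
            got = assemble_triplets(ml, mg, lg)
            expected = brute_force_triplets(ml, mg, lg)
            assert set(zip(got["lncrna_id"], got["mirna_id"], got["mrna_id"])) == expected

    def test_monotone_in_pair_lists(self, rng):
        ml, mg, lg = random_pair_lists(rng, density=0.4)
        full = len(assemble_triplets(ml, mg, lg))
        for frac in (0.3, 0.6, 1.0):
            k = int(len(lg) * frac)
            sub = len(assemble_triplets(ml, mg, lg.iloc[:k]))
            assert sub <= full

    def test_duplicates_deduplicated_with_warning(self, ovarian_pairs):
        dup = pd.concat(
            [ovarian_pairs["miRNA-lncRNA"]] * 2, ignore_index=True
        )
        with pytest.warns(UserWarning, match="duplicate"):
            t = assemble_triplets(
                dup, ovarian_pairs["miRNA-mRNA"], ovarian_pairs["lncRNA-mRNA"]
            )
        assert len(t) == 16

    def test_class_mismatch_rejected(self, ovarian_pairs):
        with pytest.raises(ValueError, match="expected classes"):
            assemble_triplets(
                ovarian_pairs["miRNA-mRNA"],  # wrong slot
                ovarian_pairs["miRNA-mRNA"],
                ovarian_pairs["lncRNA-mRNA"],
            )


class TestSeedFilter:
    def test_published_annotations_select_supported_members(
        self, ovarian_pairs, ovarian_sites
    ):
        t = assemble_triplets(
            ovarian_pairs["miRNA-lncRNA"],
            ovarian_pairs["miRNA-mRNA"],
            ovarian_pairs["lncRNA-mRNA"],
        )
        kept = filter_by_seed_sites(t, ovarian_sites)
        assert set(kept["lncrna_id"]) == {"OIP5-AS1", "MLK7-AS1"}
        assert set(kept["mrna_id"]) == {"c-MET", "ZEB1", "ZEB2"}
        by_key = kept.set_index(["lncrna_id", "mrna_id"])
        assert by_key.loc[("OIP5-AS1", "c-MET"), "mrna_site_type"] == "8mer"
        assert by_key.loc[("OIP5-AS1", "c-MET"), "lncrna_site_type"] == "7mer-m8"

    def test_empty_annotations_remove_everything(self, ovarian_pairs, ovarian_sites):
        t = assemble_triplets(
            ovarian_pairs["miRNA-lncRNA"],
            ovarian_pairs["miRNA-mRNA"],
            ovarian_pairs["lncRNA-mRNA"],
        )
        empty = ovarian_sites.iloc[0:0]
        assert len(filter_by_seed_sites(t, empty)) == 0

    def test_full_annotation_is_identity(self, ovarian_pairs):
        t = assemble_triplets(
            ovarian_pairs["miRNA-lncRNA"],
            ovarian_pairs["miRNA-mRNA"],
            ovarian_pairs["lncRNA-mRNA"],
        )
        ids = set(t["lncrna_id"]) | set(t["mrna_id"])
        sites = pd.DataFrame(
            [
                {"mirna_id": m, "transcript_id": tid, "site_type": "6mer"}
                for m in set(t["mirna_id"]) for tid in ids
            ]
        )
        kept = filter_by_seed_sites(t, sites)
        assert len(kept) == len(t)
        assert (kept["lncrna_site_type"] == "6mer").all()


class TestNetworkExport:
    def _table2_triplets(self, ovarian_pairs):
        return assemble_triplets(
            ovarian_pairs["miRNA-lncRNA"],
            ovarian_pairs["miRNA-mRNA"],
            ovarian_pairs["lncRNA-mRNA"],
        )

    def test_single_triplet_is_a_triangle(self):
        t = pd.DataFrame(
            [{
                "lncrna_id": "L", "mirna_id": "M", "mrna_id": "G",
                "rho_mi_lnc": -0.5, "rho_mi_mrna": -0.4, "rho_lnc_mrna": 0.6,
                "lncrna_site_type": NO_SITE, "mrna_site_type": NO_SITE,
            }]
        )
        g = triplet_network(t)
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 3

    def test_published_network_node_count(self, ovarian_pairs):
        # every RNA printed in the pair lists joins at least one triplet:
        # 2 miRNAs + 5 lncRNAs + 7 mRNAs
        g = triplet_network(self._table2_triplets(ovarian_pairs))
        ids = set()
        t = self._table2_triplets(ovarian_pairs)
        for col in ("lncrna_id", "mirna_id", "mrna_id"):
            ids |= set(t[col])
        assert g.number_of_nodes() == len(ids) == 14

    def test_graphml_round_trip(self, ovarian_pairs, tmp_path):
        t = self._table2_triplets(ovarian_pairs)
        path = tmp_path / "net.graphml"
        export_network(t, path, "graphml")
        back = nx.read_graphml(path)
        g = triplet_network(t)
        assert set(back.nodes) == set(g.nodes)
        assert {frozenset(e) for e in back.edges} == {frozenset(e) for e in g.edges}
        for n in g.nodes:
            assert back.nodes[n]["rna_class"] == g.nodes[n]["rna_class"]

    def test_sif_export_and_unknown_format(self, ovarian_pairs, tmp_path):
        t = self._table2_triplets(ovarian_pairs)
        path = tmp_path / "net.sif"
        export_network(t, path, "sif")
        lines = path.read_text().strip().split("\n")
        assert len(lines) == triplet_network(t).number_of_edges()
        with pytest.raises(ValueError, match="graphml, sif"):
            export_network(t, tmp_path / "x", "dot")

    def test_empty_export_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            export_network(pd.DataFrame(columns=["lncrna_id"]), "x", "sif")
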