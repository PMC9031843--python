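"""Assembly of lncRNA-miRNA-mRNA triplets from screened pair lists.

A candidate triplet (L, M, G) is emitted exactly when all three supporting
edges survived the correlation screen: (M, L) in the miRNA-lncRNA list,
(M, G) in the miRNA-mRNA list, and (L, G) in the lncRNA-mRNA list. Triplets
can then be filtered by canonical seed-site support: the competing lncRNA
and mRNA must *both* carry at least one binding site for the shared miRNA.
"""

from __future__ import annotations

import warnings

import networkx as nx
import pandas as pd

from .seedmatch import NO_SITE, SITE_PRIORITY

TRIPLET_COLUMNS = [
    "lncrna_id", "mirna_id", "mrna_id",
    "rho_mi_lnc", "rho_mi_mrna", "rho_lnc_mrna",
    "lncrna_site_type", "mrna_site_type",
]


def _pair_map(pairs: pd.DataFrame, class_a: str, class_b: str, name: str) -> dict:
    """(id_a, id_b) -> rho with class validation and dedup."""
    need = {"id_a", "class_a", "id_b", "class_b", "rho"}
    missing = need - set(pairs.columns)
    if missing:
        raise ValueError(f"{name}: missing columns {sorted(missing)}")
    bad = pairs[(pairs["class_a"] != class_a) | (pairs["class_b"] != class_b)]
    if len(bad):
        raise ValueError(
            f"{name}: expected classes ({class_a}, {class_b}); offending rows: "
            f"{bad[['id_a', 'class_a', 'id_b', 'class_b']].head().to_dict('records')}"
        )
    dup = pairs.duplicated(subset=["id_a", "id_b"])
    if dup.any():
        warnings.warn(f"{name}: {int(dup.sum())} duplicate pairs dropped")
        pairs = pairs[~dup]
    return {(a, b): r for a, b, r in zip(pairs["id_a"], pairs["id_b"], pairs["rho"])}


def assemble_triplets(
    mi_lnc: pd.DataFrame, mi_mrna: pd.DataFrame, lnc_mrna: pd.DataFrame
) -> pd.DataFrame:
    """All (lncRNA, miRNA, mRNA) triplets supported by three screened pairs.

    Pair tables use the screening output columns (id_a/class_a are the
    miRNA for miRNA-* lists and the lncRNA for the lncRNA-mRNA list).
    Output is sorted lexicographically by (lncrna_id, mirna_id, mrna_id)
    and carries the three supporting correlation coefficients.
    """
    ml = _pair_map(mi_lnc, "miRNA", "lncRNA", "mi_lnc")
    mg = _pair_map(mi_mrna, "miRNA", "mRNA", "mi_mrna")
    lg = _pair_map(lnc_mrna, "lncRNA", "mRNA", "lnc_mrna")

    lnc_by_mi: dict[str, list[str]] = {}
    for m, l in ml:
        lnc_by_mi.setdefault(m, []).append(l)
    rows = []
    for (m, g), rho_mg in mg.items():
        for l in lnc_by_mi.get(m, []):
            if (l, g) in lg:
                rows.append(
                    {
                        "lncrna_id": l,
                        "mirna_id": m,
                        "mrna_id": g,
                        "rho_mi_lnc": ml[(m, l)],
                        "rho_mi_mrna": rho_mg,
                        "rho_lnc_mrna": lg[(l, g)],
                        "lncrna_site_type": NO_SITE,
                        "mrna_site_type": NO_SITE,
                    }
                )
    out = pd.DataFrame(rows, columns=TRIPLET_COLUMNS)
    return out.sort_values(
        ["lncrna_id", "mirna_id", "mrna_id"], kind="stable"
    ).reset_index(drop=True)


def _site_lookup(sites: pd.DataFrame) -> dict[tuple[str, str], str]:
    """(mirna_id, transcript_id) -> best canonical site type."""
    best: dict[tuple[str, str], str] = {}
    for _, row in sites.iterrows():
        stype = row["site_type"]
        if pd.isna(stype) or stype == NO_SITE:
            continue
        if stype not in SITE_PRIORITY:
            raise ValueError(f"unknown site type: {stype!r}")
        key = (row["mirna_id"], row["transcript_id"])
        if key not in best or SITE_PRIORITY[stype] < SITE_PRIORITY[best[key]]:
            best[key] = stype
    return best


def filter_by_seed_sites(triplets: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Keep triplets whose lncRNA AND mRNA both carry a canonical site for
    the triplet's miRNA; annotate each member's best site type
    (8mer > 7mer-m8 > 7mer-A1 > 6mer)."""
    lookup = _site_lookup(sites)
    out = triplets.copy()
    lnc_site = [
        lookup.get((m, l)) for m, l in zip(out["mirna_id"], out["lncrna_id"])
    ]
    mrna_site = [
        lookup.get((m, g)) for m, g in zip(out["mirna_id"], out["mrna_id"])
    ]
    out["lncrna_site_type"] = [s or NO_SITE for s in lnc_site]
    out["mrna_site_type"] = [s or NO_SITE for s in mrna_site]
    keep = [ls is not None and ms is not None for ls, ms in zip(lnc_site, mrna_site)]
    return out[keep].reset_index(drop=True)


def triplet_network(triplets: pd.DataFrame) -> nx.Graph:
    """Undirected RNA interaction graph of the assembled triplets: nodes
    typed by RNA class, edges weighted by the supporting Spearman rho."""
    g = nx.Graph()
    rows = triplets.sort_values(["lncrna_id", "mirna_id", "mrna_id"], kind="stable")
    for _, r in rows.iterrows():
        g.add_node(r["lncrna_id"], rna_class="lncRNA")
        g.add_node(r["mirna_id"], rna_class="miRNA")
        g.add_node(r["mrna_id"], rna_class="mRNA")
        g.add_edge(r["mirna_id"], r["lncrna_id"], rho=float(r["rho_mi_lnc"]))
        g.add_edge(r["mirna_id"], r["mrna_id"], rho=float(r["rho_mi_mrna"]))
        g.add_edge(r["lncrna_id"], r["mrna_id"], rho=float(r["rho_lnc_mrna"]))
    return g


def export_network(triplets: pd.DataFrame, path, fmt: str = "graphml") -> None:
    """Write the triplet network as GraphML or SIF with stable ordering."""
    if triplets.empty:
        raise ValueError("cannot export an empty network")
    g = triplet_network(triplets)
    if fmt == "graphml":
        # rebuild with sorted nodes/edges for a bit-stable file
        h = nx.Graph()
        for node in sorted(g.nodes):
            h.add_node(node, **g.nodes[node])
        for u, v in sorted(tuple(sorted(e)) for e in g.edges):
            h.add_edge(u, v, **g.edges[u, v])
        nx.write_graphml(h, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v in sorted(tuple(sorted(e)) for e in g.edges):
                cu = g.nodes[u]["rna_class"]
                cv = g.nodes[v]["rna_class"]
                rel = "-".join(sorted((cu, cv)))
                fh.write(f"{u}\t{rel}\t{v}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}; supported: graphml, sif")
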