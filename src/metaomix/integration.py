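"""Direction-aware integration of the four omics layers.

For each deregulated gene the layers are interrogated for a consistent
explanation: a recurrent copy-number change in the matching direction
(gain <-> up, loss <-> down), at least one significant direction-consistent
methylation probe (hypo <-> up, hyper <-> down) in the configured gene region,
and a differentially expressed miRNA targeting the gene. miRNA links are
labelled ``repression`` when the directions are opposite (canonical miRNA
action) and ``counter_regulation`` when they agree — a compensatory reading in
which the cell raises a miRNA against an over-expressed target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .differential import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class OverlapReport:
    """Venn-style intersections of the DEG set with the explaining layers."""

    deg: set[str]
    deg_cnv: set[str]
    deg_meth: set[str]
    deg_mirna: set[str]
    four_way: set[str] = field(default_factory=set)
    combined_without_mirna: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.four_way = self.deg_cnv & self.deg_meth & self.deg_mirna
        self.combined_without_mirna = self.deg_cnv & self.deg_meth

    def sizes(self) -> dict[str, int]:
        return {
            "deg": len(self.deg),
            "deg_cnv": len(self.deg_cnv),
            "deg_meth": len(self.deg_meth),
            "deg_mirna": len(self.deg_mirna),
            "four_way": len(self.four_way),
            "combined_without_mirna": len(self.combined_without_mirna),
        }

    def to_dict(self) -> dict:
        return {
            "sizes": self.sizes(),
            "members": {
                "deg_cnv": sorted(self.deg_cnv),
                "deg_meth": sorted(self.deg_meth),
                "deg_mirna": sorted(self.deg_mirna),
                "four_way": sorted(self.four_way),
                "combined_without_mirna": sorted(self.combined_without_mirna),
            },
        }


def valid_target_filter(
    mirna_de: pd.DataFrame,
    target_map: list[tuple[str, str]],
    mrna_de: pd.DataFrame,
) -> pd.DataFrame:
    """Keep miRNA-target pairs where both partners are differentially
    expressed, labelling each ``repression`` (opposite directions) or
    ``counter_regulation`` (same direction)."""
    sig_mir = mirna_de[mirna_de["significant"]]
    sig_gene = mrna_de[mrna_de["significant"]]
    rows = []
    for mirna, gene in target_map:
        if mirna not in sig_mir.index or gene not in sig_gene.index:
            continue
        m_lfc = float(sig_mir.loc[mirna, "logFC"])
        g_lfc = float(sig_gene.loc[gene, "logFC"])
        consistency = "repression" if m_lfc * g_lfc < 0 else "counter_regulation"
        rows.append((mirna, gene, m_lfc, g_lfc, consistency))
    return pd.DataFrame(
        rows, columns=["mirna", "gene", "mirna_logFC", "gene_logFC", "consistency"]
    )


def attribute_deg_sources(
    deg: pd.DataFrame,
    cnv_gain: set[str],
    cnv_loss: set[str],
    dm_probes: pd.DataFrame | None = None,
    mirna_pairs: pd.DataFrame | None = None,
    mirna_policy: str = "opposite",
    meth_regions: tuple[str, ...] | None = ("promoter",),
) -> pd.DataFrame:
    """Per-DEG source attribution with direction-consistency rules.

    ``deg`` is a differential-expression table (only rows flagged significant
    are attributed). ``dm_probes`` is a probe-level table with columns
    gene_id, region, direction, significant. ``mirna_pairs`` is the output of
    :func:`valid_target_filter`. ``mirna_policy`` 'opposite' accepts only
    repression links; 'any' also accepts counter-regulation.
    """
    if mirna_policy not in {"opposite", "any"}:
        raise ValueError(f"unknown mirna_policy {mirna_policy!r}")
    degs = deg[deg["significant"]]
    deg_dir = {g: ("up" if lfc > 0 else "down") for g, lfc in degs["logFC"].items()}

    meth_by_gene: dict[str, list[tuple[str, str]]] = {}
    if dm_probes is not None and not dm_probes.empty:
        sig = dm_probes[dm_probes["significant"]]
        unknown = set(sig["gene_id"]) - set(deg.index)
        if unknown:
            logger.warning("attribution: %d methylation genes not in the DEG table",
                           len(unknown))
        for probe, row in sig.iterrows():
            if meth_regions is not None and row.get("region") not in meth_regions:
                continue
            meth_by_gene.setdefault(str(row["gene_id"]), []).append(
                (str(probe), str(row["direction"]))
            )

    links_by_gene: dict[str, list[tuple[str, str, str]]] = {}
    if mirna_pairs is not None and not mirna_pairs.empty:
        for _, row in mirna_pairs.iterrows():
            mdir = "up" if row["mirna_logFC"] > 0 else "down"
            links_by_gene.setdefault(str(row["gene"]), []).append(
                (str(row["mirna"]), mdir, str(row["consistency"]))
            )

    rows = []
    for gene, direction in deg_dir.items():
        wanted_cnv = "gain" if direction == "up" else "loss"
        in_gain, in_loss = gene in cnv_gain, gene in cnv_loss
        cnv_dir = "gain" if in_gain else ("loss" if in_loss else "")
        cnv_explained = (wanted_cnv == "gain" and in_gain) or (
            wanted_cnv == "loss" and in_loss
        )

        wanted_meth = "hypo" if direction == "up" else "hyper"
        consistent_probes = [
            p for p, mdir in meth_by_gene.get(gene, []) if mdir == wanted_meth
        ]
        meth_explained = len(consistent_probes) > 0

        links = links_by_gene.get(gene, [])
        if mirna_policy == "opposite":
            links = [lk for lk in links if lk[2] == "repression"]
        mirna_linked = len(links) > 0

        rows.append({
            "gene_id": gene,
            "deg_direction": direction,
            "cnv_explained": cnv_explained,
            "cnv_direction": cnv_dir,
            "meth_explained": meth_explained,
            "meth_direction": wanted_meth if meth_explained else "",
            "meth_probe_count": len(consistent_probes),
            "mirna_linked": mirna_linked,
            "mirna_links": links,
        })
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "deg_direction", "cnv_explained", "cnv_direction",
                 "meth_explained", "meth_direction", "meth_probe_count",
                 "mirna_linked", "mirna_links"],
    )
    return out.set_index("gene_id")


def multiway_overlap(attributions: pd.DataFrame) -> OverlapReport:
    """Intersections of the DEG set with its CNV / methylation / miRNA
    explanations, including the four-way overlap and the combined set that
    ignores the miRNA layer."""
    deg = set(attributions.index)
    return OverlapReport(
        deg=deg,
        deg_cnv={g for g in deg if attributions.loc[g, "cnv_explained"]},
        deg_meth={g for g in deg if attributions.loc[g, "meth_explained"]},
        deg_mirna={g for g in deg if attributions.loc[g, "mirna_linked"]},
    )


def ora_hypergeometric(
    gene_list: list[str] | set[str],
    universe: list[str] | set[str],
    gene_sets: dict[str, list[str]],
) -> pd.DataFrame:
    """Over-representation of ``gene_list`` in each gene set by the upper-tail
    hypergeometric test P(X >= k), BH-adjusted across sets.

    Sets are intersected with the universe first; sets disjoint from it are
    skipped with a warning. The gene list must be a subset of the universe.
    """
    uni = set(universe)
    lst = set(gene_list)
    offenders = lst - uni
    if offenders:
        raise ValueError(f"gene list not in universe: {sorted(offenders)[:5]}")
    n_universe = len(uni)
    n_list = len(lst)
    rows = []
    for name, members in gene_sets.items():
        in_uni = set(members) & uni
        if not in_uni:
            logger.warning("ORA: set %r disjoint from universe, skipped", name)
            continue
        k = len(lst & in_uni)
        big_k = len(in_uni)
        p = float(hypergeom.sf(k - 1, n_universe, big_k, n_list))
        rows.append((name, k, big_k, n_list, n_universe, min(p, 1.0)))
    df = pd.DataFrame(
        rows, columns=["set_name", "overlap", "set_size", "list_size",
                       "universe_size", "p_value"]
    )
    if not df.empty:
        df["fdr"] = bh_adjust(df["p_value"].to_numpy())
    else:
        df["fdr"] = []
    return df.set_index("set_name")
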