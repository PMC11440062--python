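"""Kinase-substrate annotation and enrichment.

Sites are joined against a kinase-substrate (KS) table on the substrate
identifier plus the site string (residue + 1-based position, e.g. ``S473``).
The join yields three tables in the network idiom: the annotated pair table,
a node table (kinases and substrates with role labels) and an edge table
(kinase -> substrate-site links).  Kinase enrichment in a foreground site
set against a background universe uses Fisher's exact test with
Benjamini-Hochberg correction across kinases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .crossmap import MappedSite
from .prealign import SiteRecord

logger = logging.getLogger("phosmap")

__all__ = [
    "KSRecord",
    "read_ks_table",
    "annotate_ks",
    "kinase_enrichment_test",
]


@dataclass(frozen=True)
class KSRecord:
    """One kinase-substrate-site annotation row."""

    kinase_gene: str
    substrate_gene: str
    site: str  # e.g. "S473"
    substrate_accession: str = ""
    species: str = ""

    @property
    def residue(self) -> str:
        return self.site[0]

    @property
    def position(self) -> int:
        return int(self.site[1:])


def read_ks_table(path: str | Path) -> list[KSRecord]:
    """Read a KS TSV with columns kinase, substrate_gene, substrate_accession,
    site, species (the last two optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"kinase", "substrate_gene", "site"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"KS table missing columns: {sorted(missing)}")
    return [
        KSRecord(
            kinase_gene=r.kinase,
            substrate_gene=r.substrate_gene,
            site=r.site,
            substrate_accession=getattr(r, "substrate_accession", ""),
            species=getattr(r, "species", ""),
        )
        for r in df.itertuples(index=False)
    ]


def _site_keys(site: SiteRecord | MappedSite) -> tuple[str, str, str]:
    """(accession, site string, window) for the join."""
    if isinstance(site, MappedSite):
        src = site.source
        if site.target_position is not None:
            return (
                site.target_accession or "",
                f"{site.target_residue}{site.target_position}",
                site.target_window or "",
            )
        return (src.protein_accession, f"{src.residue}{src.position}", src.window)
    return (site.protein_accession, f"{site.residue}{site.position}", site.window)


def annotate_ks(
    sites: Sequence[SiteRecord | MappedSite],
    ks_table: Sequence[KSRecord],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Join sites against the KS table; returns (pairs, nodes, edges).

    The join key is the substrate accession when both sides carry one,
    otherwise the gene symbol (case-insensitive), always together with the
    site string.  Duplicated annotations collapse to one row.
    """
    if not ks_table:
        raise ValueError("empty kinase-substrate table")
    pair_rows = []
    for site in sites:
        acc, site_str, window = _site_keys(site)
        for ks in ks_table:
            key_matches = (
                (ks.substrate_accession and acc and ks.substrate_accession == acc)
                or (not ks.substrate_accession and ks.substrate_gene.upper() == acc.upper())
                or ks.substrate_gene.upper() == acc.upper()
            )
            if key_matches and ks.site == site_str:
                pair_rows.append(
                    {
                        "kinase": ks.kinase_gene,
                        "substrate": ks.substrate_gene or acc,
                        "substrate_accession": ks.substrate_accession or acc,
                        "site": site_str,
                        "window": window,
                    }
                )
    pairs = pd.DataFrame(
        pair_rows, columns=["kinase", "substrate", "substrate_accession", "site", "window"]
    ).drop_duplicates(subset=["kinase", "substrate_accession", "site"], ignore_index=True)

    node_rows = []
    for k in pairs["kinase"].unique():
        node_rows.append({"node": k, "role": "kinase"})
    for s in pairs["substrate"].unique():
        node_rows.append({"node": s, "role": "substrate"})
    nodes = pd.DataFrame(node_rows, columns=["node", "role"]).drop_duplicates(
        ignore_index=True
    )
    edges = pairs[["kinase", "substrate", "site"]].copy()
    edges.columns = ["source", "target", "site"]
    return pairs, nodes, edges


def _substrate_site_index(ks_table: Sequence[KSRecord]) -> dict[str, set[tuple[str, str]]]:
    """kinase -> set of (substrate key uppercased, site)."""
    idx: dict[str, set[tuple[str, str]]] = {}
    for ks in ks_table:
        for key in filter(None, {ks.substrate_accession, ks.substrate_gene.upper()}):
            idx.setdefault(ks.kinase_gene, set()).add((key.upper(), ks.site))
    return idx


def kinase_enrichment_test(
    foreground: Sequence[SiteRecord | MappedSite],
    background: Sequence[SiteRecord | MappedSite],
    ks_table: Sequence[KSRecord],
    alternative: str = "two-sided",
    annotated_only: bool = False,
) -> pd.DataFrame:
    """Fisher's exact test per kinase for substrate enrichment.

    For each kinase with at least one annotated substrate site in the
    background, the 2x2 table is (a) foreground substrate sites, (b) other
    foreground sites, (c) background-only substrate sites, (d) remaining
    background-only sites; the background universe is all input sites by
    default (``annotated_only=True`` restricts it to sites carrying any KS
    annotation).  P-values are BH-adjusted across all tested kinases and
    rows are sorted by adjusted p.
    """
    fg_keys = {(acc.upper(), s) for acc, s, _ in map(_site_keys, foreground)}
    bg_keys = {(acc.upper(), s) for acc, s, _ in map(_site_keys, background)}
    if not bg_keys:
        raise ValueError("empty background")
    if not fg_keys <= bg_keys:
        raise ValueError("foreground sites must be a subset of the background")
    idx = _substrate_site_index(ks_table)
    if annotated_only:
        annotated = set().union(*idx.values())
        bg_keys = {k for k in bg_keys if k in annotated}
        fg_keys = {k for k in fg_keys if k in annotated}
    n_fg = len(fg_keys)
    n_bg_only = len(bg_keys) - n_fg
    rows = []
    for kinase in sorted(idx):
        subs = idx[kinase]
        a = sum(1 for k in fg_keys if k in subs)
        c = sum(1 for k in bg_keys - fg_keys if k in subs)
        if a + c == 0:
            continue
        b = n_fg - a
        d = n_bg_only - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        rows.append(
            {"kinase": kinase, "a": a, "b": b, "c": c, "d": d,
             "odds_ratio": odds, "p": p}
        )
    if not rows:
        return pd.DataFrame(
            columns=["kinase", "a", "b", "c", "d", "odds_ratio", "p", "adj_p"]
        )
    df = pd.DataFrame(rows)
    df["adj_p"] = multipletests(df["p"], method="fdr_bh")[1]
    return df.sort_values("adj_p", kind="stable", ignore_index=True)
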