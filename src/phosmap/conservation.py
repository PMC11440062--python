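"""Conservation analysis across many species.

A multi-species mapping run yields one 0/1 *presence matrix*: rows are
reference sites, columns species, and an entry is 1 when the site mapped
into that species and passed the similarity filters.  Row sums (the number
of species carrying a site) feed an equal-frequency segmentation into
conservation bins Q1 (least conserved) .. Qk (most conserved, k = 5 by
default), per-segment feature enrichment uses Fisher's exact test with BH
correction, and species relationships are summarised as an agglomerative
clustering tree over the presence columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .crossmap import MappedSite

logger = logging.getLogger("phosmap")

__all__ = [
    "build_presence_matrix",
    "segment_by_conservation",
    "segment_enrichment",
    "cluster_species_tree",
]


def build_presence_matrix(
    mapped_runs: Mapping[str, Sequence[MappedSite]],
    include_residue_type: bool = True,
) -> pd.DataFrame:
    """Assemble a site x species 0/1 matrix from per-species mapping runs.

    ``mapped_runs`` maps species name -> list of MappedSite sharing one
    reference site universe (the MappedSite sources).  The returned frame is
    indexed by reference site id with one integer column per species plus,
    optionally, a ``residue_type`` column (pS/pT/pY) from the reference
    central residue.  Conflicting duplicate (site, species) flags raise.
    """
    if not mapped_runs:
        raise ValueError("no mapping runs given")
    universe: dict[str, str] = {}  # site_id -> residue
    flags: dict[str, dict[str, int]] = {}
    for species, run in mapped_runs.items():
        for m in run:
            sid = m.source.site_id
            universe.setdefault(sid, m.source.residue)
            val = int(m.passed_filters)
            prev = flags.setdefault(sid, {}).get(species)
            if prev is not None and prev != val:
                raise ValueError(
                    f"conflicting presence flags for site {sid} in {species}"
                )
            flags[sid][species] = val
    species_names = list(mapped_runs)
    site_ids = sorted(universe)
    data = {
        sp: [flags[sid].get(sp, 0) for sid in site_ids] for sp in species_names
    }
    df = pd.DataFrame(data, index=pd.Index(site_ids, name="site_id"), dtype=int)
    if include_residue_type:
        df.insert(0, "residue_type", ["p" + universe[sid] for sid in site_ids])
    return df


def _presence_values(matrix: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in matrix.columns if c != "residue_type"]
    return matrix[cols]


def segment_by_conservation(
    species_counts: Mapping[str, int] | pd.Series,
    k: int = 5,
) -> pd.DataFrame:
    """Equal-frequency binning of sites by species count into Q1..Qk.

    Sites with the same species count never split across segments: the
    distinct counts are walked in ascending order and each segment boundary
    is placed where the cumulative number of sites is nearest to ``j/k`` of
    the total.  Q1 holds the least conserved sites, Qk the most conserved.
    """
    counts = pd.Series(dict(species_counts)) if not isinstance(
        species_counts, pd.Series
    ) else species_counts.copy()
    if (counts < 1).any():
        raise ValueError("species counts must be >= 1")
    if k < 2:
        raise ValueError("need at least 2 segments")
    distinct = np.sort(counts.unique())
    if k > len(distinct):
        raise ValueError(
            f"k={k} exceeds the {len(distinct)} distinct species counts; "
            "choose a smaller k"
        )
    total = len(counts)
    sizes = counts.value_counts().reindex(distinct).to_numpy()
    cum = np.cumsum(sizes)
    boundaries: list[int] = []  # index into `distinct`: last value of segment
    prev = -1
    for j in range(1, k):
        target = j * total / k
        lo = prev + 1
        hi = len(distinct) - (k - j)  # leave room for remaining segments
        cand = range(lo, hi + 1)
        best = min(cand, key=lambda i: (abs(cum[i] - target), i))
        boundaries.append(best)
        prev = best
    boundaries.append(len(distinct) - 1)
    seg_of_value: dict[int, str] = {}
    lo = 0
    for seg_idx, b in enumerate(boundaries, start=1):
        for v in distinct[lo: b + 1]:
            seg_of_value[int(v)] = f"Q{seg_idx}"
        lo = b + 1
    return pd.DataFrame(
        {
            "site_id": counts.index,
            "species_count": counts.to_numpy(),
            "segment": [seg_of_value[int(c)] for c in counts],
        }
    )


def segment_enrichment(
    assignments: pd.DataFrame,
    feature_sets: Mapping[str, set[str]],
    alpha: float = 0.01,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Per (feature, segment) enrichment of feature sites among segments.

    For each feature x segment 2x2 table: sites in both, the segment's other
    sites, the feature's other sites, and the rest.  ``ratio`` is the
    feature share within the segment over the feature share overall (log2
    reported alongside); Fisher p-values are BH-adjusted across every
    (feature, segment) test and flagged at ``adj_p < alpha``.
    """
    all_sites = set(assignments["site_id"])
    seg_of = dict(zip(assignments["site_id"], assignments["segment"]))
    segments = sorted(assignments["segment"].unique())
    n_total = len(all_sites)
    rows = []
    for feature, sites in feature_sets.items():
        if not sites:
            logger.warning("feature %s has an empty site set; skipped", feature)
            continue
        if not sites <= all_sites:
            raise ValueError(f"feature {feature!r} has sites outside the assignment")
        share_overall = len(sites) / n_total
        for seg in segments:
            seg_sites = {s for s in all_sites if seg_of[s] == seg}
            a = len(sites & seg_sites)
            b = len(seg_sites) - a
            c = len(sites) - a
            d = n_total - a - b - c
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
            ratio = (a / len(seg_sites)) / share_overall
            rows.append(
                {
                    "feature": feature,
                    "segment": seg,
                    "a": a, "b": b, "c": c, "d": d,
                    "ratio": ratio,
                    "log2_ratio": np.log2(ratio) if ratio > 0 else -np.inf,
                    "p": p,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["feature", "segment", "a", "b", "c", "d", "ratio",
                     "log2_ratio", "p", "adj_p", "significant"]
        )
    df = pd.DataFrame(rows)
    df["adj_p"] = multipletests(df["p"], method="fdr_bh")[1]
    df["significant"] = df["adj_p"] < alpha
    return df


def _linkage_to_newick(link: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(link)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left = walk(node.left)
        right = walk(node.right)
        bl_left = node.dist - node.left.dist
        bl_right = node.dist - node.right.dist
        return f"({left}:{bl_left:.6g},{right}:{bl_right:.6g})"

    return walk(tree) + ";"


def cluster_species_tree(
    matrix: pd.DataFrame,
    distance: str = "jaccard",
    linkage: str = "average",
) -> str:
    """Agglomerative clustering of species presence columns, as newick.

    Distances: ``jaccard`` (default; undefined and an error for an all-zero
    species column) or ``simple-matching`` (Hamming fraction).  Linkage:
    ``average`` or ``complete``.  Branch lengths are merge-height
    differences; input columns are sorted by species name first so ties in
    the linkage break deterministically.
    """
    values = _presence_values(matrix)
    if values.shape[1] < 3:
        raise ValueError("need at least 3 species columns")
    values = values.reindex(sorted(values.columns), axis=1)
    X = values.to_numpy().T.astype(bool)
    if distance == "jaccard":
        if (~X).all(axis=1).any():
            bad = [c for c, col in zip(values.columns, X) if not col.any()]
            raise ValueError(
                f"all-zero species column(s) {bad} make the Jaccard distance undefined"
            )
        D = pdist(X, metric="jaccard")
    elif distance == "simple-matching":
        D = pdist(X, metric="hamming")
    else:
        raise ValueError(f"unknown distance {distance!r}")
    if linkage not in {"average", "complete"}:
        raise ValueError(f"unknown linkage {linkage!r}")
    link = hierarchy.linkage(D, method=linkage)
    return _linkage_to_newick(link, list(values.columns))
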