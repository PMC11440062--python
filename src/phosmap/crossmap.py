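"""Cross-species mapping of PTM sites.

The pipeline pairs each query protein with its best hit in the reference
proteome, aligns the pair globally, transfers the site coordinate through the
alignment, extracts the reference window, and scores the window pair with two
complementary scores:

* the **window similarity** WS — the count of positionally identical
  characters between the two fixed-width windows (an integer in
  ``0..w.width``); and
* a **BLOSUM50 alignment score** of the de-padded windows, which credits
  conservative substitutions.

Best hits are ranked by a simplified database E-value

    E = m * n * 2**(-S)

with ``m`` the query length, ``n`` the summed database length and ``S`` the
bit score; ties go to the larger matching percentage, then the longer
alignment, then the lexicographically smaller subject accession.

Central residues across species are classified into the five phospho match
classes S<>S, T<>T, Y<>Y, S<>T and S/T<>Y (anything else is "other"), and the
class requirement, WS threshold and BLOSUM50 threshold are independent
filters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from ._alphabet import PAD, UNKNOWN
from .io import ProteinRecord
from .prealign import DEFAULT_HALFWIDTH, SiteRecord, extract_window

logger = logging.getLogger("phosmap")

__all__ = [
    "BlastHit",
    "AlignmentResult",
    "MappedSite",
    "CrossmapParams",
    "evalue",
    "bit_score",
    "best_hit",
    "read_blast_tabular",
    "align_pair",
    "transfer_site_position",
    "window_similarity",
    "blosum50_score",
    "classify_central_match",
    "central_match_ok",
    "crossmap_sites",
    "mapped_sites_to_frame",
]

# Karlin-Altschul constants used to convert raw Smith-Waterman scores into
# bit scores (standard ungapped-protein-search values).
KA_LAMBDA = 0.267
KA_K = 0.041


def evalue(m: int, n: int, S: float) -> float:
    """Simplified database-search E-value ``E = m * n * 2**(-S)``.

    ``m`` is the query protein length, ``n`` the total database length (sum
    over all database sequences) and ``S`` the bit score.
    """
    if m < 1 or n < 1:
        raise ValueError("sequence lengths m and n must be >= 1")
    return m * n * 2.0 ** (-S)


def bit_score(raw_score: float, lam: float = KA_LAMBDA, k: float = KA_K) -> float:
    """Convert a raw alignment score to bits: ``(lambda*raw - ln K) / ln 2``."""
    return (lam * raw_score - math.log(k)) / math.log(2.0)


@dataclass(frozen=True)
class BlastHit:
    """A best-hit protein pair with its E-value bookkeeping."""

    query_accession: str
    subject_accession: str
    bit_score: float
    evalue: float
    query_length: int
    database_length: int
    matching_percentage: float  # matched residues / query length, in [0, 1]
    alignment_length: int


@dataclass(frozen=True)
class AlignmentResult:
    """A global pairwise alignment with per-column position bookkeeping.

    ``column_map`` holds one ``(query_position, target_position)`` pair per
    alignment column (1-based; ``None`` marks a gap on that side).
    """

    query_aligned: str
    target_aligned: str
    raw_score: float
    column_map: tuple[tuple[int | None, int | None], ...]

    def target_position_of(self, query_position: int) -> int | None:
        for q, t in self.column_map:
            if q == query_position:
                return t
        raise ValueError(f"query position {query_position} not in alignment")


@dataclass(frozen=True)
class MappedSite:
    """One query site carried across species (or annotated unmapped)."""

    source: SiteRecord
    target_accession: str | None = None
    target_position: int | None = None
    target_residue: str | None = None
    target_window: str | None = None
    ws_score: int | None = None
    blosum50_score: float | None = None
    match_class: str | None = None
    passed_filters: bool = False
    reason: str | None = None  # no_hit | gap_at_site | fails_ws | fails_blosum | central_mismatch


@dataclass
class CrossmapParams:
    """Filter and backend settings for :func:`crossmap_sites`."""

    ws_min: int = 8
    blosum_min: float | None = None
    central_match: str = "phospho"  # exact | phospho | any
    evalue_max: float = 10.0
    halfwidth: int = DEFAULT_HALFWIDTH
    ignore_pads: bool = False
    search_open: float = 11.0
    search_extend: float = 1.0
    global_open: float = 10.0
    global_extend: float = 0.5
    blosum50_open: float = 10.0
    blosum50_extend: float = 4.0


def _local_aligner(params: CrossmapParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -params.search_open
    aligner.extend_gap_score = -params.search_extend
    return aligner


def _global_aligner(params: CrossmapParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -params.global_open
    aligner.extend_gap_score = -params.global_extend
    return aligner


def best_hit(
    query: ProteinRecord,
    database: Sequence[ProteinRecord],
    params: CrossmapParams | None = None,
) -> BlastHit | None:
    """Best database hit for one query protein, or ``None``.

    Each candidate is scored by local (Smith-Waterman) alignment under
    BLOSUM62 with affine gaps; the raw score becomes a bit score via the
    Karlin-Altschul conversion and an E-value via the simplified formula.
    Selection: smallest E-value; ties by largest matching percentage, then
    longest alignment, then lexicographically smallest subject accession.
    Hits with E-value above ``params.evalue_max`` are discarded.
    """
    params = params or CrossmapParams()
    if not database:
        raise ValueError("empty database")
    aligner = _local_aligner(params)
    n_db = sum(len(p.sequence) for p in database)
    m = len(query.sequence)
    candidates: list[BlastHit] = []
    for subject in database:
        alns = aligner.align(query.sequence, subject.sequence)
        if len(alns) == 0:
            continue
        aln = alns[0]
        qa, ta = str(aln[0]), str(aln[1])
        matched = sum(1 for a, b in zip(qa, ta) if a == b and a != "-")
        S = bit_score(aln.score)
        E = evalue(m, n_db, S)
        if E > params.evalue_max:
            continue
        candidates.append(
            BlastHit(
                query_accession=query.accession,
                subject_accession=subject.accession,
                bit_score=S,
                evalue=E,
                query_length=m,
                database_length=n_db,
                matching_percentage=matched / m,
                alignment_length=len(qa),
            )
        )
    if not candidates:
        return None
    return min(
        candidates,
        key=lambda h: (
            h.evalue,
            -h.matching_percentage,
            -h.alignment_length,
            h.subject_accession,
        ),
    )


def read_blast_tabular(
    path: str | Path,
    query_proteome: Sequence[ProteinRecord],
    database_length: int,
) -> dict[str, list[BlastHit]]:
    """Import precomputed hits in 12-column BLAST tabular (outfmt 6) format.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore.  The file's own E-value is discarded and recomputed
    from the bit score with the simplified formula so all emitted hits share
    one E-value definition; the matching percentage is reconstructed as
    ``pident/100 * length / query_length``.
    """
    qlen = {p.accession: len(p.sequence) for p in query_proteome}
    cols = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    df = pd.read_csv(path, sep="\t", names=cols, comment="#")
    hits: dict[str, list[BlastHit]] = {}
    for row in df.itertuples(index=False):
        if row.qseqid not in qlen:
            raise ValueError(f"BLAST hit for unknown query accession {row.qseqid!r}")
        m = qlen[row.qseqid]
        matched = min(1.0, (row.pident / 100.0) * row.length / m)
        hits.setdefault(row.qseqid, []).append(
            BlastHit(
                query_accession=row.qseqid,
                subject_accession=row.sseqid,
                bit_score=float(row.bitscore),
                evalue=evalue(m, database_length, float(row.bitscore)),
                query_length=m,
                database_length=database_length,
                matching_percentage=matched,
                alignment_length=int(row.length),
            )
        )
    return hits


def select_best(hits: Sequence[BlastHit], evalue_max: float = 10.0) -> BlastHit | None:
    """Apply the best-hit selection rule to pre-scored hits."""
    kept = [h for h in hits if h.evalue <= evalue_max]
    if not kept:
        return None
    return min(
        kept,
        key=lambda h: (
            h.evalue,
            -h.matching_percentage,
            -h.alignment_length,
            h.subject_accession,
        ),
    )


def align_pair(
    query_sequence: str,
    target_sequence: str,
    params: CrossmapParams | None = None,
) -> AlignmentResult:
    """Global (Needleman-Wunsch) alignment of a blasted protein pair.

    BLOSUM62 with affine gap penalties (open 10, extend 0.5 by default).
    Ties between equal-scoring alignments are broken by the aligner's
    deterministic enumeration order (the first alignment is always the same
    for the same inputs).
    """
    params = params or CrossmapParams()
    if not query_sequence or not target_sequence:
        raise ValueError("cannot align an empty sequence")
    aligner = _global_aligner(params)
    aln = aligner.align(query_sequence, target_sequence)[0]
    qa, ta = str(aln[0]), str(aln[1])
    column_map: list[tuple[int | None, int | None]] = []
    qi = ti = 0
    for qc, tc in zip(qa, ta):
        qpos = tpos = None
        if qc != "-":
            qi += 1
            qpos = qi
        if tc != "-":
            ti += 1
            tpos = ti
        column_map.append((qpos, tpos))
    return AlignmentResult(
        query_aligned=qa,
        target_aligned=ta,
        raw_score=float(aln.score),
        column_map=tuple(column_map),
    )


def transfer_site_position(alignment: AlignmentResult, query_position: int) -> int | None:
    """Map a 1-based query coordinate through the alignment.

    Returns the target coordinate aligned in the same column, or ``None``
    when the target holds a gap there.
    """
    return alignment.target_position_of(query_position)


def window_similarity(window_a: str, window_b: str, ignore_pads: bool = False) -> int:
    """Count positionally identical characters between two equal-width windows.

    Literal character equality, with two caveats: the unknown residue ``X``
    never matches (not even another ``X``), and with ``ignore_pads=True``
    columns where either window carries the terminus pad ``_`` are excluded
    from the count (by default ``_`` vs ``_`` counts as a match and ``_`` vs
    a residue as a mismatch).
    """
    if len(window_a) != len(window_b):
        raise ValueError(
            f"window lengths differ: {len(window_a)} vs {len(window_b)}"
        )
    ws = 0
    for a, b in zip(window_a, window_b):
        if ignore_pads and (a == PAD or b == PAD):
            continue
        if a == b and a != UNKNOWN:
            ws += 1
    return ws


_BLOSUM50 = None


def blosum50_score(
    window_a: str,
    window_b: str,
    open_penalty: float = 10.0,
    extend_penalty: float = 4.0,
) -> float:
    """BLOSUM50 global-alignment score of two windows after pad stripping."""
    global _BLOSUM50
    a = window_a.replace(PAD, "")
    b = window_b.replace(PAD, "")
    if not a or not b:
        raise ValueError("cannot score an all-pad window")
    if _BLOSUM50 is None:
        _BLOSUM50 = substitution_matrices.load("BLOSUM50")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM50
    aligner.open_gap_score = -open_penalty
    aligner.extend_gap_score = -extend_penalty
    return float(aligner.score(a, b))


def classify_central_match(query_residue: str, target_residue: str) -> str:
    """Five phospho central-match classes; anything else is "other"."""
    q, t = query_residue, target_residue
    if q == t and q in "STY":
        return f"{q}<>{q}"
    if {q, t} == {"S", "T"}:
        return "S<>T"
    if (q in "ST" and t == "Y") or (t in "ST" and q == "Y"):
        return "S/T<>Y"
    if q == t:
        return f"{q}<>{q}"
    return "other"


def central_match_ok(match_class: str, mode: str) -> bool:
    if mode == "any":
        return True
    if mode == "exact":
        return match_class in {"S<>S", "T<>T", "Y<>Y"} or (
            "<>" in match_class and match_class.split("<>")[0] == match_class.split("<>")[1]
        )
    if mode == "phospho":
        return match_class in {"S<>S", "T<>T", "Y<>Y", "S<>T", "S/T<>Y"}
    raise ValueError(f"unknown central_match mode {mode!r}")


def crossmap_sites(
    sites: Sequence[SiteRecord],
    query_proteome: Sequence[ProteinRecord],
    target_proteome: Sequence[ProteinRecord],
    params: CrossmapParams | None = None,
    precomputed_hits: Mapping[str, list[BlastHit]] | None = None,
    target_species: str = "",
) -> tuple[list[MappedSite], dict[str, int]]:
    """Map query-species sites onto the target proteome.

    For each site: best hit -> global alignment -> position transfer ->
    target window -> WS + BLOSUM50 -> central-match class -> filters.  Every
    input site appears exactly once in the output, either mapped or annotated
    with a reason code (``no_hit``, ``gap_at_site``, ``fails_ws``,
    ``fails_blosum``, ``central_mismatch``).  Returns the mapped sites plus a
    summary count per outcome.
    """
    params = params or CrossmapParams()
    query_by_acc = {p.accession: p for p in query_proteome}
    target_by_acc = {p.accession: p for p in target_proteome}
    for s in sites:
        if s.protein_accession not in query_by_acc:
            raise ValueError(
                f"site accession {s.protein_accession!r} not in query proteome"
            )

    hit_cache: dict[str, BlastHit | None] = {}
    aln_cache: dict[tuple[str, str], AlignmentResult] = {}

    def hit_for(acc: str) -> BlastHit | None:
        if acc not in hit_cache:
            if precomputed_hits is not None:
                hit_cache[acc] = select_best(
                    precomputed_hits.get(acc, []), params.evalue_max
                )
            else:
                hit_cache[acc] = best_hit(
                    query_by_acc[acc], list(target_proteome), params
                )
        return hit_cache[acc]

    def alignment_for(qacc: str, tacc: str) -> AlignmentResult:
        key = (qacc, tacc)
        if key not in aln_cache:
            aln_cache[key] = align_pair(
                query_by_acc[qacc].sequence, target_by_acc[tacc].sequence, params
            )
        return aln_cache[key]

    out: list[MappedSite] = []
    summary: dict[str, int] = {
        "mapped": 0, "no_hit": 0, "gap_at_site": 0,
        "fails_ws": 0, "fails_blosum": 0, "central_mismatch": 0,
    }
    for site in sites:
        hit = hit_for(site.protein_accession)
        if hit is None:
            out.append(MappedSite(source=site, reason="no_hit"))
            summary["no_hit"] += 1
            continue
        tacc = hit.subject_accession
        if tacc not in target_by_acc:
            raise ValueError(f"hit subject {tacc!r} not in target proteome")
        aln = alignment_for(site.protein_accession, tacc)
        tpos = transfer_site_position(aln, site.position)
        if tpos is None:
            out.append(
                MappedSite(source=site, target_accession=tacc, reason="gap_at_site")
            )
            summary["gap_at_site"] += 1
            continue
        tseq = target_by_acc[tacc].sequence
        twin = extract_window(tseq, tpos, params.halfwidth)
        tres = tseq[tpos - 1]
        ws = window_similarity(site.window, twin, ignore_pads=params.ignore_pads)
        b50 = blosum50_score(
            site.window, twin, params.blosum50_open, params.blosum50_extend
        )
        mclass = classify_central_match(site.residue, tres)
        reason = None
        if ws < params.ws_min:
            reason = "fails_ws"
        elif params.blosum_min is not None and b50 < params.blosum_min:
            reason = "fails_blosum"
        elif not central_match_ok(mclass, params.central_match):
            reason = "central_mismatch"
        passed = reason is None
        out.append(
            MappedSite(
                source=site,
                target_accession=tacc,
                target_position=tpos,
                target_residue=tres,
                target_window=twin,
                ws_score=ws,
                blosum50_score=b50,
                match_class=mclass,
                passed_filters=passed,
                reason=reason,
            )
        )
        summary["mapped" if passed else reason] += 1
    return out, summary


def mapped_sites_to_frame(mapped: Sequence[MappedSite]) -> pd.DataFrame:
    """Tabulate mapped sites (all scores and reason codes) for TSV export."""
    return pd.DataFrame(
        {
            "accession": [m.source.protein_accession for m in mapped],
            "position": [m.source.position for m in mapped],
            "residue": [m.source.residue for m in mapped],
            "window": [m.source.window for m in mapped],
            "target_accession": [m.target_accession for m in mapped],
            "target_position": [m.target_position for m in mapped],
            "target_residue": [m.target_residue for m in mapped],
            "target_window": [m.target_window for m in mapped],
            "ws_score": [m.ws_score for m in mapped],
            "blosum50_score": [m.blosum50_score for m in mapped],
            "match_class": [m.match_class for m in mapped],
            "passed_filters": [m.passed_filters for m in mapped],
            "reason": [m.reason for m in mapped],
        }
    )
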