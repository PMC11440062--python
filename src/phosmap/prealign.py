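"""Peptide-to-protein localization and fixed-width sequence windows.

A *sequence window* is the fixed-width neighbourhood of a modification site:
the central residue plus ``halfwidth`` flanking residues on each side
(default 7, i.e. a 15-mer), padded with ``_`` where the window overhangs a
protein terminus.  Windows are the unit of all downstream similarity scoring
and motif work.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._alphabet import PAD, PHOSPHO_RESIDUES
from .io import ModifiedPeptide, ProteinRecord

logger = logging.getLogger("phosmap")

DEFAULT_HALFWIDTH = 7

__all__ = [
    "SiteRecord",
    "DEFAULT_HALFWIDTH",
    "extract_window",
    "locate_peptides",
    "retrieve_motif_windows",
    "motif_pattern_to_regex",
    "sites_to_frame",
]


@dataclass(frozen=True)
class SiteRecord:
    """A localized PTM site with its protein coordinate and sequence window."""

    protein_accession: str
    position: int  # 1-based residue index within the protein
    residue: str
    window: str
    localization_prob: float | None = None
    species: str = ""
    mod_type: str = "phospho"
    ambiguous_within_protein: bool = False

    @property
    def site_id(self) -> str:
        return f"{self.protein_accession}_{self.residue}{self.position}"

    def __post_init__(self) -> None:
        half = (len(self.window) - 1) // 2
        if len(self.window) != 2 * half + 1:
            raise ValueError("window length must be odd")
        if self.window[half] != self.residue:
            raise ValueError(
                f"window centre {self.window[half]!r} disagrees with residue "
                f"{self.residue!r} for {self.protein_accession} {self.position}"
            )


def extract_window(protein_sequence: str, position: int, halfwidth: int = DEFAULT_HALFWIDTH) -> str:
    """Return the ``2*halfwidth + 1`` window centred on ``position`` (1-based).

    Residues beyond either terminus are padded with ``_`` so the centre always
    sits at index ``halfwidth``.
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    n = len(protein_sequence)
    if not 1 <= position <= n:
        raise ValueError(f"position {position} out of range 1..{n}")
    i = position - 1
    left = protein_sequence[max(0, i - halfwidth): i]
    right = protein_sequence[i + 1: i + 1 + halfwidth]
    return (
        PAD * (halfwidth - len(left))
        + left
        + protein_sequence[i]
        + right
        + PAD * (halfwidth - len(right))
    )


def locate_peptides(
    peptides: Sequence[ModifiedPeptide],
    proteome: Sequence[ProteinRecord],
    halfwidth: int = DEFAULT_HALFWIDTH,
    species: str = "",
    min_loc_prob: float | None = None,
) -> tuple[list[SiteRecord], list[ModifiedPeptide]]:
    """Find every exact occurrence of each stripped peptide in the proteome.

    Each occurrence yields one :class:`SiteRecord` per modification position;
    peptides shared by several proteins produce one record per harbouring
    protein, and multiple occurrences within one protein are all reported and
    flagged ``ambiguous_within_protein``.  Returns ``(sites, unlocated)``
    where ``unlocated`` lists peptides found nowhere (warned, not an error).
    """
    if not proteome:
        raise ValueError("proteome is empty")
    sites: list[SiteRecord] = []
    unlocated: list[ModifiedPeptide] = []
    for pep in peptides:
        if (
            min_loc_prob is not None
            and pep.localization_prob is not None
            and pep.localization_prob < min_loc_prob
        ):
            continue
        hits: list[tuple[ProteinRecord, int]] = []  # (protein, 0-based start)
        for prot in proteome:
            start = prot.sequence.find(pep.stripped_sequence)
            starts: list[int] = []
            while start != -1:
                starts.append(start)
                start = prot.sequence.find(pep.stripped_sequence, start + 1)
            hits.extend((prot, s) for s in starts)
        if not hits:
            logger.warning("peptide %r not found in proteome", pep.stripped_sequence)
            unlocated.append(pep)
            continue
        multi_in_protein = {
            acc for acc in {p.accession for p, _ in hits}
            if sum(1 for p, _ in hits if p.accession == acc) > 1
        }
        for prot, start in hits:
            for pep_pos, residue in zip(pep.mod_positions, pep.mod_residues):
                prot_pos = start + pep_pos  # 1-based protein coordinate
                sites.append(
                    SiteRecord(
                        protein_accession=prot.accession,
                        position=prot_pos,
                        residue=residue,
                        window=extract_window(prot.sequence, prot_pos, halfwidth),
                        localization_prob=pep.localization_prob,
                        species=species,
                        mod_type=pep.mod_type,
                        ambiguous_within_protein=prot.accession in multi_in_protein,
                    )
                )
    return sites, unlocated


# -- motif pattern retrieval --------------------------------------------------

# Bulky hydrophobic class used in kinase-motif notation.
PHI_CLASS = "FLIVM"

_MODIFIABLE = PHOSPHO_RESIDUES


def motif_pattern_to_regex(pattern: str, halfwidth: int = DEFAULT_HALFWIDTH) -> re.Pattern:
    """Compile dash-separated motif notation into an anchored window regex.

    Tokens: a residue letter; ``x`` (any residue, not padding); ``A/B``
    alternatives; the Greek ``ϕ`` (or ``phi``) for the bulky-hydrophobic
    class F/L/I/V/M.  The token whose residue class consists of modifiable
    residues (S/T/Y) and sits rightmost-of-centre ... more precisely, the
    *last* token containing only modifiable residues is taken as the central
    anchor; the compiled regex matches a full window iff the motif aligns
    with that token on the window centre.  Raw regular expressions (any
    string containing regex metacharacters other than ``/``) are anchored on
    a central S/T/Y group if they contain the marker ``(?P<c>...)``,
    otherwise rejected for anchored mode.
    """
    tokens = pattern.split("-")
    if len(tokens) < 1:
        raise ValueError("empty motif pattern")
    classes: list[str] = []
    for tok in tokens:
        tok = tok.strip()
        if not tok:
            raise ValueError(f"empty token in motif pattern {pattern!r}")
        if tok.lower() == "x":
            classes.append("")  # wildcard over residues (never padding)
        else:
            residues = []
            for alt in tok.split("/"):
                alt = alt.strip()
                if alt in ("ϕ", "phi", "Φ"):
                    residues.extend(PHI_CLASS)
                elif len(alt) == 1 and alt.isalpha():
                    residues.append(alt.upper())
                else:
                    raise ValueError(f"invalid motif token {tok!r} in {pattern!r}")
            classes.append("".join(residues))
    # central anchor: the last token made purely of modifiable residues
    anchor = None
    for i, cls in enumerate(classes):
        if cls and set(cls) <= _MODIFIABLE:
            anchor = i
    if anchor is None:
        raise ValueError(
            f"motif pattern {pattern!r} has no central modifiable (S/T/Y) token"
        )
    width = 2 * halfwidth + 1
    left_pad = halfwidth - anchor
    right_pad = width - left_pad - len(classes)
    if left_pad < 0 or right_pad < 0:
        raise ValueError(
            f"motif pattern {pattern!r} does not fit a width-{width} window"
        )
    aa_any = "[A-Z]"  # any residue; '_' padding never matches a residue class
    parts = [f"[{PAD}A-Z]" * 0]
    # positions outside the motif may be residues or padding
    parts.append(f"[{PAD}A-Z]{{{left_pad}}}" if left_pad else "")
    for cls in classes:
        parts.append(aa_any if cls == "" else f"[{cls}]")
    parts.append(f"[{PAD}A-Z]{{{right_pad}}}" if right_pad else "")
    return re.compile("^" + "".join(parts) + "$")


def retrieve_motif_windows(
    sites: Iterable[SiteRecord],
    pattern: str,
    halfwidth: int = DEFAULT_HALFWIDTH,
) -> list[SiteRecord]:
    """Return the sites whose windows match ``pattern`` anchored on the centre."""
    rx = motif_pattern_to_regex(pattern, halfwidth=halfwidth)
    return [s for s in sites if rx.match(s.window)]


def sites_to_frame(sites: Sequence[SiteRecord]) -> pd.DataFrame:
    """Tabulate SiteRecords for TSV export."""
    return pd.DataFrame(
        {
            "accession": [s.protein_accession for s in sites],
            "position": [s.position for s in sites],
            "residue": [s.residue for s in sites],
            "window": [s.window for s in sites],
            "localization_prob": [s.localization_prob for s in sites],
            "species": [s.species for s in sites],
            "ambiguous_within_protein": [s.ambiguous_within_protein for s in sites],
        }
    )


def write_sites(sites: Sequence[SiteRecord], path: str | Path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)
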