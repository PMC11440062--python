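"""Reading and writing of protein databases and modified-peptide tables.

Protein databases come and go as FASTA.  Identified modified peptides arrive
in one of three marker dialects:

``plain``
    a ``#`` immediately *after* the modified residue, e.g. ``GIGT#PPNTTPIK``
    (this is also the canonical in-memory representation);
``maxquant``
    a parenthesised lowercase label after the residue, e.g.
    ``GIGT(ph)PPNTTPIK``;
``spectronaut``
    a bracketed description after the residue, e.g.
    ``GIGT[Phospho (STY)]PPNTTPIK``, with optional leading/trailing ``_``.

All dialects are normalised into :class:`ModifiedPeptide`, which records the
stripped sequence plus 1-based modification positions within the peptide.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._alphabet import ALLOWED_SEQUENCE_CHARS, PHOSPHO_RESIDUES

logger = logging.getLogger("phosmap")

__all__ = [
    "ProteinRecord",
    "ModifiedPeptide",
    "read_fasta",
    "write_fasta",
    "parse_modified_peptides",
    "render_peptide",
    "read_peptide_table",
]


@dataclass(frozen=True)
class ProteinRecord:
    """One protein database entry.

    ``sequence`` is an uppercase string over the 20-letter amino-acid
    alphabet; ``X`` is tolerated for unknown residues.
    """

    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.accession!r} has an empty sequence")
        bad = sorted(set(self.sequence) - ALLOWED_SEQUENCE_CHARS)
        if bad:
            raise ValueError(
                f"protein {self.accession!r} contains non-amino-acid "
                f"characters: {''.join(bad)}"
            )


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide string with localised modifications.

    ``mod_positions`` are 1-based indices into ``stripped_sequence``;
    ``mod_residues[i]`` is the residue at ``mod_positions[i]``.
    """

    raw_string: str
    stripped_sequence: str
    mod_positions: tuple[int, ...]
    mod_residues: tuple[str, ...]
    mod_type: str = "phospho"
    protein_hint: str | None = None
    localization_prob: float | None = None

    def __post_init__(self) -> None:
        for pos, res in zip(self.mod_positions, self.mod_residues):
            if not 1 <= pos <= len(self.stripped_sequence):
                raise ValueError(
                    f"modification position {pos} outside peptide "
                    f"{self.stripped_sequence!r}"
                )
            if self.stripped_sequence[pos - 1] != res:
                raise ValueError(
                    f"residue mismatch at position {pos} of "
                    f"{self.stripped_sequence!r}: expected {res!r}"
                )


def _accession_from_header(header: str) -> str:
    """UniProt-style ``db|ACC|NAME`` headers yield ACC; otherwise the first
    whitespace-delimited token."""
    token = header.split()[0]
    parts = token.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1]
    return token


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA database.

    Wrapped sequence lines are concatenated; the accession is extracted from
    the header (``db|ACC|NAME`` yields ``ACC``, otherwise the first token).
    Duplicate accessions, empty files and non-amino-acid characters raise
    ``ValueError``.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = _accession_from_header(rec.description or rec.id)
        if acc in seen:
            raise ValueError(f"duplicate accession in FASTA: {acc!r}")
        seen.add(acc)
        records.append(
            ProteinRecord(
                accession=acc,
                sequence=str(rec.seq).upper(),
                description=rec.description,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write protein records as FASTA (60-column wrapped)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.description or "")
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# -- modified-peptide dialects ------------------------------------------------

_DIALECT_MARKER = {
    # marker regex matching text that FOLLOWS the modified residue
    "plain": re.compile(r"#"),
    "maxquant": re.compile(r"\(([a-z]{1,4})\)"),
    "spectronaut": re.compile(r"\[([^\]]*)\]"),
}


def _strip_decorations(raw: str, dialect: str) -> str:
    s = raw.strip()
    if dialect == "spectronaut":
        s = s.strip("_")
        # charge suffix like ".2" occasionally appended
        s = re.sub(r"\.\d+$", "", s)
    return s


def parse_modified_peptide(
    raw: str,
    dialect: str = "plain",
    mod_type: str = "phospho",
    on_bad_residue: str = "reject",
) -> ModifiedPeptide | None:
    """Parse one peptide string in the given dialect.

    For phospho data a marker attached to a residue outside {S, T, Y} emits a
    warning and, under the default ``on_bad_residue='reject'`` policy, returns
    ``None``; ``'keep'`` retains the site.
    """
    if dialect not in _DIALECT_MARKER:
        raise ValueError(f"unsupported dialect {dialect!r}")
    marker = _DIALECT_MARKER[dialect]
    text = _strip_decorations(raw, dialect)

    stripped_chars: list[str] = []
    positions: list[int] = []
    residues: list[str] = []
    i = 0
    while i < len(text):
        m = marker.match(text, i)
        if m is not None:
            if not stripped_chars:
                raise ValueError(f"modification marker before any residue: {raw!r}")
            positions.append(len(stripped_chars))
            residues.append(stripped_chars[-1])
            i = m.end()
            continue
        ch = text[i]
        if not ch.isalpha():
            raise ValueError(f"unparseable character {ch!r} in peptide {raw!r}")
        stripped_chars.append(ch.upper())
        i += 1

    stripped = "".join(stripped_chars)
    if mod_type == "phospho":
        bad = [(p, r) for p, r in zip(positions, residues) if r not in PHOSPHO_RESIDUES]
        if bad:
            logger.warning(
                "peptide %r carries a phospho marker on non-S/T/Y residue(s) %s",
                raw,
                bad,
            )
            if on_bad_residue == "reject":
                return None
    return ModifiedPeptide(
        raw_string=raw,
        stripped_sequence=stripped,
        mod_positions=tuple(positions),
        mod_residues=tuple(residues),
        mod_type=mod_type,
    )


def parse_modified_peptides(
    rows: Sequence[str],
    dialect: str = "plain",
    mod_type: str = "phospho",
    on_bad_residue: str = "reject",
) -> list[ModifiedPeptide]:
    """Parse a sequence of peptide strings; see :func:`parse_modified_peptide`.

    Raises ``ValueError`` naming the row index for unparseable rows; rejected
    rows (bad phospho residue under the default policy) are dropped with a
    warning.
    """
    if len(rows) == 0:
        raise ValueError("empty peptide table")
    out: list[ModifiedPeptide] = []
    for idx, raw in enumerate(rows):
        try:
            pep = parse_modified_peptide(
                raw, dialect=dialect, mod_type=mod_type, on_bad_residue=on_bad_residue
            )
        except ValueError as exc:
            raise ValueError(f"row {idx}: {exc}") from exc
        if pep is not None:
            out.append(pep)
    return out


def render_peptide(pep: ModifiedPeptide, dialect: str = "plain") -> str:
    """Render a canonical peptide back into a dialect string (round-trip aid)."""
    token = {"plain": "#", "maxquant": "(ph)", "spectronaut": "[Phospho (STY)]"}
    if dialect not in token:
        raise ValueError(f"unsupported dialect {dialect!r}")
    marks = set(pep.mod_positions)
    parts: list[str] = []
    for i, ch in enumerate(pep.stripped_sequence, start=1):
        parts.append(ch)
        if i in marks:
            parts.append(token[dialect])
    return "".join(parts)


def read_peptide_table(
    path: str | Path,
    dialect: str = "plain",
    mod_type: str = "phospho",
    on_bad_residue: str = "reject",
) -> list[ModifiedPeptide]:
    """Read a TSV with required column ``peptide`` and optional columns
    ``protein`` and ``localization_prob``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "peptide" not in df.columns:
        raise ValueError("peptide table must have a 'peptide' column")
    peptides: list[ModifiedPeptide] = []
    for idx, row in df.iterrows():
        pep = parse_modified_peptide(
            row["peptide"], dialect=dialect, mod_type=mod_type,
            on_bad_residue=on_bad_residue,
        )
        if pep is None:
            continue
        hint = row.get("protein")
        prob = row.get("localization_prob")
        peptides.append(
            ModifiedPeptide(
                raw_string=pep.raw_string,
                stripped_sequence=pep.stripped_sequence,
                mod_positions=pep.mod_positions,
                mod_residues=pep.mod_residues,
                mod_type=pep.mod_type,
                protein_hint=None if pd.isna(hint) else str(hint),
                localization_prob=None if pd.isna(prob) else float(prob),
            )
        )
    if not peptides:
        raise ValueError(f"no parseable peptides in {path}")
    return peptides
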