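"""Deterministic synthetic fixtures for the whole pipeline.

The generator emulates the tool's real inputs at desk scale: a query
proteome, an ortholog target proteome derived from it by per-residue
substitution and indels, a modified-peptide table whose peptides are literal
substrings of the query proteins, a toy kinase-substrate table, and a
site x sample intensity matrix with planted group effects and
missing-at-random gaps.  Everything is a pure function of the seed, and a
``truth`` block records what was planted (motif sites, differential sites,
per-site ortholog coordinates) so tests can score recovery.

The quantitative noise model is intentionally plain: per-site log2 baseline
~ Normal(20, 2), per-sample log2 noise sd 0.3, planted log2 effects added to
the second group, missingness completely at random.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._alphabet import AA20
from .io import ModifiedPeptide, ProteinRecord, render_peptide, write_fasta
from .ks import KSRecord
from .prealign import DEFAULT_HALFWIDTH
from .quant import QuantMatrix

__all__ = ["PlantedMotif", "FixtureConfig", "FixtureBundle", "generate_fixture"]


@dataclass(frozen=True)
class PlantedMotif:
    """A degenerate motif to plant around a fraction of sites.

    ``constraints`` are (offset-from-centre, residue) pairs, e.g.
    ``((-3, "R"),)`` for arginine three positions upstream.
    """

    constraints: tuple[tuple[int, str], ...]
    fraction: float
    central_residue: str = "S"


@dataclass(frozen=True)
class FixtureConfig:
    seed: int
    n_proteins: int = 30
    min_length: int = 200
    max_length: int = 400
    substitution_rate: float = 0.05
    indel_rate: float = 0.01
    planted_motifs: tuple[PlantedMotif, ...] = ()
    n_sites: int = 300
    n_samples: int = 8
    n_differential: int = 20
    effect_log2: float = 3.0
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.3
    missing_fraction: float = 0.1
    halfwidth: int = DEFAULT_HALFWIDTH


@dataclass
class FixtureBundle:
    config: FixtureConfig
    query_proteome: list[ProteinRecord]
    target_proteome: list[ProteinRecord]
    peptide_table: list[ModifiedPeptide]
    ks_table: list[KSRecord]
    quant_matrix: QuantMatrix
    truth: dict = field(default_factory=dict)


# residue frequencies for site centres: mostly serine, as in phosphoproteomes
_CENTRE_RESIDUES = ("S", "T", "Y")
_CENTRE_PROBS = (0.75, 0.20, 0.05)


def _validate(config: FixtureConfig) -> None:
    if config.n_proteins < 1:
        raise ValueError("need at least one protein")
    for name in ("substitution_rate", "indel_rate", "missing_fraction"):
        rate = getattr(config, name)
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {rate}")
    if sum(m.fraction for m in config.planted_motifs) > 1.0 + 1e-12:
        raise ValueError("planted motif fractions sum to more than 1")
    if config.min_length < 4 * config.halfwidth + 2:
        raise ValueError("proteins too short for the window halfwidth")


def _mutate_protein(
    sequence: str,
    rng: np.random.Generator,
    substitution_rate: float,
    indel_rate: float,
) -> tuple[str, dict[int, int | None]]:
    """Derive an ortholog by per-residue substitution/indels.

    Returns the new sequence and a map from 1-based query positions to
    1-based target positions (``None`` where the residue was deleted).
    """
    out: list[str] = []
    pos_map: dict[int, int | None] = {}
    p_del = p_ins = indel_rate / 2.0
    for qpos, res in enumerate(sequence, start=1):
        if rng.random() < p_del:
            pos_map[qpos] = None
            continue
        if rng.random() < substitution_rate:
            choices = [a for a in AA20 if a != res]
            res = choices[rng.integers(len(choices))]
        out.append(res)
        pos_map[qpos] = len(out)
        if rng.random() < p_ins:
            out.append(AA20[rng.integers(len(AA20))])
    return "".join(out), pos_map


def generate_fixture(config: FixtureConfig) -> FixtureBundle:
    """Generate the full fixture bundle; byte-identical per seed."""
    _validate(config)
    rng = np.random.default_rng(config.seed)
    half = config.halfwidth
    aa = np.array(list(AA20))

    # 1. query proteome
    query: list[str] = []
    for i in range(config.n_proteins):
        length = int(rng.integers(config.min_length, config.max_length + 1))
        query.append("".join(aa[rng.integers(len(aa), size=length)]))

    # 2. site placement on a non-overlapping grid of windows
    slots: list[tuple[int, int]] = []  # (protein index, 1-based position)
    for pi, seq in enumerate(query):
        pos = half + 1
        while pos + half <= len(seq):
            slots.append((pi, pos))
            pos += 2 * half + 2
    if config.n_sites > len(slots):
        raise ValueError(
            f"n_sites={config.n_sites} exceeds {len(slots)} non-overlapping slots; "
            "use more or longer proteins"
        )
    chosen = rng.choice(len(slots), size=config.n_sites, replace=False)
    chosen.sort()
    site_list = [slots[i] for i in chosen]

    # set central residues
    centres = rng.choice(
        np.array(_CENTRE_RESIDUES), size=config.n_sites, p=np.array(_CENTRE_PROBS)
    )
    mutable = [list(s) for s in query]
    for (pi, pos), res in zip(site_list, centres):
        mutable[pi][pos - 1] = res

    # 3. plant motifs on disjoint site subsets
    motif_truth: list[dict] = []
    available = list(range(config.n_sites))
    for motif in config.planted_motifs:
        n_plant = int(round(motif.fraction * config.n_sites))
        picked_idx = rng.choice(len(available), size=n_plant, replace=False)
        picked = sorted(available[j] for j in picked_idx)
        available = [s for s in available if s not in set(picked)]
        for si in picked:
            pi, pos = site_list[si]
            mutable[pi][pos - 1] = motif.central_residue
            centres[si] = motif.central_residue
            for off, res in motif.constraints:
                mutable[pi][pos - 1 + off] = res
        motif_truth.append(
            {"constraints": motif.constraints, "site_indices": picked}
        )
    query = ["".join(chars) for chars in mutable]
    query_records = [
        ProteinRecord(accession=f"Q{i:03d}", sequence=seq, description=f"query protein {i}")
        for i, seq in enumerate(query)
    ]

    # 4. target proteome by substitution + indels
    target_records: list[ProteinRecord] = []
    pos_maps: list[dict[int, int | None]] = []
    for i, seq in enumerate(query):
        tseq, pmap = _mutate_protein(
            seq, rng, config.substitution_rate, config.indel_rate
        )
        target_records.append(
            ProteinRecord(
                accession=f"T{i:03d}", sequence=tseq, description=f"target ortholog {i}"
            )
        )
        pos_maps.append(pmap)

    # 5. peptide table: literal substrings covering each site
    peptides: list[ModifiedPeptide] = []
    site_ids: list[str] = []
    ortholog_positions: dict[str, tuple[str, int | None]] = {}
    for si, ((pi, pos), res) in enumerate(zip(site_list, centres)):
        seq = query[pi]
        left = int(rng.integers(3, 8))
        right = int(rng.integers(3, 8))
        start = max(0, pos - 1 - left)
        end = min(len(seq), pos + right)
        stripped = seq[start:end]
        pep_pos = pos - start  # 1-based within peptide
        peptides.append(
            ModifiedPeptide(
                raw_string=stripped[:pep_pos] + "#" + stripped[pep_pos:],
                stripped_sequence=stripped,
                mod_positions=(pep_pos,),
                mod_residues=(str(res),),
                protein_hint=f"Q{pi:03d}",
            )
        )
        sid = f"Q{pi:03d}_{res}{pos}"
        site_ids.append(sid)
        ortholog_positions[sid] = (f"T{pi:03d}", pos_maps[pi][pos])

    # 6. kinase-substrate table: random assignments plus one motif-linked kinase
    ks_rows: list[KSRecord] = []
    n_kinases = 5
    for ki in range(n_kinases):
        n_subs = int(rng.integers(10, 30))
        subs = rng.choice(config.n_sites, size=min(n_subs, config.n_sites), replace=False)
        for si in sorted(subs):
            pi, pos = site_list[si]
            ks_rows.append(
                KSRecord(
                    kinase_gene=f"KIN{ki + 1}",
                    substrate_gene=f"Q{pi:03d}",
                    substrate_accession=f"Q{pi:03d}",
                    site=f"{centres[si]}{pos}",
                    species="query",
                )
            )
    if motif_truth:
        for si in motif_truth[0]["site_indices"]:
            pi, pos = site_list[si]
            ks_rows.append(
                KSRecord(
                    kinase_gene="KINM",
                    substrate_gene=f"Q{pi:03d}",
                    substrate_accession=f"Q{pi:03d}",
                    site=f"{centres[si]}{pos}",
                    species="query",
                )
            )

    # 7. quantitative matrix with planted two-group effects
    n_half = config.n_samples // 2
    samples = [f"s{j + 1}" for j in range(config.n_samples)]
    group_labels = ["A"] * n_half + ["B"] * (config.n_samples - n_half)
    baselines = rng.normal(config.baseline_mean, config.baseline_sd, config.n_sites)
    log2_vals = baselines[:, None] + rng.normal(
        0.0, config.noise_sd, (config.n_sites, config.n_samples)
    )
    diff_idx = rng.choice(
        config.n_sites, size=min(config.n_differential, config.n_sites), replace=False
    )
    diff_idx = np.sort(diff_idx)
    signs = rng.choice([-1.0, 1.0], size=len(diff_idx))
    for j, (si, sign) in enumerate(zip(diff_idx, signs)):
        log2_vals[si, n_half:] += sign * config.effect_log2
    raw = np.power(2.0, log2_vals)
    mask = rng.random((config.n_sites, config.n_samples)) < config.missing_fraction
    raw[mask] = np.nan
    quant = QuantMatrix(
        values=pd.DataFrame(raw, index=pd.Index(site_ids, name="site_id"), columns=samples),
        groups=pd.Series(group_labels, index=samples, name="group"),
    )

    truth = {
        "planted_motifs": motif_truth,
        "site_ids": site_ids,
        "site_positions": [(f"Q{pi:03d}", pos) for pi, pos in site_list],
        "ortholog_positions": ortholog_positions,
        "differential_sites": {
            site_ids[si]: float(sign * config.effect_log2)
            for si, sign in zip(diff_idx, signs)
        },
    }
    return FixtureBundle(
        config=config,
        query_proteome=query_records,
        target_proteome=target_records,
        peptide_table=peptides,
        ks_table=ks_rows,
        quant_matrix=quant,
        truth=truth,
    )


def write_bundle(bundle: FixtureBundle, outdir: str | Path) -> None:
    """Write the bundle as plain-text inputs (FASTA + TSVs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.query_proteome, outdir / "query.fasta")
    write_fasta(bundle.target_proteome, outdir / "target.fasta")
    pd.DataFrame(
        {
            "peptide": [render_peptide(p) for p in bundle.peptide_table],
            "protein": [p.protein_hint for p in bundle.peptide_table],
        }
    ).to_csv(outdir / "peptides.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "kinase": k.kinase_gene,
                "substrate_gene": k.substrate_gene,
                "substrate_accession": k.substrate_accession,
                "site": k.site,
                "species": k.species,
            }
            for k in bundle.ks_table
        ]
    ).to_csv(outdir / "ks_table.tsv", sep="\t", index=False)
    bundle.quant_matrix.values.to_csv(outdir / "quant.tsv", sep="\t")
    bundle.quant_matrix.groups.rename("group").to_frame().to_csv(
        outdir / "groups.tsv", sep="\t"
    )
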