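# phosmap

Motif-centric cross-species mapping and analysis of post-translational
modification (PTM) sites.

Mass-spectrometry phosphoproteomics is deep for human and a handful of model
organisms and shallow for everything else. Yet a phosphosite is rarely an
isolated residue: the kinase that writes it recognises the short sequence
neighbourhood around it, so a site whose ±7-residue window is conserved in
another species is a strong candidate to exist — and to be regulated the same
way — there. `phosmap` exploits this to transfer site-level knowledge between
species: it localizes identified phosphopeptides on a proteome, pairs each
protein with its best hit in a second proteome, carries every site through a
pairwise alignment, and scores how well the sequence window survived. On top
of that core it provides motif discovery, kinase–substrate (KS) annotation
and enrichment, conservation segmentation across many species, and a
quantitative differential pipeline for site × sample intensity matrices.

It is a library first (plain functions over `pandas`/`biopython` objects)
with a thin `phosmap` CLI for shell use.

## The scores at the core

For a site at protein position *p*, the **sequence window** is the
`2h + 1`-mer centred on *p* (default half-width `h = 7`, i.e. a 15-mer),
padded with `_` at protein termini. Two windows are compared by:

* **Window similarity** — the count of positionally identical residues,

  `WS = Σᵢ 1[A_query,i = A_ref,i]`, an integer in `0..15`,

  with `WS = 15` for a perfectly conserved window. Sites with `WS ≥ 8`
  pass the default conservation filter.
* **BLOSUM50 score** — the global-alignment score of the de-padded windows
  under the BLOSUM50 substitution matrix, which credits conservative
  substitutions that plain identity misses.

Best-hit protein pairing ranks candidate hits by the simplified database
E-value `E = m·n·2⁻ˢ` (query length *m*, summed database length *n*, bit
score *S*), with ties broken by matching percentage, then alignment length.
Central residues across species are classified as `S<>S`, `T<>T`, `Y<>Y`,
`S<>T` or `S/T<>Y`; the class requirement is a separate, adjustable filter.

Downstream layers use the standard machinery of the field: iterative
(motif-x-style) binomial motif enrichment, position weight matrices and PWM
correlation for kinase matching, Fisher's exact test with Benjamini–Hochberg
correction for KS and per-segment enrichment, equal-frequency conservation
quintiles Q1–Q5, agglomerative clustering of species presence profiles, and
a SAM-style permutation test `d = (x̄₂ − x̄₁)/(s + s₀)` for two-group
differential sites (median/log2 normalization → missingness filter → kNN
imputation → 1000 label permutations, FDR 0.01, |log2FC| ≥ 1).

## Worked example

Map one phosphosite onto a diverged ortholog:

```python
import phosmap as pm
from phosmap.io import ProteinRecord

query = ProteinRecord("Q_AKT1S1", "MASGRPEELWEAVV...PRPRLNTSDFQKLKRKY")  # full sequence
(pep,) = pm.parse_modified_peptides(["RLNTS#DFQK"])      # '#' marks the phospho-S
sites, _ = pm.locate_peptides([pep], [query])
s = sites[0]
print(s.residue, s.position, s.window)

target = ProteinRecord("T_AKT1S1", query.sequence.replace(
    "RLNTSDFQKLKRKY", "RLNSSDFHKLKRKY"))                 # ortholog, 2 substitutions
mapped, summary = pm.crossmap_sites(sites, [query], [target])
m = mapped[0]
print(m.target_window, m.ws_score, m.blosum50_score, m.match_class, m.passed_filters)
```

prints

```
S 247 PRPRLNTSDFQKLKR
PRPRLNSSDFHKLKR 13 94.0 S<>S True
```

The peptide's phospho-serine localizes to protein position 247; its 15-mer
window differs from the ortholog's at two positions, so the window
similarity is 13 of 15 (the BLOSUM50 score 94 reflects that T→S and Q→H are
conservative). The central residues pair as `S<>S`, and with `WS = 13 ≥ 8`
the site passes the default filters — this site would be transferred.

The same flow runs from the shell:

```sh
phosmap prealign --fasta query.fasta --peptides peptides.tsv --out sites.tsv
phosmap crossmap --query-fasta query.fasta --target-fasta target.fasta \
                 --sites sites.tsv --ws-min 8 --out mapped.tsv
```

and `phosmap fixture --seed 1 --outdir demo/` generates a complete synthetic
input set (paired proteomes, peptides, KS table, quantity matrix) to try
every subcommand on.

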