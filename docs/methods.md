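# Methods

## The procedure

`isotriage` implements a structure-guided triage of alternative transcript
isoforms. The premise: AlphaFold2-class predictors emit a per-residue
confidence, the predicted local distance difference test (pLDDT, 0–100),
stored in the temperature-factor column of the coordinate file; the mean
pLDDT over a protein is a calibrated proxy for how well the chain folds.
When an alternate isoform of a gene folds decisively better than the
designated canonical (MANE-style) isoform — and expression evidence does
not contradict it — that alternate is a candidate for being the gene's
functional product.

For every alternate isoform at a locus anchored by a canonical transcript,
with one mean pLDDT per *distinct* protein sequence:

1. **Eligibility gate.** The alternate must encode a protein distinct from
   the canonical's; its coding sequence must overlap the canonical CDS by
   ≥ 1 bp on the same strand (this removes intron-nested processed
   pseudogenes, which otherwise out-score their host gene); its mean pLDDT
   must be ≥ 70, excluding the intrinsic-disorder regime; and its protein
   must be ≤ 1000 aa (the structure-prediction length cutoff — longer
   proteins are triaged only if a score was imported for them, and are
   flagged `over_length` otherwise).
2. **Acceptance branches.** With canonical score *p*, length *ℓ*, sample
   count *s*, and alternate *p′*, *ℓ′*, *s′*:
   - **A** (better fold, comparable length): `p′ ≥ 1.05·p` and `ℓ′ ≥ 0.90·ℓ`;
   - **B** (longer, no worse, at least as expressed): `ℓ′ ≥ 1.05·ℓ`,
     `p′ ≥ p`, `s′ ≥ s`;
   - **C** (shorter but decisively better): `ℓ′ ≥ 0.50·ℓ`, `p′ ≥ 1.05·p`,
     `s′ ≥ s`.
   Membership is the union; the reported label is the first of A, B, C
   that holds.
3. **Deduplication.** Isoforms sharing an identical coding sequence share
   one structure and one score; only the isoform assembled in the most
   samples is kept (ties broken by smallest transcript id).

"5% higher" is read as relative (×1.05), parallel to the unambiguous
"90% as long"; all comparisons are non-strict (≥), matching "at least" /
"equal or higher". Both the margins and the gate are `Thresholds`
parameters and CLI options.

Sample counts mean *presence* — the number of RNA-seq samples in which the
isoform was assembled — not expression above a TPM cutoff. An isoform with
no expression record counts as never assembled (0 samples, 0 TPM), since a
handful of canonical proteins are legitimately absent from such summaries.

Transcriptome-level context is computed alongside: the number of
alternates whose score strictly exceeds their canonical's, and the
fraction of loci whose most commonly observed isoform (max sample count;
ties by higher pLDDT, then id) scores below 70 — the disorder-heavy
fraction of the gene set.

## Supporting evidence computations

- **Intron conservation.** A transcript's introns are the gaps between its
  exons; in transcription order each must start GT (donor) and end AG
  (acceptor). Boundaries are mapped through MAF alignment blocks to a
  target species; the transcript is conserved (`TRUE`) only if every
  boundary dinucleotide reads GT/AG there. A substitution, an alignment
  gap, or an unaligned boundary gives `FALSE` — conservation is affirmed,
  never assumed. Intronless transcripts are vacuously `TRUE` (reported
  distinctly in the per-intron `boundary_checks`). Soft-masked lowercase
  bases are uppercased, not treated as missing.
- **Dihedrals and Ramachandran classification.** φ(i) is the
  C(i−1)–N(i)–CA(i)–C(i) torsion and ψ(i) the N(i)–CA(i)–C(i)–N(i+1)
  torsion, IUPAC sign, degrees in [−180, 180). Residues are classified
  against a gridded general-case φ/ψ reference: the Top500 (Richardson
  lab) high-resolution histogram distributed with MDAnalysis, 4° bins,
  thresholded at the density levels that package contours (≥ 17 favored,
  ≥ 1 allowed; favored ⊂ allowed by construction). Glycine and proline —
  which the general-case map does not describe — and residues with
  undefined angles (termini, missing backbone atoms) are counted as
  skipped, so the four counts always sum to the chain length.
  `RamaRegionMap` is generic (any grid, bin width and thresholds), so a
  different contour source can be swapped in as a data file.
- **Superposition RMSD.** Residues of two structures are paired by global
  sequence alignment (BLOSUM62, affine gaps −11/−1 — the comparisons are
  between isoforms/orthologs with clear sequence correspondence, so no
  structural alignment is needed); only match columns are used. The Kabsch
  algorithm (SVD with determinant correction; reflections never allowed)
  superposes the selected atoms — all shared heavy atoms by default, with
  backbone and CA-only modes — and the RMSD is reported with no outlier
  rejection, printed to 2 decimals.

## Numerical choices

- Genomic intervals are 0-based half-open internally; GTF I/O converts
  from 1-based inclusive once, at the boundary.
- pLDDT is read from the CA atom only (the file replicates it across a
  residue's atoms) and rounded to two decimals, the resolution of the
  temperature-factor column; this also undoes float32 parser error.
- Branch thresholds are compared with a 1e-9 absolute slack
  (`alt ≥ 1.05·canon − 1e-9`): 1.05 × 80.00 is 84.00000000000001 in binary
  floating point, and a score exactly at a decimal threshold must not be
  rejected by representation error. The slack is four orders of magnitude
  below the scores' two-decimal resolution, so it can never flip a
  genuinely below-threshold comparison.
- ORF finding is deliberately simple: longest ATG-initiated reading frame
  ending in a stop, 5′-most start on ties, no Kozak context — a stated
  simplification of reference-guided ORF assignment. Translation uses the
  standard code, drops the terminal stop, and treats an internal stop as
  an error naming the codon index.
- A CDS whose length is not divisible by 3 is truncated by the trailing
  1–2 nt with a warning; a locus whose canonical lacks a structure score
  is skipped with a warning rather than failing the run.

## The synthetic benchmark

`synthetic.make_benchmark` generates a complete toy input set — genome
FASTA, GTF, canonical list, per-protein PDB structures, scores TSV,
expression TSV, and a two-species MAF — with the ground truth recorded at
construction time, so every pipeline stage is testable without downloads.

Study conditions (fixed defaults): 20 loci; canonical isoforms of 100 aa
with mean pLDDT 80.00 and 50 samples; a case deck that plants one instance
of each acceptance branch, rejection cases, a same-CDS duplicate pair
(samples 10 vs 3), an intron-nested pseudogene decoy, an over-length
(1001 aa) protein, and boundary cases exactly at and one representable
step across every threshold (84.00/83.99 against ×1.05; lengths 90/89,
105/104, 50/49; gate 70.00/69.99 against a 63.00 canonical); 7 of 20 loci
carry a low-confidence (< 70) most-sampled isoform, giving a planted
fraction of 0.35; each intron boundary set is flipped in the mouse row
with probability 0.2. Loci alternate strands and are shuffled per seed.

Construction details that make the ground truth exact:

- All spliced transcripts at a locus share a first exon (5′UTR + ATG + 9
  codons) and its donor GT; each gets a private acceptor AG and second
  exon, so CDS overlap with the canonical holds by construction, protein
  prefixes are shared, and remainders are independent random codons. The
  pseudogene decoy is a private single-exon ORF placed inside the shared
  intron, upstream of the canonical's second exon.
- Structures are ideal-geometry backbones (N–CA 1.46 Å, CA–C 1.52 Å,
  C–N 1.33 Å, standard angles, trans omega) built from per-residue
  torsions: helix −57/−47, strand −119/+113, coil randomized. No physics —
  downstream code consumes only coordinates, torsions and B-factors.
- Per-residue pLDDT plans are piecewise-constant with Gaussian jitter
  (sd 1.5) re-centred on the planned mean and clipped to [0, 100] —
  margin-critical cases use constant plans so the two-decimal B-factor
  rounding preserves the planted epsilon exactly. The scores TSV carries
  the realized mean of the rounded values, so file-derived and
  TSV-derived scores agree.
- Output is byte-identical for a fixed seed.

What the generator does **not** emulate: realistic sequence evolution,
splice-site sequence context beyond the GT/AG dinucleotides, RNA-seq
noise, multi-gene overlap, UTR introns, alternative start sites, or any
correlation between pLDDT and sequence content. Passing the benchmark
therefore demonstrates that the decision logic, file plumbing, coordinate
conventions and strand handling are correct — not that the thresholds are
biologically optimal on real data.

## Problem sizes used in checks

The repository's principal check re-runs the full file-level pipeline on
100 seeded benchmark instances (≈ 20 loci, ~60 transcripts each) and
demands exact recovery of the planted accepted set, branch labels, dedup
survivors, exclusions and conservation flags; it completes in a few
seconds. Oracle comparisons use 50 random 4–10-point sets against a
multi-start rotational minimizer (agreement to 1e-6 Å), 1000 random ORFs
against a literal codon table, and global alignments against a hand-rolled
Gotoh DP; the threshold grid is exhaustive over 5 × 8 × 3 score/length/
sample placements around every boundary.

## Known limitations

- The eligibility gate applies the ≤ 1000 aa cutoff to alternates only;
  canonical proteins above it participate whenever a score is supplied
  for them (mirroring imported scores for long proteins).
- Branch B/C compare raw per-transcript sample counts, not counts pooled
  across same-CDS duplicates.
- The Ramachandran map is the general case only; pre-proline and
  glycine-specific maps are out of scope, and both glycine and proline are
  excluded from counting.
- Multi-chain coordinate files are handled by taking the first chain with
  a warning; multi-model files use the first model.
- No multiple-testing control is applied — the cascade is a deterministic
  rule set, not hypothesis testing — and the output is evidence for
  curation, not an assertion of function: score comparisons alone can
  mislead, e.g. for genuinely disordered proteins.
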