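# Methods

This note documents the models, heuristics and numerical choices behind
`laccmine`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## ORF model

ORFs are ATG-initiated and run to the first in-frame stop (complete) or
to the transcript's 3′ end (3′-partial), scanned over both strands and
all three frames. One maximal ORF is reported per (strand, frame, stop):
internal ATGs do not spawn nested ORFs. 5′-partial ORFs (no ATG) are
excluded by default because every laccase CDS this tool targets begins
with a methionine; `allow_partial_start=True` enables them. Coordinates
are 0-based half-open on the forward strand internally; reports print
1-based inclusive positions. Codons containing any non-ACGT base
translate to `X`, and `X` never satisfies a signature ligand position —
a deliberately conservative treatment of assembly ambiguity. The default
`min_aa = 100` suppresses micro-ORFs while sitting far below the
~480-residue floor of real laccase peptides.

For every complete ORF, `nt = 3 × (aa + 1)` (the stop codon is counted
in the CDS, not the peptide); this invariant is enforced in the
`OrfRecord` constructor itself.

Unigene (longest-isoform-per-component) selection is implemented but
**off by default** in mining: laccase families frequently keep distinct
products on isoforms of one component (alternative splicing), and
longest-isoform selection would silently collapse them. The tie-break is
the lexicographically smallest isoform id, making selection idempotent
and order-stable.

## Laccase signature

The four conserved regions are encoded as residue-class regular
expressions with explicit copper-ligand offsets:

| region | default core pattern | ligands |
|--------|----------------------|---------|
| L1 | `H[WF]H[GAS]` | His at 0, 2 |
| L2 | `G[TS].[WF][WYF]H[SCA]H` | His at 5, 7 |
| L3 | `HP.H[LIF]HG` | His at 0, 3, 5 |
| L4 | `HCH[IVLF]..H` | His at 0, 2, 6; Cys at 1 |

These are conservative cores of the classical fungal-laccase signature
regions: they pin the invariant 10-His + 1-Cys ligand architecture while
leaving the variable positions as character classes. They are
configurable through a plain-text file (`signature_to_text` /
`signature_from_text`), since any fixed consensus trades sensitivity
against specificity. The axial T1 ligand is read at `L4-Cys + 10`, the
canonical spacing in basidiomycete laccases; the offset is part of the
configuration. Axial Met/Leu/Phe map to classes 1/2/3; anything else is
`unclassified`. With the axial residue the signature accounts for the
twelve copper-interacting positions.

`scan_regions` reports at most one hit per region with starts in strict
L1 < L2 < L3 < L4 order and no overlap. Because a pattern can match
spuriously, the scanner selects, among all order-consistent assignments,
the one covering the most regions (leftmost chain on ties) rather than
committing greedily left to right.

### Candidate classification

- **true_laccase** — a single complete ORF carries the full ordered
  four-region chain.
- **pseudogene_no_stop** — a 3′-partial ORF carries ≥ 3 regions
  (threshold configurable): the coding region runs off the transcript
  end. Requiring three regions keeps random partial matches from being
  promoted to pseudogenes.
- **pseudogene_premature_stop** — no single ORF has all four regions,
  but ≥ 2 same-strand ORFs jointly cover them. For this union the
  scanner's ordering constraint is deliberately dropped (order-free
  region *presence* per fragment): an internal stop splits the signature
  across fragments, so within-fragment order carries no information, and
  a spurious early match could otherwise mask a real region.
- **partial_signature** — anything else with at least one region
  (including single-ligand-disrupted multicopper oxidase decoys).

Pseudogenes are excluded from axial-class counting; their C-terminal
region may be unreadable.

## Physicochemical characterization

- **GC content**: `100 × (G + C) / (A + C + G + T)`; ambiguous bases are
  excluded from the denominator, and an all-ambiguous sequence is an
  error rather than a number.
- **Molecular weight**: sum of average (not monoisotopic) residue masses
  plus one water (18.0153 Da), reported in kDa to one decimal. Computed
  on the full predicted chain, not the post-cleavage mature chain.
- **Theoretical pI**: the unique zero of the Henderson–Hasselbalch net
  charge on pH ∈ [2, 13], found by bisection to |charge| < 10⁻⁴. The pKa
  constants are the Bjellqvist set used by the common web calculators
  (C-terminus 3.55; N-terminus 7.50 with residue-specific values for
  A/M/S/P/T/V/E; side chains D 4.05, E 4.45, H 5.98, C 9.00, Y 10.00,
  K 10.00, R 12.00), kept in one block in `physchem.py` so an alternative
  set can be swapped in. Net charge is strictly decreasing in pH, so
  bisection is globally convergent; a composition with no zero crossing
  in [2, 13] raises a numerical error. Agreement with a 10⁻⁴-step grid
  search and with an independent implementation of the same constants is
  part of the test suite.
- **N-glycosylation**: the sequon rule N-X-[S/T] with X ≠ P, nothing
  more. Trained-model site filtering (neural networks/SVMs) is out of
  scope, so detected sequons are a superset of the sites such predictors
  would keep; downstream comparisons should use containment, not
  equality.
- **Secretion**: a transparent rule-based heuristic, not a trained
  predictor. A cleavage candidate `c ∈ [10, 35]` needs (i) small
  residues (A/G/S/C/T) at `c` and `c−2` (the von Heijne −1/−3 rule),
  (ii) an h-region — a ≥ 7-residue window in `[1, c−3]` with mean
  Kyte–Doolittle hydropathy ≥ 1.6 — and (iii) a non-negative n-region
  charge (K/R minus D/E up to the h-region start). Candidates score
  `h-mean + 2 + 1` against a threshold of 3.0; absence of a candidate
  is the non-secreted outcome. Predicted cleavage positions are
  order-of-residues accurate on constructed signals but should be read
  as approximate (± a few residues) on real proteins.

## Similarity, distances, trees

- **Pairwise similarity** is percent identity over *compared columns* —
  columns where neither row of the BLOSUM62 global alignment (affine
  gaps, open 10, extend 0.5) is a gap. Under this convention two
  isoforms differing only by an in-frame insertion score exactly 100.0,
  which is what makes insertion isoform pairs recognizable in the
  similarity table. All alignment parameters are exposed because
  similarity values depend on them. Traceback ties are resolved by the
  alignment engine's deterministic enumeration order; the score and, on
  non-degenerate inputs, the identity counts are tie-insensitive.
- **Multiple alignment**: a simple progressive aligner — pairwise
  p-distances from global alignments, an average-linkage (UPGMA) guide
  tree, then affine-gap profile–profile merges using mean column
  substitution scores (gap/residue pairs score 0). An externally
  computed alignment (aligned FASTA or Clustal) can be supplied instead;
  for closely related family members the progressive result is adequate,
  but it is not a substitute for a modern MSA tool on deep alignments.
- **Distances**: pairwise-deletion p-distance by default; Poisson
  correction `−ln(1 − d)` optional and undefined at `d = 1` (an error,
  not a clamp). A pair with no compared columns is assigned distance 1.
- **Neighbor joining**: classical Saitou–Nei agglomeration with the
  standard Q-criterion and branch-length formulas; ties break to the
  lowest index pair, making the tree deterministic. Negative branch
  lengths are clamped to zero with the deficit moved to the sister
  branch (sum preserved), toggleable. Output is an unrooted tree with a
  trifurcating central node. On additive matrices NJ provably recovers
  the generating topology; the test suite checks this against a
  least-squares brute force over all topologies up to n = 6.
- **Bootstrap**: alignment columns resampled with replacement; the
  support of an internal edge is the percentage of replicate NJ trees
  containing its bipartition. Seeded and reproducible; supports are
  written as internal node labels in Newick.

## Synthetic data: what it emulates, what it does not

The generator plants laccase CDSs with the L1–L4 cores at randomized
spacings, correct ligand residues, a chosen axial residue at the
configured offset, optional signal peptides and sequons; it
back-translates with codon choices greedily steered toward a target GC
(default 55.5%, inside the 52–59% band typical of these transcripts,
verified to land within ±1%). Families are derived by point
substitutions outside protected positions (cores, axial residue, signal
prefix, initial Met) and optional 3–15-codon in-frame insertions;
insertion-only members emulate splice isoforms and keep 100.0%
similarity to their ancestor. Pseudogene variants truncate the
transcript flush with the lost stop codon, or place an internal stop
between L2 and L3 with a following ATG so the downstream fragment forms
its own ORF. Decoys disrupt exactly one ligand residue — the hardest
negative for a signature scanner. Background transcripts come from an
order-3 Markov model near 50% GC; a background draw that accidentally
classifies as a true laccase is re-rolled and logged. About 30% of
planted CDSs are embedded on the minus strand to exercise six-frame
handling. Every generated sequence is re-scanned and re-predicted before
acceptance, so the manifest is exact by construction, and all
randomness flows through explicit seeded generators (same seed ⇒
byte-identical output).

Default conditions: three families of sizes 4/3/1 (the singleton without
a signal peptide, an intracellular analog), one pseudogene per mode as
extra isoforms of the first family's component, five decoys, fifty
background transcripts, 520-residue peptides.

The generator does **not** emulate: sequencing error or assembly
artifacts, real codon-usage structure beyond the GC target, homology
between families (ancestors are independent random peptides, so
between-family distances are near-saturation), expression levels, or
UTR biology. Passing the end-to-end tests therefore demonstrates the
pipeline's bookkeeping and discrimination logic under clean conditions,
not its sensitivity on diverged real transcriptomes — on real data the
configurable signature patterns, not the pipeline logic, are the
sensitivity bottleneck.

## Problem sizes used in tests and the acceptance script

The shipped checks run the default synthetic transcriptome (65
transcripts), 1000 bootstrap pseudoreplicates on the ~8-taxon family,
100 random peptides for the pI grid oracle, exhaustive alignment
enumeration up to 8 residues, and least-squares tree brute force up to
6 taxa — sizes at which the brute-force oracles are exact and the whole
suite runs in seconds.

## Known limitations

- Signature cores are fixed-width conservative patterns; heavily
  diverged or unusual laccases (and non-laccase multicopper-oxidase
  subfamilies) are outside their design envelope. No HMM/PSSM scoring.
- The secretion and glycosylation calls are transparent rules, not
  trained predictors; they are meant for triage and cross-family
  comparison, not per-site accuracy.
- The deposited reference CDSs (GenBank MF176136–MF176145) are fetched
  on demand, never bundled; the accession-based tests report their
  absence as a failure with instructions rather than silently passing.
- NJ bootstrap supports are on the built-in progressive alignment;
  with a different MSA tool the supports (not usually the cherries)
  can shift.
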