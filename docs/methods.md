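# Methods

This note documents the models, rules and numerical choices behind each
pipeline stage, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the procedure was genuinely
open.

## Genome model and inputs

A genome is an ordered list of protein-coding genes on one replicon:
locus tag, 1-based inclusive coordinates, strand, 0-based rank in gene
order, and protein sequence (20 amino acids + X). Domain evidence is
*consumed*, not computed: pfam domain calls and whole-protein COG
assignments arrive as a TSV (`locus_tag, pfam, cog, dom_start, dom_end`),
because profile scanning is an external published-tool step whose
databases version independently of this package. Accessions are
normalized to zero-padded canonical forms (`pfam481`, `PF0481` →
`PF00481`; `cog631` → `COG0631`) since published sources mix spellings.
Strand is carried through but ignored by all downstream rules — the
positional criteria below state no strand conditions. Gene distances are
computed over CDS features only; pseudogene/RNA rows, if present in a
GFF, are skipped.

## Family classification

Classification is rule-based: an ordered schema of
(family, required pfam set, required COG set) rows, a row matching when
both requirement sets are subsets of the locus's evidence; the first
match wins. The shipped schema (also provided as
`src/phosphatome/data/family_schema.tsv` for user extension):

| family | pfam | COG |
|---|---|---|
| PP2C | PF00481 | COG0631 |
| SPOIIE | PF07228 | COG2208 |
| PPP_CANDIDATE | PF00149 | COG0639 |
| PTP | — | COG2453 |
| LOW_MW_PTP | — | COG0394 |
| DSP_PTP | — | COG2365 |
| PTP_OTHER | — | COG4551 or COG5350 |
| PTPZ | — | COG4464 |
| ELK | — | COG0515 |
| NON_ELK_KINASE | — | COG2172 |
| ANTI_ANTI_SIGMA | — | COG1366 |
| RHODANESE | — | COG0607 |

In practice the rows are disjoint; the fixed priority order only makes
degenerate double-evidence inputs deterministic. Special rules:

* **PF00149 without COG0639** → `OTHER` with the note "calcineurin-like
  non-phosphatase". The calcineurin-like superfamily contains
  nucleotidases, phosphodiesterases and nucleases; only the COG0639 group
  has experimentally supported phosphatase/ApaH activity.
* **PPP subtype** from motif content of the protein sequence:
  `CONSENSUS_COMPLETE` when all four signature motifs (GDXHG, GDXXDRG,
  GNHE, (I/L/V)D(S/T)G) are present, else `PPP_CONFIRMED` when the
  (I/L/V)D(S/T)G motif is present, else `APAH_CANDIDATE`. These three
  are by construction mutually exclusive; the completeness flag subsumes
  the confirmation it implies.
* **Rhodanese** proteins lacking the Cdc25 active-site motif CE[F/Y]SXXR
  are flagged `CDC25_NEGATIVE` (i.e. not Cdc25-type phosphatases).
* **Low-MW PTP** calls carry a free-text caveat: arsenate reductase
  (ArsC) shares the fold and COG, so the phosphatase call is provisional
  without experimental evidence.
* **Fusion flags** (cNMP = PF00027 or SM00100, HAMP = PF00672,
  FHA = PF00498, GAF = PF01590, PBD = PF00532, STAS = PF01740) are raised
  only when the accessory accession co-occurs with catalytic phosphatase
  evidence on the same locus.

Classification is a pure function of the evidence sets — independent of
gene order and of call-row order.

## Motif engine

Patterns use a PROSITE-like grammar: uppercase letters are fixed
residues, `X` is a wildcard, `(A/B)` and `[A/B]` are alternations (both
bracket styles occur in the literature). Scanning is exhaustive and
allows overlapping hits; motif presence is scored anywhere in the
sequence, not position-anchored, since the motifs are defined by
alignment consensus rather than coordinates. The wildcard matches the
ambiguity residue X in input sequences; fixed residues and alternation
members do not — an ambiguous position cannot positively confirm a
specific residue.

Kinase catalytic-loop classification is exact-match by default: DLKPEN →
Ser/Thr, DLRAAN or DLAARN → Tyr, DLKPDN → Ser/Thr with known
dual-specificity. A relaxed mode (off by default) generalizes any
DLKxxN loop to Ser/Thr, reflecting that the lysine at loop position 3 is
the Ser/Thr indicator; it is opt-in because only the exact consensus
peptides have direct experimental backing.

PP2c-superfamily proteins share a catalytic domain of eleven sequence
motifs, but only the motifs listed above are published as explicit
residue patterns; the engine therefore implements only those.

## Orthology

Orthologs are reciprocal best hits (RBH): (a, b) is a pair when b is a's
best-scoring match in the other genome, a is b's, and both directions are
significant at E ≤ 10⁻¹⁰. Design choices:

* **Optimal Smith–Waterman replaces heuristic BLASTP** (BLOSUM62, gap of
  length k costs 11 + k). This is deterministic, oracle-testable and
  strictly more sensitive; the scientific criterion is the RBH rule and
  the E-value cutoff, not BLAST internals. The implementation uses
  Biopython's `PairwiseAligner`; tests verify it against an independent
  hand-written Gotoh DP oracle.
* **Significance** uses the Karlin–Altschul form
  `E = K·m·n·exp(−λS)` with the standard gapped-BLOSUM62 constants
  λ = 0.267, K = 0.041, m = query length and n = the *total residue count
  of the target proteome* (database-style scaling, configurable). The
  stored pair E-value is the worse of the two directions, so every
  emitted pair satisfies the cutoff by construction.
* **Ties** on raw score break toward the lexicographically smaller locus
  tag, and a tie-broken best still counts; the choice is a declared
  convention (the best-hit definition does not specify tie handling).
* **Within-genome self-comparison is excluded** — orthology is defined
  between organisms; paralog detection is out of scope.
* An optional **k-mer seed prefilter** (`seed_filter=(k, min_shared)`)
  skips exact alignment for pairs sharing fewer than `min_shared`
  distinct k-mers, a BLAST-like seeding heuristic for large runs. It is
  off by default; a pair that could pass E ≤ 10⁻¹⁰ shares many k-mers in
  practice, and a test asserts seeded/exhaustive agreement on the
  synthetic data.

Ortholog groups are connected components of the RBH graph. A component
with two members from one genome is repaired by repeatedly deleting its
weakest edge (largest E-value, ties on endpoint labels) until every
component is genome-unique; components reduced below two members are
dropped.

## Gene context

Gene distance is purely positional: `|index_a − index_b| − 1` intervening
CDS, strand-ignored, no operon inference. Co-organization means distance
≤ 5 (configurable); distance 0 is a *direct* pair. PtpZ-like proteins
are excluded from the opposing-phosphatase set by convention — they are
not believed to counteract ELKs. Replicons are treated as linear; for
circular chromosomes the wrap-around distance is not taken (the window
sizes involved are negligible against replicon length).

Local synteny formalizes what is classically a manual neighborhood
inspection: for each ortholog pair whose two loci are both
phosphatase-family genes (the anchor), collect other ortholog pairs
within ±5 genes of both anchors; emit a block when ≥ 2 such neighbor
pairs exist *and* their relative gene order is identical or fully
reversed in the two genomes. Window and threshold are parameters; the
order-consistency test is all-or-nothing over the collected neighbors,
so a scrambled neighborhood yields no block rather than a partial one.

## Phylogeny

* **Pairwise distances**: global affine-gap alignment (BLOSUM62, same gap
  costs), p-distance = 1 − identities / comparable columns (gap–gap
  columns excluded; gap-vs-residue counts as a difference). Kimura's
  empirical protein correction `d = −ln(1 − p − 0.2p²)` is available
  behind a flag and capped at 10 substitutions/site near saturation;
  uncorrected p-distance is the default since the distance-correction
  settings of the classical ClustalX recipe are not specified.
* **Progressive MSA**: NJ guide tree on pairwise p-distances; profiles
  merged leaf-to-root by global profile–profile alignment with
  mean-of-pairs BLOSUM62 column scores (gap symbols score 0) and the same
  affine penalties. Two sequences reduce exactly to their pairwise
  alignment; every row ungaps back to its input by construction. This
  in-repo aligner replaces ClustalX: published trees are figure-only and
  not reproducible targets, so what matters is internal consistency and
  synthetic-clade recovery, both of which are tested.
* **Neighbor joining**: the Saitou–Nei algorithm with the standard
  Q-criterion `Q(i,j) = (n−2)d(i,j) − r_i − r_j`; equal-Q candidates
  break toward the smallest sorted label pair (Q comparisons use a 1e-12
  absolute tolerance so float noise cannot flip a tie); negative branch
  lengths are clamped to 0 and flagged on the tree. The final three
  lineages join at a central trifurcation with closed-form lengths, so
  the result is an unrooted tree rooted at that trifurcation. For any
  additive matrix NJ provably recovers the generating topology and exact
  branch lengths; the tests verify path-distance reproduction to < 1e-9
  on random additive matrices up to 12 taxa, and topological agreement
  with scikit-bio's independent implementation.
* **Bootstrap**: alignment columns resampled with replacement; distances
  (p-distance with pairwise deletion of gap–gap columns) and NJ
  recomputed per replicate; the support of each internal bipartition of
  the reference tree is the percentage of replicates containing it.
  Each replicate uses an independent RNG stream keyed by
  `(seed, replicate index)`, so results are independent of evaluation
  order. A degenerate pair with no comparable columns gets distance 1.
  Newick rendering can hide supports below a threshold (the classical
  display convention hides < 50 %), but the data model keeps all values
  and the default serialization round-trips exactly (lengths at 6
  decimals, supports as internal node labels).

## Summary table

The per-genome summary counts ELKs, PP2c-type, SpoIIE-like and PPP
phosphatases, and a PTP column summing the tyrosine-phosphatase classes
(PTP + low-MW + DSP + other predicted PTPs), with PtpZ-like proteins
excluded from the PTP column by the same convention as above. The total
is the sum of the four phosphatase columns, and the ELK/PP ratio is
rendered `x.y/1` with **half-up** rounding at one decimal (`NA/1` for a
zero total). Half-up is validated against all nine published rows, none
of which is ambiguous under this rule; a missing SpoIIE count in a
published row is treated as 0, which reproduces that row's printed total.

## Synthetic data generator

The generator emulates the real inputs — per-genome FASTA, GFF and
domain-call tables — with planted structure and a ground-truth JSON.
Defaults define the study conditions: 3 genomes × 200 genes, protein
lengths 250–350, per-family planted counts echoing the relative
myxobacterial family sizes at a 200-gene scale (10 ELK, 4 PP2c-type,
2 SpoIIE-like, 3 PPP + 2 ApaH-like, 5 PTP-class + 1 PtpZ, 2 rhodanese,
1 each of non-ELK kinase, anti-anti-sigma and calcineurin-like
non-phosphatase), 25 % fusion fraction, 50 % of family members in
ortholog groups spanning all genomes, 5 % per-residue ortholog
divergence, co-organized ELK–PP2C pairs at gene distances 0/2/5, and one
synteny block (anchor + 3 conserved neighbors) between the first two
genomes.

Mechanics worth knowing:

* Ortholog groups are star-shaped — one random ancestor, independently
  mutated into each genome — so multi-genome groups are well defined.
  Mutation substitutes each position independently with the configured
  probability to a uniformly chosen different residue; planted motif
  positions are masked so family evidence survives divergence.
* Sequences are rejection-sampled against family exclusion constraints:
  ApaH-like proteins (ancestor *and* each mutated copy) must not contain
  an (I/L/V)D(S/T)G instance anywhere; rhodanese proteins must not
  contain the Cdc25 motif. Without this, roughly 1 % of random 300-mers
  would carry a chance (I/L/V)D(S/T)G hit and corrupt the subtype truth.
* Placement keeps unplanned signal out, so the ground truth is the
  *complete* answer, not a subset: kinase-family and phosphatase-family
  genes outside the planted co-organized windows live in separate genome
  zones with a 7-gene buffer (one more than the default threshold), and
  ortholog-group genes outside the planted synteny block are stratified
  so that same-genome neighbors in ortholog pairs sit farther apart than
  the synteny window. An internal audit pass re-checks truth/file
  consistency on every generation; infeasible configurations (planted
  structure exceeding genome size) fail before anything is written.
* Background composition is uniform over the 20 residues. Real proteomes
  have biased composition, homologous families, indels, domain shuffling
  and gene gain/loss — none of which is simulated. Passing tests
  therefore demonstrate the *correctness of the detection rules*, not
  their behavior under real-genome noise: with realistic divergence and
  composition bias, RBH recovery and motif specificity would be lower
  than the near-perfect values measured here.

## Problem sizes and determinism

The test suite and the acceptance script size their simulations to run in
a few minutes on one CPU: classification on 3 × 200 genes, ortholog
recovery on 2 × 170 proteins of length 300 across 5 replicate datasets
(exhaustive all-vs-all Smith–Waterman, no seeding heuristic), 100
additive matrices of 4–12 taxa, 200 alignment-oracle pairs, and 200
bootstrap replicates on an 8-taxon two-clade alignment (the classical
recipe's 1000 replicates are supported; 200 already saturate the central
bipartition). Every random draw in the package flows through
`numpy.random.default_rng` seeded from explicit parameters; reruns with
the same configuration are byte-identical, and the pipeline manifest
records the config hash and seed (but not the output directory, which is
run-location metadata).

## Known limitations

* Family calls depend entirely on the input domain-call table; there is
  no sequence-only fallback, and pfam/COG version drift between input
  sources will shift counts.
* The eleven PP2c-superfamily motifs are not individually modeled (no
  published residue patterns); PPP subtyping rests on the four explicit
  motifs.
* Synteny formalization (window 5, ≥ 2 ordered neighbors) is one
  reasonable codification of a manual procedure; other parameterizations
  are defensible and configurable.
* The progressive aligner is a didactic-grade tool adequate for
  family-sized sets (tens of sequences); it is not a substitute for a
  production MSA program on large or highly gapped families.
* No statistical test is attached to cross-genome count correlations;
  the package reports the count tables and leaves inference to the user.
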