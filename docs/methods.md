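# Methods

## The screening model

The pipeline analyzes a single-round differential phage-display screen. A
stapled-peptide (Helicon) library — each member carrying two fixed stapling
cysteines and two scaffold alanines, with randomized positions drawn from a
16-residue alphabet that excludes C, K, P and G (trimer-phosphoramidite
synthesis; staple integrity and helix compatibility) — is incubated with a
bead-immobilized target. In trimerizer mode the library is split: one portion
receives the free presenter protein at 10 µM, the other does not. Wells are
sequenced separately, with a constant non-library spike-in phage added to
each well before amplification.

### Read processing

Reads are kept only when every base of the located insert is at Phred ≥ 18.
The literature protocol "trims" low-quality reads; we drop the whole read
instead, which keeps counting exact (a trimmed amplicon read could no longer
contain the full insert anyway). Anchors (the constant flanks) are matched
exactly, both anchors must occur exactly once, the insert must be 3×L with
no N, and the translated peptide must satisfy the design constraints.
Reverse-complement rescue is on by default (amplicon orientation varies);
mismatch-tolerant anchor search is deliberately not attempted — how the
original analysis rescued flank-mutated reads is unknown, so we do not guess.

### Normalization and hit strength

Normalized count = raw / spike × 10⁴. The scale constant is arbitrary; every
downstream quantity is a ratio of normalized counts and therefore invariant
to it. Hit strength is the fold-change between the top-target-concentration
well with presenter and the replicate-averaged target-only wells
(`hs_target`), and between the same numerator and blank-beads-with-presenter
wells (`hs_counter`). When a replicate-averaged denominator is zero it is
replaced by the pseudocount 0.5 *on the normalized scale* (this matches the
operation's arithmetic contract: numerator 10 over all-zero denominators
gives 20). A consequence worth knowing: fold-changes over a zero denominator
are not invariant to global rescaling of normalized counts; nonzero
denominators are. A zero numerator always yields hit strength 0.

A trimerizer call requires `hs_target > 5` **and** `hs_counter > 5`
(strictly greater). The conjunction operationalizes the two exclusions —
presenter-independent target binders enrich in the no-presenter wells and so
have `hs_target ≈ 1`; bead and free-presenter binders enrich in the counter
wells and have `hs_counter ≈ 1`. When several top-concentration presenter
wells exist their normalized counts are averaged (a single well is the
common case; averaging generalizes it). Whether the original analysis
applied the threshold to the counter comparison, or averaged numerator
replicates, is not stated; these are this package's defaults, configurable.

### Clustering and logos

The published campaign's clustering algorithm lives in earlier work and is
not restated there, so the implementation here is a documented stand-in, not
a reproduction: distance = 1 − BLOSUM62 similarity summed over variable
positions and normalized by the geometric mean of self-similarities (0 for
identical peptides), average-linkage agglomeration, cut height 0.55 by
default. Peptides are deduplicated and sorted lexicographically before
linkage so the output is invariant to input order, and cluster ids are
assigned by each cluster's smallest member. Logos weight members equally by
default (abundance weighting available); pwm columns use a symmetric
pseudocount over the 20 amino acids and always sum to 1.

Position classification: *fixed* when the top residue's frequency ≥ 0.9
(`f_fixed`); else *partial* when the smallest residue set with cumulative
frequency ≥ 0.75 (`f_cum`) has 2–5 members; else *free*. Residues tied in
frequency with the last included one are also included — a column at
0.3/0.3/0.2/0.2 yields the four-residue favored set, and an exactly uniform
choice set classifies to itself. Without tie-extension the 0.75 boundary
would split uniform sets arbitrarily. Staple/scaffold positions are always
forced fixed. Two caveats: a column whose top frequency lies between 0.75
and 0.9 with no close runner-up classifies as *free* (a size-1 set is not a
valid partial set); and near-uniform empirical frequencies from small
clusters sit close to the 0.75 boundary, so favored-set sizes can wobble
with sampling noise — the thresholds are logged with every classification.

### Degenerate-codon search

For a favored set the search enumerates all 15³ IUPAC triplets, discards any
whose expansion contains a stop, and ranks by: exact covers first, then
fewest missing target residues, fewest off-target residues, smallest total
variation distance between the codon-implied amino-acid distribution and the
target frequencies (uniform when unspecified), fewest codons, lexicographic
triplet. The full co-optimal tier is returned because several triplets are
often equivalent (`WTK`/`WTS` for F/L/I/M); which of these the original
authors preferred follows no stated rule, so the tier's first element is a
deterministic, not a historical, choice. Fixed residues use a defined-codon
table defaulting to the codons of the worked primer (W=TGG, E=GAA, C=TGT,
A=GCA; common E. coli codons elsewhere).

Extending a 14-mer family to the 20-mer focused format adds six fully
randomized positions split 3+3 between the ends by default (configurable per
end). Diversity statistics use the uniform library model: match probability
of a logo = product over positions of |favored ∩ allowed| / |allowed|.

## Biophysics

The ternary system A (presenter) + H (Helicon) + T (target) obeys
`AH = A·H/K_AH`, `TH = T·H/K_TH`, `ATH = α·A·T·H/(K_AH·K_TH)` plus the three
mass balances. The solver eliminates free A in closed form, finds free T by
Brent bracketing on [0, T₀] (the total-T residual is strictly increasing in
free T), and wraps this in a second Brent search for free H on [0, H₀]. Both
residuals are monotone, so the physical root is unique and the solver is
deterministic and globally convergent; mass balances hold to ~1e-14
relative in practice (tested at 1e-9).

Percent ternary complex = 100 × R_max,obs / R_max,expected with
R_max,expected = R_immob × (MW_Helicon + MW_analyte) / MW_immobilized. The
source protocol's sentence inverts this ratio ("expected divided by the
experimental response"), which would make near-complete complex formation
read as ~1 rather than ~100%; observed/expected is implemented because it
reproduces the percent-scale values that the protocol reports. The Helicon's
mass is included in the expected response by default (2–3 kDa; excludable).

Dose-response: 4PL with variable slope; the biphasic form is the product of
an ascending and a descending logistic sharing plateau and slope (the
commercial "biphasic" function is proprietary), whose peak for equal slopes
sits at the geometric mean of the two EC50s. Monotone data trip a fallback
to 4PL with a flag rather than an unconstrained two-EC50 fit.

## The synthetic-data generator

`simulate_screen` emulates: a sampled background of the naive library
(default 10⁵ members standing in for 10⁸ — the analysis operates on observed
sequences, so only the sequenced sample size matters at fixed depth); planted
binders with explicit binary constants and cooperativity; per-well capture
weight = baseline + 100 × equilibrium fraction of the clone bound to
bead-displayed target (TH + ATH from the ternary model at a trace clone
concentration, presenter free at 10 µM where present); multinomial read
counts at 10⁶ reads/well with the spike-in fixed at 2% of reads. Default
planted parameters: trimerizers K_AH = 1 µM, K_TH = 100 µM, α = 500
(capture enrichment ≈ 40-fold presenter-dependent); binary binders
K_TH = 0.5 µM, no presenter arm. The default plate mirrors the screening
layout: target titrated at 0.1 and 1 µM with presenter (duplicates),
target-only duplicates at the top concentration, and blank beads with and
without presenter.

What the generator does **not** model: phage propagation and display bias,
panning-round dynamics, PCR chimeras/indels (errors are uniform
substitutions), well-to-well spike-in pipetting noise, and real sequence
composition biases. Passing end-to-end tests therefore demonstrates that the
statistics recover planted equilibrium-driven enrichment under multinomial
sampling — not that the thresholds are optimal for any particular real
campaign. The naive 14-mer scaffold places the staple cysteines at positions
4/11 and scaffold alanines at 7/8 (the i,i+7 spacing and adjacent alanines
of the worked 20-mer design); the parent library's actual coordinates are
not printed anywhere we could consult.

## Problem sizes

Tests and the acceptance script run the full-scale screen (10⁵ background,
10⁶ reads/well, 8 wells) in about two seconds per seed; five seeds are used
for recovery statistics. FASTQ round-trips use small tables (~10³–10⁴ reads)
since the read path is linear and the property being checked is exactness,
not throughput.

## Known limitations

- Equal-length, staple-aligned clustering only; no gapped alignment.
- No enrichment p-values/FDR — hit calling is a plain fold-change rule.
- The distance/linkage stand-in above may split or merge families
  differently from the original campaign's clusterer.
- Spike-in identity and input fraction are modeled, not measured.
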