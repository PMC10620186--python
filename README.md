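# heliscreen

Analysis pipeline for differential phage-display screens that discover
**trimerizers**: cysteine-stapled α-helical peptides (Helicons) that bind a
target protein only in the presence of a second, "presenter" protein (here an
E3 ubiquitin ligase), cooperatively bridging the two. The package is aimed at
screeners running M13KE stapled-peptide display campaigns and at anyone who
needs the downstream machinery — differential enrichment scoring, sequence
family logos, degenerate-codon library design, ternary-complex equilibria —
for similar molecular-glue discovery work.

## What it computes

**Hit strength.** Per-well amplicon reads are quality-filtered (every insert
base at Phred ≥ 18), the constant-flanked insert is extracted and translated,
and peptides matching the library design are tallied. Counts are normalized
by each well's spike-in count. For a peptide *i*, with `n(i, w)` the
spike-normalized count in well *w*,

```
hs_target(i)  = n(i, top-conc target + presenter) / mean_reps n(i, target, no presenter)
hs_counter(i) = n(i, top-conc target + presenter) / mean_reps n(i, blank beads + presenter)
```

with a pseudocount of 0.5 replacing a zero denominator. A **trimerizer hit**
requires both fold-changes > 5: peptides that bind the target without the
presenter sit near `hs_target = 1`, and bead/presenter binders are removed by
the counter screen.

**Families and focused libraries.** Hits are clustered (BLOSUM62 positional
similarity, average linkage) into families; each family logo's positions are
classified *fixed* (top residue ≥ 0.9), *partial* (smallest residue set
reaching cumulative 0.75, size 2–5), or *free*. The classification becomes a
primer: fixed positions get defined codons, partial positions the best
semi-degenerate IUPAC codon (exhaustive search over all 3375 triplets, stop
codons excluded — e.g. `WTK` → F/L/I/M, `TWT` → Y/F, `RTT` → V/I), and free
positions an `X` (one trimer-phosphoramidite codon over the 16 residues
excluding C/K/P/G). Coverage statistics report how many library members are
expected to match a logo in a library of 10⁸.

**Biophysics.** A mass-action model of the presenter(A)/Helicon(H)/target(T)
ternary equilibrium with cooperativity α (`ATH = α·A·T·H / (K_AH·K_TH)`),
solved by nested bracketed root finding; steady-state 1:1 SPR fits
(`R = R_max·C/(K_D + C)`), percent-ternary from expected vs observed R_max,
and 4PL / biphasic dose-response fits. α = 1 bifunctionals show the
bell-shaped hook effect; cooperative trimerizers rise monotonically over
practical dose ranges.

**Synthetic screens.** `simulate_screen` plants trimerizers, binary binders
and bead binders in a large background, derives per-well capture weights from
the equilibrium model, and draws multinomial read counts — ground truth for
end-to-end validation; `simulate_reads` round-trips the counts through FASTQ.

## Worked example

```
$ python examples/screen_to_hits.py
       peptide  hs_target  hs_counter       mode  is_hit      truth
MTWCNIAAMYCEVL  46.107692   61.163265 trimerizer    True trimerizer
TYICFTAAFSCFLT  43.460432   67.122222 trimerizer    True trimerizer
...
5 trimerizer hits called at threshold 5; planted trimerizers recovered: True
```

The five planted cooperative binders top the table with both fold-changes
far above 5, while background peptides and presenter-independent binders sit
near 1. Other example scripts cover codon picking (`codon_picker.py`),
family clustering into a focused primer (`cluster_and_design.py`), the FASTQ
round trip (`fastq_roundtrip.py`) and the hook effect (`ternary_hook.py`).
A thin CLI mirrors the scripts: `heliscreen simulate|count|hits|cluster|design|codon|fit`.

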