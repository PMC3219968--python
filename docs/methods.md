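# Methods

## Problem and model

`mesoscan` classifies the evolutionary relationship between two genome
assemblies into one of three whole-genome synteny classes, each with a
degraded sub-state:

* **macrosynteny** — chromosome-scale co-linearity, visible as long
  diagonals on a dot plot;
* **mesosynteny** — conservation of gene *content* within homologous
  chromosomes with randomized gene order and orientation, visible as
  dots confined to boxes with no diagonals (the pattern characteristic
  of filamentous Ascomycete fungi, especially the Dothideomycetes);
* **no synteny** — matches scattered at random.

The input is the coordinate list of translated-DNA matches between the
two assemblies (MUMmer `promer --mum`, repeat-filtered with
`delta-filter -g`, exported with `show-coords`), plus the sequence
lengths of each assembly. Sequences shorter than 500 kb are discarded
before any statistic is computed; a boundary-length sequence of exactly
500,000 bp is retained. All coordinates are 1-based inclusive and
interval length is `end − start + 1`, so no off-by-one arises against
MUMmer's conventions.

## Significance of pairwise conservation

Every retained sequence pair (a from genome A, b from genome B) that
shares at least one match is tested. With interval-union conserved
lengths (overlaps counted once),

    x = (conserved in a × conserved in b) / (len(a) × len(b))
    p = (total conserved in A × total conserved in B)
        / (total length A × total length B)

the probability of synteny is the one-tailed cumulative binomial

    P_syn = P(X ≤ k),  X ~ Binomial(n = 100, p),  k = round(100·x),

computed by direct summation in log space with exact binomial
coefficients (relative error ≲ 1e-13; no normal approximation). A pair
is significantly conserved when `P_syn ≥ 0.99` and it has non-zero
conserved length on both axes — a pair with no observed conservation is
never treated as evidence of synteny, however permissive the
background. Rounding of `n·x` is half-up and the inequality is `≤`;
both conventions are isolated in `conservation.p_syn` /
`conservation.binomial_cdf` so either could be flipped in one place.
Genome-wide totals use per-sequence unions over *all* matches of a
sequence, so a base matched to two partners counts once. No
multiple-testing correction is applied across pairs.

A structural property of these formulas worth knowing: if every
chromosome of both genomes is conserved to exactly the same degree and
partitions one-to-one, then x = p for the true pairs and P_syn ≈ 0.5 —
no pair tests as significant. The test's contrast comes entirely from
heterogeneity in per-chromosome conservation (unconserved or
lineage-specific chromosomes, unequal coverage), which real genomes
always have; the simulator reproduces it explicitly (below). For the
same reason a self-comparison is modelled as what an aligner actually
emits — full-length self-matches (x = p = 1, P_syn = 1) — not as
gene-granular matches.

## Co-linear regions

For each significant pair, matches are densified into scatter points
(one point every 1 kb along each match, plus the exact endpoint; the
partner coordinate is interpolated linearly, descending for
anti-parallel matches). Windows of 20 kb, stepping by 2 kb and anchored
at position 1 (the grid phase is otherwise arbitrary; anchoring at 1
makes the scan deterministic), slide along the axis of sequence a. A
window is co-linear when it contains ≥ 15 points with R² ≥ 0.9, where
R² is the squared Pearson correlation of the two coordinates (identical
to the OLS coefficient of determination; direction of regression is
immaterial for R², and the reported slope regresses the partner axis on
the scan axis). Windows with fewer than two distinct positions or zero
variance on either coordinate have undefined R² and are never
co-linear. R² is orientation-blind: inverted segments are negative-slope
diagonals and still count as co-linear.

Windows holding ≥ 15 points that *fail* the R² test are **blocking**:
they are positive evidence against co-linearity. Co-linear windows are
trimmed to exclude the spans of overlapping blocking windows (when a
blocking union splits a window, the maximal left and right remainders
are kept). Trimmed co-linear windows within 50 kb of one another merge
— pooling their points plus any intermediate points between them and
refitting the slope — when the signed ratio of their slopes lies
strictly in (0.8, 1.2). Opposite-sign slopes never merge (ratio < 0),
preserving inversion breakpoints, and a merge is refused when a
blocking span lies in the gap. The distinction between blocking and
merely sparse windows is what makes the 50-kb rule coherent: every
coordinate of the axis is covered by some window, so if *any*
non-co-linear window forbade bridging, nothing could ever merge across
a gap; if none did, regions could overlap windows that actively
contradict them. Data-free gaps (unaligned stretches) may be bridged;
data-bearing contradictions may not. Merging proceeds left-to-right to
a fixed point. Surviving windows of ≥ 5 kb become *syntenic regions*;
the scan is repeated along the axis of sequence b and regions from both
axes are pooled.

## Classification

With `N_scp` significant pairs and `S_a`, `S_b` retained sequence
counts, the **significant pair ratio** is `N_scp / min(S_a, S_b)`: under
perfect whole-genome synteny with unequal scaffold counts the expected
number of conserved pairs is the smaller count, which scores the
identity comparison exactly 1. (The published prose defines the ratio
verbally as observed over expected; this reconstruction satisfies every
verbal constraint but the original display is not recoverable, so the
formula is isolated in `classification.significant_pair_ratio`.) A
ratio < 0.25 means no whole-genome synteny. Otherwise the mean syntenic
region length over all significant pairs and both axes decides: ≥ 20 kb
is macrosynteny, less (including zero regions — boxes with no
diagonals) is mesosynteny.

**Pair exclusivity** for a significant pair is
`C_ab / (C_Ab + C_aB − C_ab)`, where `C_ab` is the conserved length
between a and b, `C_Ab` between a and all of genome B, and `C_aB`
between b and all of genome A, each an interval-union length summed
over both projections of the pair. This is the fraction of the pair's
row-and-column conserved length residing inside the box. An alternative
reading, `min(C_ab/C_Ab, C_ab/C_aB)`, is available via
`ClassifierConfig(exclusivity_mode="min")`. Synteny is **degraded** when
the maximum exclusivity over significant pairs is < 0.75 (the literal
rule; a per-box variant — degraded when fewer than a configurable share
of pairs are exclusive — is available via `degraded_mode="share"`).

All thresholds (500 kb / 0.99 / 0.25 / 20 kb / 0.75, and the window
parameters) are configuration with the published values as defaults.
The classification is deterministic and symmetric under swapping the
two genomes.

## The simulator

`mesoscan.simulate` generates genome pairs descended from a common
synthetic ancestor so the pipeline is testable without genome
downloads. The ancestor is an ordered gene map: by default 8
chromosomes × 300 genes of 1500 bp separated by 1-kb spacers (~750 kb
per chromosome, all passing the 500-kb filter; a full classify run
takes well under a second). Each lineage then experiences, in order:
divergence of designated *private* chromosomes (their genes become
lineage-specific and emit no matches — emulating conditionally
dispensable chromosomes), gene loss (per-gene Bernoulli), inversions
(random intra-chromosomal segment reversal with strand flip, breakpoints
in intergenic space only so genes are never truncated), and
translocations (a segment of 1–10% of the source chromosome's genes
excised and inserted elsewhere). Every random choice is recorded in a
truth log whose replay reproduces the derived genome exactly. Matches
are emitted at gene granularity — one match per gene surviving in both
lineages, orientation from the strand product — reflecting that
translated-DNA dots correspond overwhelmingly to genes.

Scenario rates are chosen to separate the classes cleanly, not
inferred from any organism:

| scenario | chromosomes (private) | inversions/chr | translocations | loss |
|---|---|---|---|---|
| `colinear` | 8 (2) | 0 | 0 | 5% |
| `inversion_only` | 8 (2) | 900 | 0 | 5% |
| `translocation_rich` | 8 (2) | 0 | 60 | 5% |
| `unrelated` | 8 (0) | — | — | — |
| `degraded_meso` | 12 (8) | 900 | 60 | 5% |

`unrelated` places 600 gene-sized matches uniformly at random
(length-proportionally) between two independent genomes. 900 inversions
on a ~285-gene chromosome cut each gene adjacency ~6 times per lineage,
leaving essentially no co-linear runs — gene content is conserved per
chromosome (the definition of mesosynteny) while order and orientation
are random. 60 translocations move roughly half of each genome's
content off its natal chromosome, which destroys pair significance or
exclusivity. The `degraded_meso` regime sits, by construction, on the
biological boundary where degraded mesosynteny shades into no synteny;
some seeds legitimately classify as "None".

What the simulator does **not** model: nucleotide-level evolution
(percent similarity is an assigned label, not simulated divergence),
sub-gene alignment fragments, repeat-induced point mutation, paralogy,
lateral transfer of real sequence, or assembly artifacts. Passing the
simulation tests therefore demonstrates that the statistics and decision
rules behave as specified on idealized match sets of known history —
not that any particular pair of real genomes would classify identically;
real inputs should come from the promer tool chain.

## Numerical and design choices

* Binomial CDF: log-space summation over exact `math.comb`
  coefficients, clamped to [0, 1]; accuracy ~1e-13 relative, verified
  against exact rational summation in the tests. Intended for the
  n = 100 regime; very large n would warrant an incomplete-beta
  formulation.
* Window statistics: globally centered prefix sums give every window's
  R²/slope in closed form (~1e-11 worst-case cancellation error at
  chromosome-scale coordinates, verified against `scipy.stats.linregress`
  at 1e-9); degenerate windows (variance below the smallest value two
  distinct integer positions can produce) are marked undefined.
* Ties and order: pairs are processed in sorted id order; window
  merging is deterministic left-to-right; all simulator draws come from
  one seeded `numpy` generator, so `(scenario, seed)` identifies an
  experiment completely.
* Degenerate inputs: an empty genome after filtering raises
  (classification is impossible); empty match sets classify as "None";
  a pair with no matches is simply absent from the pair list.
* Problem sizes in the test suite and acceptance script (20 seeds per
  scenario, 300-gene chromosomes, 1000 random regression point sets)
  are the package's chosen study conditions: large enough that the
  class-recovery rates are stable, small enough that the whole suite
  runs in about a minute.

## Known limitations

* The significant-pair-ratio and pair-exclusivity formulas are
  reconstructions from prose constraints (see above); both are isolated
  and configurable.
* `show-coords` parsing supports the default and `-T [-H]` layouts
  without extra column flags (`-c`, `-l`, `-k` add columns the parser
  does not expect).
* Orientation is parsed and plotted but deliberately never used by the
  classifier.
* Real-genome comparisons require running MUMmer externally; the
  package consumes its output and does not reimplement alignment.
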