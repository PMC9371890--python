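# Methods

## The model

Somatic hypermutation (SHM) deposits point mutations across the rearranged
immunoglobulin heavy-chain variable region of germinal-center B cells. The
initiating lesion is AID deamination of cytosine, preferentially in WRC
trinucleotides (GYW on the opposite strand); downstream error-prone
processing of the U:G mismatch spreads mutations onto A:T pairs,
preferentially at polymerase-eta WA/TW dinucleotide motifs. The balance
between G:C and A:T mutagenesis, and between hotspot and non-hotspot sites,
is therefore a readout of the mismatch-repair machinery acting on the AID
lesion. Class-switch recombination (CSR) resolves AID-induced double-strand
breaks between switch regions; the microhomology/insertion structure of the
sealed Sμ–Sγ3 junction is the analogous readout of end-joining pathway
choice.

Three estimation problems follow, and this package implements each as a
stand-alone module behind a common pipeline:

1. recover the set of distinct sequenced molecules from redundant,
   error-containing read pairs (UMI consensus);
2. estimate per-subtype mutation frequencies that are not inflated by
   clonal expansion and not confounded by base composition (clonal
   resampling with composition normalization);
3. assign each switch junction a single signed score (+k microhomology, 0
   blunt, −m insertion) and compare score distributions and insertion
   frequencies across genotypes.

## Site classification

Every germline position receives exactly one subtype from its germline
context: `GC_AID_HOT` (C in WRC or G in GYW), `GC_OTHER`, `AT_POL_HOT`
(A in WA or T in TW), `AT_OTHER`. Context windows that extend past either
sequence end never match, so terminal bases fall into the `_OTHER`
classes. Classification uses the *germline* context even for mutated
sequences: hotspot-ness is a property of the target site, not of the
mutated product. Because WRC↔GYW and WA↔TW are mutual reverse complements,
the hotspot site counts are invariant under reverse complementing the
reference (a property test asserts this).

## The resampling statistic

Counting every sequence once would count a mutation inherited by an
expanded clone once per member, overstating the underlying number of
independent mutational events. Instead, each of `n_iterations` (default
1000) rounds draws one member uniformly from every CDR3-defined clone and
tallies mutations per subtype. The normalization `f_s = N_s / (S_s ·
n_seq)` divides by the number of site-opportunities of subtype `s` in the
sampled set; since a site mutates at most once per molecule, `f_s ∈ [0,1]`
and the estimate is interpretable as a per-site per-sequence mutation
probability, directly comparable between AT- and GC-rich subtypes. The
aggregate report is the arithmetic mean across iterations with the sample
SD and the 2.5–97.5 percentile interval as the resampling spread. When a
subtype has no eligible sites its frequency is reported as missing (NaN),
never as 0.

Positional profiles accumulate, per position, the number of
iteration×sequence events with a mutation there, then rescale within each
subtype so the most-hit position of every non-empty subtype is 1.

Genotype contrasts build, per subtype (or pooled), the 2×2 table of
rounded mean mutated opportunities vs. the remaining opportunities and
apply the chi-squared test with the Yates correction, clamping
`|O−E|−0.5` at 0 so identical tables give statistic 0 and p = 1. Contrasts
with a zero expected cell are flagged not computable. These are design
choices where the procedure was genuinely open: the contrast defaults to
per-subtype tables (a pooled mode is exposed), and cohorts are pooled per
genotype rather than averaged per animal.

## Junction decomposition

Scoring finds the longest junction prefix occurring contiguously in the
donor and the longest suffix occurring in the acceptor (leftmost
occurrence on ties). Prefix and suffix overlapping by k bases ⇒ +k;
abutting ⇒ 0; separated by g bases ⇒ −g with the gap reported as the
untemplated insert. Because any admissible prefix is a prefix of the
longest one (and likewise for suffixes), this greedy rule maximizes the
microhomology and minimizes the insertion over all decompositions — the
tests verify equivalence against exhaustive enumeration. Junctions whose
anchors fall below `anchor_min` (default 10 bases) are reported
unresolved and excluded from distributions rather than guessed. The
decomposition identity `prefix + |insert| + suffix − overlap = length`
holds for every resolved junction. Exact matching replaces
sequencing-error-tolerant alignment by design; junctions with errors in
their anchor regions will shorten the anchors and, at worst, become
unresolved rather than silently mis-scored.

Kruskal–Wallis on the signed scores uses tie-corrected ranks; with a
pooled sample of ≤ 12 observations the p-value is computed by exact
permutation enumeration (the chi-square approximation is unusable there),
otherwise asymptotically. Dunn's pairwise z tests share the tie-corrected
rank variance; pairwise p-values are unadjusted by default with Bonferroni
available. Fisher's exact test on insertion counts is two-sided with the
conditional-MLE odds ratio; a zero margin returns p = 1. Relative CSR
efficiency rescales per-animal switched fractions so the reference
(wild-type-like) group mean is 100%.

## The synthetic-data generator

The generator is first-class, tested code: it defines the study conditions
under which every acceptance property is evaluated.

* **Germline**: random 294-base sequence (the span of the murine VH186.2 V
  region) at configurable G+C content, with an FR/CDR layout and a 15-base
  CDR3 tag interval. The tag is clone-specific random sequence giving exact
  clonal truth without modeling V(D)J junction biology; it is excluded from
  all spectra.
* **Repertoire**: clone sizes default to Geometric(0.5) (many singletons,
  occasional expanded clones). Each clone draws founder mutations at
  `inherited_fraction` (default 0.25) times the per-subtype rates, shared
  by all members; members add private mutations at the complementary rate
  at sites not already mutated, so each site mutates at most once per
  molecule (no back-mutation, matching the frequency bound of 1) and the
  marginal per-site rate stays at the configured value. Preset profiles:
  wild-type-like (0.02/0.005/0.015/0.003 for GC-hot/GC-other/AT-hot/
  AT-other), plus nuclease-dead-like and knockout-like presets with
  collapsed A:T and elevated G:C mutagenesis. Substitution targets default
  to uniform over the three non-source bases.
* **Reads**: fragment = UMI + molecule; mates overlap by ~60 bases;
  substitution errors are i.i.d. per base (default 0.001). UMI bases are
  error-free by default because collapse is by exact UMI identity with no
  error correction. UMI length 8 and 3 read pairs per molecule are
  defaults chosen here (depth and barcode design are not dictated by the
  analysis).
* **Junctions**: breakpoints for microhomology junctions are sampled from
  positions where the two references naturally share an exact k-mer whose
  flanking bases differ, so the engineered label is exactly recoverable;
  blunt and insertion junctions enforce the analogous local
  non-extendability conditions. Random 400-base references bound attainable
  microhomologies at ~8 bp — real switch regions are repeat-rich and
  support far longer microhomologies, which this generator deliberately
  does not reproduce.
* **CSR counts**: per-animal switched fractions are Binomial(n_cells,
  p_switch)/n_cells draws with cohort sizes 8/8/5 animals.

What the generator does **not** emulate: indels, quality-dependent or
context-dependent sequencing error, PCR duplicates and chimeras, UMI
collisions/errors, biological V(D)J recombination, selection during the
germinal-center reaction, and repeat-rich switch-region structure. Passing
recovery tests therefore demonstrates correctness of the computations
under the stated generative model, not robustness to every artifact of
real libraries.

## Numerical and procedural choices

* One top-level integer seed derives all per-stage, per-genotype seeds via
  `numpy` `SeedSequence`; identical configuration and seed reproduce every
  output byte for byte.
* Coordinates are 0-based half-open internally and 1-based inclusive in
  every report file.
* Read merging scans all overlaps ≥ `min_overlap` (default 10), keeps the
  fewest-mismatch overlap (longest on ties), resolves disagreements by
  higher base quality with ties going to read 1, and rejects pairs whose
  best overlap exceeds `max_mismatch_frac` (default 0.1).
* Consensus ties vote `N`; `N` positions are skipped by mutation calling,
  so a sequencing tie can never fabricate a mutation.
* Sequences whose mismatch fraction against germline exceeds 0.2 are
  rejected as misassemblies; any length difference rejects the record
  (substitution-only model).
* `proportion_percent` rounds half away from zero.
* Per-iteration SDs are reported as exactly 0 when every iteration yields
  the same value (singleton-clone repertoires).
* Rejected records are never dropped silently: each carries a reason code,
  and every pipeline stage reports input = passed + rejected.

## Problem sizes

Default analyses run at desk scale: repertoires of a few hundred clones
(~300–1000), 1000 resampling iterations, 40 junctions per cohort (above
the >22 per group of the motivating design), and 400-replicate null
simulations for the calibration checks. All sizes are configuration
parameters and scale up without code changes.

## Known limitations

* Exact CDR3 identity defines clones; the IMGT clonotype convention
  (anchor-delimited CDR3, allele assignment) is not reimplemented, which
  may alter clone granularity on real data.
* Junction scoring has no mismatch-tolerant mode; error-containing real
  junctions resolve only if their anchors remain exact.
* The chi-square contrast construction (rounded mean opportunities) is one
  explicit, reproducible choice among several defensible ones; with the
  Yates correction it is conservative under the null (verified by
  simulation).
* A junction carrying both a microhomology and an adjacent insertion is
  scored by the max-microhomology-first tie-break and is not separately
  flagged in statistics.
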