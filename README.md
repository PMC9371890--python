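# shmcsr

Analysis of the two programmed DNA-diversification reactions of germinal-center
B cells — somatic hypermutation (SHM) of the immunoglobulin heavy-chain
variable region and class-switch recombination (CSR) — from amplicon
sequencing data, for researchers comparing mutational spectra and
switch-junction repair signatures across mouse genotypes (e.g. mismatch-repair
or end-resection mutants).

The package implements three analyses plus a fully seeded synthetic-data
generator that emulates the study design end to end:

1. **UMI-collapsed VH repertoire reconstruction.** Paired reads are merged by
   best suffix/prefix overlap, grouped by their unique molecular identifier
   (UMI), and collapsed to one majority consensus per input molecule (ties
   vote `N` and are never called as mutations).

2. **Clonal-resampling SHM spectrum.** Consensus sequences are compared
   position-by-position to the germline V reference; each mutated site is
   classified by its germline motif context into AID hotspots (WRC/GYW, with
   W={A,T}, R={A,G}, Y={C,T}), other G:C sites, polymerase-eta hotspots
   (WA/TW), and other A:T sites. Sequences sharing a CDR3 nucleotide sequence
   form a clone; for each of *T* iterations (default 1000) one sequence is
   drawn per clone, so mutations inherited within a clonal lineage are counted
   once rather than once per member. Per iteration the frequency of subtype
   *s* is normalized to its potential maximum,

       f_s = N_s / (S_s · n_seq),

   where *N_s* counts sampled mutations of subtype *s*, *S_s* the eligible
   germline sites of that subtype, and *n_seq* the clones sampled — correcting
   for base composition so the four subtypes are directly comparable.
   Genotype contrasts use Pearson's chi-squared test with the Yates continuity
   correction on 2×2 mutated/unmutated opportunity tables; positional
   profiles are rescaled within each subtype to a maximum of 1.

3. **Switch-junction scoring.** Each Sμ–Sγ3 junction is decomposed exactly
   against the donor and acceptor references: score 0 for a blunt joint, +k
   for a k-base microhomology (sequence shared by both ends, written once),
   −m for m untemplated inserted bases. Cohorts are compared with the
   tie-corrected Kruskal–Wallis test plus Dunn's post tests, insertion
   frequencies with Fisher's exact test, and ex-vivo switching efficiencies
   are reported relative to the wild-type group mean (defined as 100%).

## Worked example

```python
from shmcsr import PROFILES, make_germline, simulate_repertoire, simulate_reads
from shmcsr.umi_consensus import process_read_pairs
from shmcsr.annotation import annotate_all
from shmcsr.spectrum import SpectrumConfig, aggregate

germline = make_germline(294, gc_fraction=0.5, seed=17)
mols, truth = simulate_repertoire(germline, PROFILES["WT-like"], n_clones=300, seed=17)
pairs, _ = simulate_reads(mols, seed=17)
consensuses, rejected = process_read_pairs(pairs)
annotated, _ = annotate_all(consensuses, germline)
result = aggregate(annotated, germline, SpectrumConfig(n_iterations=1000, seed=17))
print(f"{len(mols)} molecules -> {len(consensuses)} consensus sequences -> {result.n_seq} clones")
for s in result.subtypes:
    print(f"{s:11s} mean={result.mean[s]:.4f} sd={result.sd[s]:.4f} sites={result.site_counts[s]}")
```

prints

```
562 molecules -> 562 consensus sequences -> 300 clones
GC_AID_HOT  mean=0.0198 sd=0.0007 sites=32
GC_OTHER    mean=0.0052 sd=0.0002 sites=118
AT_POL_HOT  mean=0.0163 sd=0.0004 sites=60
AT_OTHER    mean=0.0032 sd=0.0002 sites=69
```

All 562 simulated molecules were recovered as UMI consensuses and collapsed
into the 300 simulated clones. The per-site mutation frequencies recover the
wild-type-like generator profile (0.02 / 0.005 / 0.015 / 0.003): AID-hotspot
cytosines and guanines mutate ~4× more often than other G:C sites, and
polymerase-eta WA/TW adenines/thymines ~5× more than other A:T sites. The
`sd` column is the spread across the 1000 clonal resampling iterations.

The same pipeline is available from the shell:

```bash
shmcsr run-all -o out --seed 17       # simulate -> consensus -> annotate -> spectrum -> junctions
shmcsr validate my_config.yaml        # check a YAML configuration
```

which writes TSV tables (spectrum, positional profile, contrasts, junction
scores), a statistics JSON and a run report with per-stage record accounting.

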