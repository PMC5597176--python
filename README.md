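# cpsa — chromatin particle spectrum analysis

`cpsa` maps the chromatin landscape from paired-end MNase-seq at *particle
size* resolution. Micrococcal nuclease degrades DNA that is not protected by
a bound protein, so the insert length of each sequenced pair reports the size
of the particle that protected it: sub-nucleosomal particles (**subNSP**,
< 120 bp — transcription factors, initiation complexes), mono-nucleosomes
(**NSP**, ~150 bp), and partially digested arrays of N nucleosomes
(**multiNSP**, ~N·150 + (N−1)·30 bp including linkers). Comparing *limited*
against *complete* digestion further exposes labile structures — most
prominently a fragile −1 nucleosome just upstream of transcription start
sites (TSS) — that complete digestion destroys before they can be observed.

The package is written for regulatory-genomics analyses that link these
size-resolved occupancy maps to transcription: TSS/CSS-aligned aggregate
profiles, per-bin correlation of occupancy with digestion level,
expression-quartile and subNSP-peak-kurtosis analyses, subNSP vs expression
log2 fold-change linkage with a loess trend, genome-wide subNSP position
calling with distance-to-CDS statistics, and strand-aware aggregation over
transcription-factor binding site (TFBS) catalogs.

## What it computes

For retained fragments (20 bp – 1 kb) with length *L*:

- class(*L*) = subNSP if *L* < 120; otherwise nucleosome order
  *N̂* = round((*L* + linker) / (nucleosome + linker)) with nucleosome = 150,
  linker = 30 (mono if *N̂* = 1);
- **midpoint tracks**: dyad positions from fragments with *L* ∈ 150 ± 15;
  subNSP footprint tracks from *L* < 120;
- **coverage tracks**: per-base protection depth of all fragments ≥ 120 bp
  (interpolating between the sequenced pair ends);
- **digestion index**: mono fraction of nucleosome-scale fragments,
  |{*L* ∈ [120, 180]}| / |{*L* ≥ 120}| — monotone in digestion completeness;
- **fragile-nucleosome tests**: Welch t on mean window occupancy
  ([−125, −75) and [+75, +125) around the TSS) between digestion groups, and
  per-10-bp-bin Pearson *r* between digestion index and NSP occupancy;
- **recruitment statistics**: Fisher excess kurtosis of subNSP midpoints in
  the TSS window [−250, +50], quartile analyses, and per-gene
  log2(CPM_light / CPM_dark) of windowed subNSP abundance.

A first-class synthetic-data module simulates the whole experiment — a toy
annotated genome, planted nucleosome arrays with a labile −1 and
digestion-sensitive TSS footprints, junction-wise multi-nucleosome linkage,
coupled RNA counts — so every stage is validated against planted ground
truth without any external download. The default experiment mirrors a
2 conditions × 2 digestion levels × 2 replicates design (8 samples).

## Worked example

```python
from cpsa import (
    ToyGenomeSpec, build_toy_genome, plant_landscape, sample_fragments,
    SampleSpec, DigestionSetting, SizeClassScheme, midpoint_track,
    normalize_tracks, digestion_index, call_subnsp_positions,
)

genome = ToyGenomeSpec(chrom_lengths=(("chr1", 100_000),), n_genes=15,
                       gene_length=3_000, intergenic_spacing=2_500)
annotation = build_toy_genome(genome)
landscape = plant_landscape(annotation, seed=1)

scheme = SizeClassScheme()          # subNSP < 120 bp, mono ~150 bp, multi N*(150+30)
low = DigestionSetting("low", p_link=0.55)
high = DigestionSetting("high", p_link=0.10, background_rate=5.0)
for dig in (low, high):
    fs = sample_fragments(landscape, SampleSpec(f"light_{dig.level}", "light",
                                                dig, depth=100_000, seed=7))
    counts = fs.class_counts(scheme)
    print(f"{dig.level:>4} digest: {len(fs):6d} fragments | "
          f"subNSP {counts['subNSP']:5d}  mono {counts['mono']:5d}  "
          f"multi {sum(v for k, v in counts.items() if k.startswith('multi')):5d} | "
          f"digestion index {digestion_index(fs):.3f}")
    if dig.level == "low":
        sub = normalize_tracks(
            midpoint_track(fs, annotation.chrom_sizes, size_window=(20, 119)), len(fs))
        calls = call_subnsp_positions(sub)
        planted = [t.center for t in landscape.templates if t.role == "tss_footprint"]
        hits = sum(any(abs(c.pos - p) <= 20 for p in planted) for c in calls)
        print(f"     called {len(calls)} subNSP positions; "
              f"{hits}/{len(planted)} planted TSS footprints recovered")
```

Output:

```
 low digest:  98317 fragments | subNSP 12984  mono 61847  multi 23486 | digestion index 0.722
     called 15 subNSP positions; 15/15 planted TSS footprints recovered
high digest:  98730 fragments | subNSP  4301  mono 89366  multi  5063 | digestion index 0.942
```

Heavier digestion cleaves oligo-nucleosome fragments to monomers (multi
counts drop, the digestion index rises from 0.72 to 0.94) and strips the
labile sub-nucleosomal particles (subNSP counts drop threefold), while the
caller recovers every planted TSS footprint from the low-digest sample.

## Command line

`cpsa simulate --out run/ --seed 7` writes the 8-sample default experiment
(fragment BEDs, GFF3 annotation, expression/DE/truth tables, manifest);
`cpsa tracks`, `cpsa profile`, `cpsa digestion`, `cpsa quartiles`,
`cpsa kurtosis`, `cpsa fc`, `cpsa subnsp`, `cpsa tfbs` and
`cpsa gene-report` then run the individual analysis stages over that
directory (or any directory with the same layout built from real aligned
fragments). Exit codes: 0 success, 1 validation error, 2 runtime failure.

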