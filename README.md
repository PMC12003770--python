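# resectseq

Genome-wide analysis and simulation of meiotic DNA double-strand-break (DSB)
end resection from strand-specific end-sequencing endpoint maps (S1-seq /
Exo7/T-seq / END-seq style data).

## Who this is for

During meiosis, SPO11 makes DSBs at hotspots; the 5′ strands are then resected,
exposing the 3′ ssDNA tails needed for homologous recombination. End-sequencing
assays record, per strand and per base, how many sequenced ends terminate at
each position: top-strand reads mark rightward resection endpoints, bottom-strand
reads leftward ones, unresected breaks leave reads at the cut sites, and
recombination intermediates leave a "central" signal at hotspot centers.
`resectseq` is for anyone who has (or wants to simulate) such endpoint maps and
needs the standard downstream statistics with full provenance and tests.

## What it computes

Given per-strand bedGraph endpoint tracks and a hotspot table, the pipeline
normalizes to reads per million (RPM), stacks ±3-kb windows around hotspot
centers, co-orients the strands (bottom-strand offsets mirrored about the
center, x → −x), averages across hotspots, and subtracts the background level
measured 2.5 kb from the center. From the resulting genome-average profile
v(x) it reports:

- **Mean resection length** — signal outside [100, 2500] bp is zeroed, the
  window is split into 100-bp bins, and the mean is Σᵢ fᵢ·mᵢ over bin
  fractions fᵢ and midpoints mᵢ ∈ {150, 250, …, 2450} nt.
- **Modal resection length** — argmax of the 151-bp-Hann-smoothed profile
  over [100, 2500] bp.
- **Central:resection ratio** — AUC(−300..+100) / AUC(+100..+2500), the
  relative abundance of recombination-intermediate signal.
- **Strand offset** — centroid(top) − centroid(bottom) of the 51-bp-smoothed
  strand-specific averages within ±400 bp; positive offsets are the
  signature of SPO11 double cutting (only outermost ends are sequenced).
- **SPO11-oligo statistics** — fast/slow size-class fractions around the
  34-nt marker and the dominant (~10 nt) length periodicity by detrended
  autocorrelation.
- **Heatmaps** — strand-specific 40-bp-binned signal per hotspot, locally
  normalized so each hotspot totals 1 across a 4001-bp window, decile-classified.
- **Replicate reproducibility** — percent CV of any statistic across
  replicate libraries.

A mechanistic simulator (`resectseq.synthetic`) generates endpoint libraries
with ground truth under packaged genotype presets (wild type, Mre11-cKO,
nuclease-dead Mre11-cHN, MRN hypomorphs, Exo1DA combinations, Atm-null …):
truncated-gamma resection tracts calibrated to a target mean/mode, unresected
and double-cut molecules, central recombination-intermediate signal, uniform
background, and SPO11-oligo length mixtures. See `docs/methods.md` for the
model and its assumptions.

## Worked example

Simulate a wild-type library (1000 hotspots on a 30-Mb chromosome, 2×10⁵
molecules) and analyze it:

```bash
resectseq simulate --preset wt --seed 1 --out-dir demo --n-molecules 200000
# simulated 312728 reads (1000 hotspots) -> demo

resectseq analyze \
    --top demo/endpoints.top.bedgraph --bottom demo/endpoints.bottom.bedgraph \
    --hotspots demo/hotspots.bed --chrom-sizes demo/chrom.sizes \
    --out-dir demo/analysis --genotype wt
# mean_length=1100.7 nt  modal_length=1030 nt  central_ratio=0.402
```

The wild-type preset's tract distribution has a true mean of 1100 nt and the
simulator's ground truth for this run (`demo/truth.json`) records a realized
mean of 1100.9 nt — the pipeline estimate of 1100.7 nt recovers it to within
a fraction of a percent. The modal length (1030 nt) sits slightly above the
tract-distribution mode (1015 nt) because the within-hotspot cut-position
spread shifts the observed peak; the central ratio (0.402) matches the
preset's configured 0.40. `demo/analysis/` also contains the raw, smoothed
and peak-normalized profiles, the decile heatmap, a double-cut report and a
manifest with the config hash and seed.

SPO11-oligo double-cut ladder:

```bash
resectseq oligos --preset Mre11-cKO --classes double-cut --n 20000 --seed 8 \
    --out-dir demo/oligos
# fast=0.275 slow=0.725 periodicity=10
```

All lengths are ≥33 nt with the diagnostic 10-nt periodicity; the fast
(<34 nt) fraction is just the lowest rung of the ladder.

The same steps are available as library calls (`simulate_dataset`,
`summarize`, `strand_offset`, `estimate_periodicity`, …) — the CLI is a thin
wrapper.

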