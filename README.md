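# hmdnuc

Analysis of nucleosome organization in hypomethylated domains (HMDs):
domain calling from per-CpG methylation, accessible-linker summit
detection, boundary-anchored metaprofiles, autocorrelation spacing
estimation, k-mer SVM prediction of linker positions from sequence,
motif periodicity, and sequence-based equilibrium nucleosome occupancy —
exercised end-to-end on a synthetic chromatin generator with known
ground truth.

## Layout

| module | purpose |
| --- | --- |
| `hmdnuc.genome_io` | domain types (intervals, tracks, genome) and FASTA/BED/narrowPeak/bedGraph/TSV I/O |
| `hmdnuc.hmd` | HMD calling: maximal runs of >=10 consecutive CpGs with methylation ratio < 0.4 |
| `hmdnuc.accessibility` | cut shifting, CPM coverage, lightweight summit caller, HMD/DHS overlap stats |
| `hmdnuc.metaprofile` | boundary anchors (TSS-oriented) and anchor-aligned average profiles; per-base feature tracks |
| `hmdnuc.spacing` | lag-by-lag autocorrelation spacing estimate; 5' boundary linker gap |
| `hmdnuc.svm` | k-mer spectrum SVMs (linker-vs-core and HMD-vs-methylated), window scoring, score-signal correlation, ROC/PR, weight comparison |
| `hmdnuc.periodicity` | top-weight k-mers, within-domain pairwise distance histograms, string reversal control |
| `hmdnuc.occupancy` | hard-rod equilibrium occupancy DP with pluggable energy models |
| `hmdnuc.simulate` | synthetic genome + tracks with ground truth for parameter recovery |
| `hmdnuc.pipeline` / `hmdnuc.cli` | orchestration, report, command-line interface |

## CLI

Every stage is a subcommand of `hmdnuc`; `hmdnuc run` chains them.

```sh
hmdnuc simulate --seed 0 --out sim/
hmdnuc call-hmds --meth sim/meth.tsv --out hmds.bed
hmdnuc summits --cuts sim/dnase_cuts.bed --genome sim/genome.fa --out summits.narrowPeak
hmdnuc profiles --hmds hmds.bed --summits summits.narrowPeak --tss sim/tss.bed \
    --track sim/mnase_dyads.bed --positions --genome sim/genome.fa --out dyads.tsv
hmdnuc spacing --profile dyads.tsv --side hmd
hmdnuc train --hmds hmds.bed --summits summits.narrowPeak --genome sim/genome.fa \
    --mode dnase --holdout-chrom chr4 --out-prefix model
hmdnuc periodicity --model model --hmds hmds.bed --genome sim/genome.fa --out hist.tsv
hmdnuc occupancy --genome sim/genome.fa --model gc:1.0 --out occ.bdg
hmdnuc run --out out/            # full synthetic pipeline -> out/report.json
```

`hmdnuc run --config run.toml` accepts a TOML file with top-level pipeline
keys plus an optional `[synthetic]` section mirroring the generator
defaults; `--seed` overrides the configured seed.

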