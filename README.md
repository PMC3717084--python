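# spectroqtl

Quantitative phenotyping of tissue ATR-FTIR spectra and marker-regression
QTL mapping in recombinant-inbred (RI) mouse panels, plus a synthetic-cohort
generator so the entire pipeline can be exercised and verified offline.

The pipeline turns per-replicate absorbance spectra into macromolecular
traits (fat, collagen, glycogen composite band areas; acyl chain length,
collagen integrity, lipid-to-protein and saturation ratios), summarizes them
per strain, and maps them to genomic loci with permutation-derived
genome-wide thresholds and 1.5-LOD (6.9 LRS) support intervals.

## Modules

| module | what it does |
|---|---|
| `spectroqtl.synthetic` | RI genotype mosaics (map-expansion law R = 4r/(1+6r)), additive component amplitudes with planted QTLs, Gaussian sub-band spectra with baseline/vapor/noise artifacts, cohort writer |
| `spectroqtl.spectrum` | `Spectrum` container, canonical 600–4000 cm⁻¹ / 1 cm⁻¹ grid, two-column text I/O |
| `spectroqtl.preprocess` | water-vapor correction (smoothness-fit reference subtraction), quality test (intensity / vapor residual / SNR), min-max normalization over 1700–1500 cm⁻¹, replicate averaging |
| `spectroqtl.features` | band integration above an endpoint-anchored linear baseline; per-tissue composite and ratio traits from a versioned registry TSV |
| `spectroqtl.traitstats` | 3-SD winsorization, strain summaries, pairwise-complete Pearson correlations with Holm adjustment, broad-sense heritability, ddCt relative expression |
| `spectroqtl.qtl` | single-marker regression scans (LRS = n·ln(RSS₀/RSS₁)), permutation thresholds (p<0.05 / p<0.63), LOD↔LRS conversion, drop-off support intervals, QTL summary |
| `spectroqtl.candidates` | offline candidate-gene filter cascade (location, expression, variant load, cis-eQTL, function keywords) |
| `spectroqtl.pipeline` / `spectroqtl.cli` | stage orchestration with file interfaces, checksummed run log, `spectroqtl` CLI |

## CLI

```sh
# write a synthetic cohort with a planted QTL
spectroqtl simulate --out-dir cohort --n-strains 30 --seed 1 \
    --tissue adipose --qtl adipose:2:30:lipid_CH:0.7

# full pipeline: preprocess -> traits -> stats -> scan
spectroqtl run-all --spectra-dir cohort --manifest cohort/manifest.tsv \
    --geno cohort/panel.geno --out-dir run --seed 1 --n-perm 1000

# individual stages
spectroqtl preprocess --config pipeline.yaml
spectroqtl scan --config pipeline.yaml --n-perm 1000 --drop-lrs 6.9

# candidate-gene cascade on one interval
spectroqtl candidates --gene-table genes.tsv --chrom 12 \
    --start-mb 26 --end-mb 30 --tissue adipose --keyword lipid

spectroqtl convert 1.5            # LOD -> LRS
```

Exit codes: 0 ok, 2 config validation failure, 3 stage failure.

Inputs: spectra are two-column text (wavenumber, absorbance) listed in a
tab-delimited manifest (`file strain animal tissue replicate`); genotypes
use a GeneNetwork-style `.geno` dialect (`Chr Locus cM Mb` + one B/D column
per strain); gene annotations for the candidate cascade are a plain TSV.

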