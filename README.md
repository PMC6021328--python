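# gapstrat

Gene-amplification-profile (GAP) calling and prognostic stratification for
glioblastoma SNP-array copy-number data.

The package implements the full analysis chain as a tested pipeline:

1. **genome model** (`gapstrat.genome`) — cytoband/arm coordinate system and a
   BED6 gene catalog with interval queries (0-based half-open throughout).
2. **synthetic cohorts** (`gapstrat.simulate`) — paired tumor/normal probe
   tracks with planted focal amplicons (>7 copies ≙ >4.8 arbitrary units),
   broad 3–4-copy polyploid gains, germline CNVs shared by both tracks,
   multiplicative-saturation copies→value transform, and survival times whose
   distribution depends on the planted GAP class. Everything is seeded and
   bit-reproducible, with truth tables for recovery scoring.
3. **amplicon calling** (`gapstrat.calling`) — germline masking against the
   paired normal, running-median smoothing, recursive binary segmentation
   (plus a windowed carve-out scan for short interior events), and
   thresholding of segment means at 4.8 arbitrary units so polyploid
   backgrounds are never called.
4. **GAP classification** (`gapstrat.classify`) — per-tumor amplification
   profiles (a "region" is a chromosome arm), the five-class scheme
   (NO_AMP / EGFR_ONLY / NON_EGFR_SINGLE / MULTI_WITH_EGFR /
   MULTI_WITHOUT_EGFR) and the two-level risk grouping.
5. **survival statistics** (`gapstrat.survival`) — from-scratch inclusion
   filtering, Kaplan–Meier with the "smallest t with S(t) ≤ 0.5" median,
   k-group log-rank, Cox proportional hazards (Breslow ties, Newton) and
   univariate-gated forward stepwise selection.
6. **pipeline CLI + study fixtures** (`gapstrat.cli`, `gapstrat.paper`) —
   stage orchestration over plain-text formats and the packaged series-1
   fixtures (45 per-tumor amplified-band profiles plus the 80-patient
   clinical roster) used by `reproduce-paper`.

The bundled annotation (`src/gapstrat/fixtures/cytobands_hg19.txt`,
`genes_hg19.bed`) is an hg19-like plumbing fixture: band boundaries are
approximate, but band/arm membership of every catalog gene is faithful.

## CLI

```bash
gapstrat simulate --n 20 --seed 1 --out out/sim          # synthetic cohort
gapstrat call --probes out/sim/probes.tsv --out out/called
gapstrat classify --amplicons out/called/amplicons.tsv --out out/cls
gapstrat survive --clinical out/sim/clinical.tsv \
                 --classes out/cls/classes.tsv --out out/surv
gapstrat report --stage-dir out/sim --stage-dir out/surv --out out/report.json
gapstrat reproduce-paper --out out/paper                 # fixtures only
```

`classify --seg file.seg` accepts external pre-segmented input; without gene
annotation, EGFR involvement falls back to overlap with band 7p11.2 (logged).
Flags `--theta`, `--min-probes`, `--seed`, `--config` (flat `key = value`
file), `--annotation`/`--genes` and `--log-level` override the defaults; every
stage writes a `provenance.json` describing its effective configuration.

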