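# termwindow

Analysis toolkit for RNA polymerase II occupancy around transcription
terminators, plus a hazard-based occupancy simulator with planted ground
truth.

The package classifies transcription units (snoRNA, CUT, SUT, XUT, NAPC,
protein-coding) as termination-defective in mutant-vs-wild-type coverage
contrasts using a readthrough index, builds anchored metagene profiles and
heat maps, localizes factor recruitment peaks and tests positional shifts
with a paired sign-flip permutation test, computes set-overlap and
proportion statistics, and quantifies amplicon-level ChIP/DIP fold
enrichment.  Because real deposited occupancy data is not bundled, a
mechanistic simulator (survival x dwell along a per-nt termination-hazard
profile, Poisson count noise) generates every input with known per-unit
parameters, so all downstream stages are testable against planted truth.

## Layout

| module | role |
|---|---|
| `termwindow.synthetic` | toy-genome annotation generator, hazard/occupancy model, Monte-Carlo trajectory oracle, Poisson track simulation, fixture I/O |
| `termwindow.tracks_io` | bedGraph read/write, centred moving average, strand-aware anchored window extraction, region means, fold enrichment |
| `termwindow.annotation` | transcription-unit records, BED6 + TSV sidecar, GFF3 read, chrom.sizes |
| `termwindow.metagene` | anchored matrices, metagene profiles, heat maps, peak localization, peak-shift permutation test |
| `termwindow.readthrough` | readthrough index, low-signal filter, defect classification, per-class fractions, pathway assignment |
| `termwindow.setstats` | hypergeometric overlap/Venn, Fisher's exact proportion comparison, BH adjustment |
| `termwindow.chip_quant` | amplicon fold enrichment, phospho/total normalization, time-course ratios |
| `termwindow.pipeline` | config-driven orchestration, validation, manifests |

Coordinates are 0-based half-open genomic positions everywhere; relative
position 0 is the anchor base and positive positions are 3' in transcript
orientation.

## CLI

```sh
# write the packaged demo configuration (200 units, 3 genotypes, 2 temperatures)
termwindow demo-config --out demo.yaml

# check a config
termwindow validate --config demo.yaml

# generate a synthetic fixture only (annotation, bedGraph tracks, truth tables)
termwindow simulate --config demo.yaml --out fixture/

# full run: simulate (or load input_dir), classify, test, report
termwindow run --config demo.yaml --out results/ --seed 1
```

`run` emits per-unit readthrough calls, per-class defective fractions,
overlap/Venn JSON, pathway category counts, metagene TSVs, a factor peak
table with the shift-test result, the snoRNA heat-map matrix with 5'-end
markers, optional amplicon quantification, and `manifest.json` (seed,
config hash, stage timings).  Exit codes: 0 ok, 1 validation failure,
2 runtime failure.

To analyse existing data instead of simulating, point the config at a
directory laid out like a fixture (`units.bed`, `units.tsv`,
`chrom.sizes`, `samples.tsv`, one bedGraph per sample) via `input_dir`.

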