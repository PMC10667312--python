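# File formats

All artifacts are plain text (TSV/JSON). Coordinates in segment-map files
follow BED convention (0-based, half-open); word and junction positions
everywhere else are 1-based.

## Segment map (`map.tsv`)

Tab-separated, `#`-prefixed header line, one row per segment in chromosome
order; rows must tile the chromosome without gaps or overlaps.

| column | meaning |
| ------ | ------- |
| `chrom` | chromosome name (single value per file) |
| `start`, `end` | 0-based half-open coordinates |
| `id` | unique segment label |
| `flags` | `;`-separated: `centromere`, `marker=NAME`, `arm=left\|right\|centromeric`; `.` for none |
| `genes` | `;`-separated gene labels, `.` for none |

## Structure words

One line per structure: `topology<TAB>word`, where topology is `linear` or
`circular` and the word is a comma-separated list of segment ids, a leading
`-` marking reverse orientation, e.g. `circular	S05,-S07,S08`. A JSON form
(`{"topology": ..., "word": [[id, sign], ...]}`) is also read/written.
`structures.txt` prefixes each line with the strain id.

## Evidence directory (per strain)

* `segments.tsv` — `id`, `depth` (synthetic-homolog read depth).
* `junctions.tsv` — `end_a`, `end_b`, `support`; ends are `SEGID.L` or
  `SEGID.R` (left/right segment end in reference orientation).
* `header.json` — `baseline_depth`, `wt_reads`, `syn_reads`,
  `topology_hint`.

## Population table (`population.tsv`)

`strain`, `topology`, `retained_fraction`, `recovery_pct`,
`trisomy_simulated`, `ploidy_flagged`, `n_events_applied`,
`n_events_called`, `call_is_minimal`, `structure`.

## Association scan (`association_scan.tsv`)

`segment`, `n_deleted`, `n_retained`, `mean_deleted`, `mean_retained`,
`effect` (deleted − retained mean recovery, percentage points), `stat`
(Welch t), `p`, `p_perm` (if permutations requested), `tested`, `reason`
(untested segments), `bonferroni_alpha`, `significant`.

## ESR table (`esr.tsv`)

`strain`, `frac_iesr_up`, `frac_resr_down`, `q_up`, `q_down`,
`esr_reversed`.

## Report (`report.json`)

Validated by the shipped JSON schema
(`src/synscramble/schemas/report_schema.json`): provenance (seed, config
hash, package version), population summary (n, mean events, topology
percentages, event-type fractions, molecule size ranges in bp),
ploidy-excluded strains, retention–recovery regression, the association
table, the top association segment, and the ESR table. Byte-identical for
identical (config, seed).

## Growth and colony inputs (optional user data)

* Growth curves: TSV with `time_min`, `od600`; uniform 20-min grid.
* Colony sizes: TSV with `strain`, `colony_mm`.
* Expression counts: TSV, genes × strains.
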