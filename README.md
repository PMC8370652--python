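# wsforecast

Forecasting adaptive mutation spectra in the *Pseudomonas* wrinkly-spreader
(WS) system: mutational target-size enumeration, c-di-GMP pathway logic,
null-model spectrum prediction, static-microcosm evolution simulation,
selection-coefficient estimation from competition assays, and scoring of
hierarchical predictions against observed mutant spectra.

## Layout

| Module | Role |
| --- | --- |
| `wsforecast.gene_models` | gene/operon models, validation, translation, coordinate math |
| `wsforecast.mutation_catalog` | mutation records, effect classification, observed spectra |
| `wsforecast.target_enumeration` | per-gene per-class target sizes; direct-repeat deletion scanner |
| `wsforecast.pathway_model` | Wsp/Aws/Mws network logic; rate-weighted null spectrum |
| `wsforecast.microcosm` | static-well evolution simulator; total-rate estimation |
| `wsforecast.fitness` | selection coefficients from CFU counts; replicate summaries |
| `wsforecast.evaluation` | G test, exact multinomial, rank agreement, region coverage, scoreboard |
| `wsforecast.synthetic` | seeded generators + bundled fixture tables (`wsforecast/data/`) |
| `wsforecast.cli` | `wsforecast` command-line pipeline |
| `wsforecast.pipeline` | convenience wiring of fixtures through the stages |

The bundled fixtures use synthetic stand-in coding sequences whose lengths
match the modelled loci; per-mutant nucleotide coordinates are placeholders
consistent with the gene-level mutation classes (each row carries a note).
Mutation-class counts, pathway assignments and the predicted-region set are
transcriptions of the published summaries.

## CLI

```sh
wsforecast targets   --outdir results        # per-gene per-class target table
wsforecast predict   --outdir results        # null-model spectrum (54/30/16)
wsforecast evaluate  --outdir results        # predictions scoreboard vs fixture
wsforecast all       --outdir results        # targets -> predict -> evaluate
wsforecast simulate  --seed 1 --wells 60 --mu-total 3e-4 --outdir results
wsforecast fitness   src/wsforecast/data/pf5_competition.tsv --outdir results
wsforecast synth     --seed 1 --outdir results
```

All stochastic subcommands require an explicit `--seed`. Exit codes:
0 success, 2 usage error, 3 data-validation error, 4 model error.

Model parameters live in a single YAML config
(`src/wsforecast/data/model_params.yaml`). The frameshift:substitution rate
ratio is the one calibrated parameter; it was fitted once so the predicted
pathway marginals reproduce 54/30/16 and is frozen there with its
calibration record.

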