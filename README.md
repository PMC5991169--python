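# iseeg

Inter-stimulus EEG (isEEG) analysis for laser-evoked potential (LEP)
experiments: band-limited magnitude (RMS) and temporal-variability (nMSSD)
features, per-subject linear fast-pain LEP–pain models, cross-individual
correlation of features with model parameters, and a similarity-weighted
cross-individual pain prediction scheme with leave-one-individual-out
evaluation. A synthetic-data generator produces multi-subject recordings with
an embedded, configurable cross-individual correlation structure so that every
stage is testable without any external data.

## Modules

| module | role |
| --- | --- |
| `iseeg.synthetic_data` | cohort generator: subject traits, stimulus schedules, energy→NRS ratings, evoked-response templates, multichannel recordings |
| `iseeg.preprocessing` | FIR filtering (zero-phase broadband pre-filter; minimum-phase causal band decomposition), inter-stimulus segments, 2-s sub-epochs, peri-stimulus epochs, N2-P2 peak-to-peak amplitude |
| `iseeg.features` | RMS and nMSSD per channel × band via randomized sub-epoch resampling (100 repetitions, 50th percentile) |
| `iseeg.lep_pain_model` | fast-pain trial selection (NRS > 4), subject inclusion (some fast-pain NRS ≥ 7), OLS fit, (a, b) ↔ (c, d) reparameterization |
| `iseeg.correlation_analysis` | Pearson correlation of features with (c, d) across subjects, Bonferroni correction over the full test grid |
| `iseeg.individualized_prediction` | Euclidean feature distances, mean/max weight rule, weighted vs conventional predictions, LOO cross-validation, MAE, paired t-test |
| `iseeg.io` | recording/event containers; plain-text and minimal EDF formats |
| `iseeg.pipeline` | end-to-end composition used by the CLI and the test suite |

## CLI

```sh
iseeg simulate   --config cfg.json --out data/ --seed 1      # synthetic cohort
iseeg preprocess --recording data/S000.txt --events data/S000_events.csv \
                 --channel Cz --out pre/                     # trials + sub-epochs
iseeg features   --recording data/S000.txt --events data/S000_events.csv \
                 --channel Cz --subject-id S000 --seed 1 --out feat.csv
iseeg fit        --trials trials.csv --out models.csv        # per-subject models
iseeg correlate  --features features.csv --models models.csv --out corr.csv
iseeg predict    --features features.csv --trials trials.csv --out pred/
iseeg report     --results pred/
```

`simulate` accepts a `GeneratorConfig` JSON (see
`iseeg.synthetic_data.GeneratorConfig` for fields and defaults) and writes one
recording (`.txt` + `.json` sidecar, or `.edf` with `--fmt edf`) and one event
CSV per subject. `fit`/`correlate`/`predict` consume long-form CSVs that pool
subjects (`subject_id` column), as produced in the examples above.

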