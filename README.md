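# spsp

Spherical phase-space symbolization and template classification for
multichannel physiological recordings.

A channels-by-samples recording is treated as a trajectory in channel space
(sample *n* is the point whose coordinates are the *M* channel values at
*n*). The pipeline:

1. **phase_space** — compute the trajectory's mean point (hypersphere
   center) and the per-sample Euclidean distance from it.
2. **symbolize** — bin the distance series into symbols, either with
   equal-width (*uniform*) or equal-occupancy (*maximum entropy*) bins.
   The alphabet size *S* is selected by sweeping *k* = 2, 3, … and stopping
   at the first *k* whose entropy increment *h(k) = H(k) − H(k−1)* drops
   below a threshold `epsilon_h` (default 0.2, which selects *S* = 8 on
   tie-free data of length 8064).
3. **classify** — build per-class template vectors as elementwise means of
   training symbol sequences, classify test sequences by maximum cosine
   similarity, and evaluate with leave-one-subject-out cross-validation.
4. **synthetic** — generate reproducible datasets whose classes differ
   exactly in the radial-distance distribution the method measures, so the
   whole pipeline is testable without any external data.

## CLI

```sh
# generate a synthetic dataset (CSV trials + JSON manifest)
spsp simulate --spec spec.yaml --out data/

# symbolize every trial; writes per-trial symbol CSVs, the entropy
# profile, and run metadata
spsp symbolize --manifest data/manifest.json --out sym/

# end-to-end: symbolization + leave-one-subject-out evaluation
spsp evaluate --manifest data/manifest.json --out eval/

# pretty-print an evaluation report
spsp report --report eval/report.json
```

A synthetic spec file is a YAML/JSON mapping of `SyntheticSpec` fields,
e.g.:

```yaml
n_subjects: 8
class_labels: [calm, excited]
M: 32
N: 2048
separation: 2.0
seed: 1
```

Run configuration (`--config c.yaml`, overridable by flags) exposes
`epsilon_h`, `S_override`, `partition_scheme` (`max_entropy` | `uniform`),
`k_max`, `selection_mode` (`pooled` | `first_trial`), `index_weighting`
(`per_trial` | `per_subject`), and `seed`. Exit codes: 0 success, 2
usage/config error, 3 data/protocol error. Identical inputs, config and
seed produce byte-identical outputs.

Dataset manifests are JSON:

```json
{
  "channel_count": 32,
  "sample_rate_hz": 128.0,
  "entries": [
    {"file_path": "s01_a01.csv", "subject_id": "s01",
     "trial_id": "a01", "label": "calm"}
  ]
}
```

Matrix files are delimited text with channels in rows (dialect flags
`delimiter`, `has_header`, `has_rownames`, `transpose` are read from the
manifest). For corpora distributed as per-subject
trials x channels x samples arrays,
`spsp.dataset_io.recordings_from_subject_array` adapts them given an
explicit trial-to-label mapping.

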