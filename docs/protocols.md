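# Evaluation protocols for benchmark EEG datasets

The package's tests run entirely on synthetic data. Users who hold a
licensed copy of a multi-subject, multi-session EEG emotion dataset (e.g.
SEED or SEED-IV differential-entropy features: 62 channels × 5 bands = 310
features per 1-second segment, 15 subjects × 3 sessions) can evaluate EDPC
with the three standard cross-validation schemes. In each case export the
features as samples-by-features CSV and the labels as a 1-based integer
column, then run `edpc fit` (or `edpc grid` to tune β, ρ, k) per split and
average the reported target accuracies.

1. **Single-subject cross-session.** For each subject, sessions 1–2 form
   the source domain and session 3 the target. One fit per subject;
   report mean ± s.d. over subjects.

2. **Cross-subject single-session.** Using session 1 only: each subject in
   turn is the target domain, the remaining 14 subjects pooled are the
   source. One fit per held-out subject.

3. **Cross-subject cross-session.** All sessions of one subject form the
   target; all sessions of the remaining subjects form the source. The
   hardest setting — both subject and session shift.

Example for one split:

```bash
edpc fit --source-x src_feats.csv --source-y src_labels.csv \
         --target-x tgt_feats.csv --target-truth tgt_labels.csv \
         --out runs/subject01 --r 30
```

For 310-dimensional features a larger subspace (e.g. `--r 30`) and the
`edpc grid` search over β, ρ ∈ {1e−6 … 1e6} and k ∈ {3, 5, 10, 15, 17} are
recommended; selection by target accuracy requires the truth file and is
an oracle protocol — without labels the grid ranks by final objective.
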