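# semtrf

Semantic speech-tracking analysis of continuous-listening EEG.

When people listen to running speech (an audiobook rather than isolated
sentences), their EEG tracks both acoustic features of the speech and the
predictability of each word. `semtrf` implements the full analysis chain
used to quantify that tracking, aimed at auditory cognitive-neuroscience
researchers studying populations such as cochlear-implant (CI) users:

* **Word surprisal** from a backoff n-gram language model,
  `S(w_k) = −log₂ p(w_k | w_{k−4} … w_{k−1})`, plus validation of
  high-surprisal word-substitution designs (an incongruent word inserted
  roughly every 45 s, surprisal > 20 bits);
* **Stimulus features**: Hilbert speech envelope, word-onset steps, and
  surprisal-scaled steps;
* **Temporal response functions (TRFs)**: the linear kernel
  `y_c(t) = Σ_f Σ_τ w(f,τ,c) x_f(t−τ) + b_c` over lags −100…1000 ms,
  estimated by Tikhonov-regularized regression with leave-one-trial-out
  cross-validation of λ over 2⁻⁵…2¹⁵;
* **Model comparison**: the added prediction accuracy Δr of surprisal over
  the acoustic (envelope + onset) model, tested with a one-sided Wilcoxon
  signed-rank;
* **Cluster-based permutation statistics** over channels × lags (4 cm
  electrode adjacency, cluster mass, Monte-Carlo null);
* **Component measures**: TRF-N1 (50–150 ms minimum), TRF-P2 (150–250 ms
  maximum), and the TRF-N400 of the condition difference wave (200–1000 ms
  minimum, ±10 ms mean amplitude), with Welch t, mixed ANOVA, Spearman+FDR
  and sensitivity analyses;
* **A ground-truth simulator** producing stories, regressors, and
  multichannel EEG (known kernels, group latency shifts, 1/f + white noise)
  so every stage is testable without any data download.

## Worked example

Simulate a small two-group cohort (normal-hearing-like and CI-like
subjects) and run the full pipeline:

```python
from semtrf import PipelineConfig, run_pipeline

config = PipelineConfig(
    out_dir="demo_out", seed=5,
    analysis_rate=64.0, trial_s=20.0,
    lag_window_ms=(-100.0, 800.0), n400_window_ms=(200.0, 800.0),
    lambda_grid_log2=(-2, 10), n_permutations=150,
    simulation={
        "n_per_group": 5, "duration_s": 80.0, "altered_interval_s": 15.0,
        "channels": ["F3", "Fz", "F4", "FC1", "FCz", "FC2", "C1", "Cz", "C2",
                     "CP1", "CPz", "CP2", "P3", "P1", "Pz", "P2", "P4", "POz"],
    },
)
result = run_pipeline(config)
peaks = result["peaks"]
print("group lambda:", result["lambda"])
print("median delta_r:", result["delta_r"]["delta_r"].median().round(4),
      " wilcoxon p:", round(result["wilcoxon"].p, 4))
print(peaks.groupby("group")["n400_latency_ms"].mean().round(1))
```

prints (numbers from this exact run):

```
group lambda: 1024.0
median delta_r: 0.2004  wilcoxon p: 0.001
group
CI    559.4
NH    425.0
Name: n400_latency_ms, dtype: float64
```

Read: the surprisal regressor adds ≈0.20 to held-out prediction accuracy in
this high-SNR simulation (one-sided Wilcoxon p = .001 across the 10
subjects), and the semantic (N400-like) component of the CI-like group
peaks ~134 ms later than the NH-like group — the simulated ground truth
places the kernels at 554.3 vs 427.2 ms. `demo_out/` contains the per-subject
tables (`added_value.tsv`, `peaks.tsv`), cluster test results, group
statistics, brain–behavior correlations, and a provenance log.

The same pipeline is scriptable from the shell:

```bash
semtrf simulate --out demo --seed 3 --subjects 2 --duration 120 --interval 45
semtrf fit --out demo_out --seed 5
semtrf report --out demo_out
```

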