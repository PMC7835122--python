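# conceptbench

A seeded, desk-scale pipeline for a question from computational
neuroscience: once a visual hierarchy has learned many object categories,
which level of its internal representation best supports learning a *novel*
category from a handful of examples?

The package builds a synthetic visual world of part-based categories, trains
a small convolutional hierarchy on 30 "base" categories, taps features at
four depths — a **Conceptual** layer (one pre-softmax unit per learned
category) and three progressively earlier **Generic** layers — and runs a
factorial one-vs-all few-shot benchmark on 10 held-out novel categories.
Performance is the signal-detection index

```
d' = Φ⁻¹(hit rate) − Φ⁻¹(false-alarm rate)
```

per classifier, aggregated over categories with bootstrap CIs and paired
sign-flip permutation contrasts. The headline phenomenon: conceptual
features dominate when only 1–2 positive examples are available, and the
advantage dissolves as examples accumulate — prior *concept* learning is
specifically a few-shot asset.

## Worked example

```python
from conceptbench.pipeline import run_experiment
from conceptbench.stats_report import summarize, contrast

out = run_experiment(seed=7)          # ~4 minutes on one CPU
summary = summarize(out["results"])
print(summary.groupby(["feature_set", "n_pos"])["grand_mean"].first()
             .unstack("n_pos").round(3))
row = contrast(out["results"], "Conceptual", "Generic1", n_pos=1)
print(f"Conceptual - Generic1 at 1 positive: "
      f"{row['mean_diff']:.3f}, p = {row['p_value']:.4f}")
```

prints (seed 7):

```
n_pos                   1      2      4      8      16
feature_set
Conceptual           0.460  1.084  1.485  1.743  2.058
Generic1             0.225  0.927  1.337  1.724  2.087
Generic1+Conceptual  0.313  1.089  1.468  1.779  2.133
Generic2             0.189  1.019  1.528  2.017  2.405
Generic3             0.130  0.799  1.287  1.655  2.003
Conceptual - Generic1 at 1 positive: 0.235, p = 0.0079
```

Read the columns left to right: with a single positive training example the
ordering is Conceptual > Generic1 > Generic2 > Generic3 (deeper wins), and
the Conceptual-over-Generic1 advantage of 0.235 d′ units is significant
under a paired permutation test across the 10 novel categories. By 16
positives the advantage is gone — generic shape features catch up once data
are no longer scarce.

The same pipeline is available as a CLI:

```bash
conceptbench generate --out data/ --seed 7
conceptbench train --data data/ --out model.ckpt.npz --seed 7
conceptbench extract --model model.ckpt.npz --data data/ --tap Conceptual --out feats/Conceptual.csv
conceptbench benchmark --features-dir feats/ --out results.tsv --seed 7
conceptbench report --results results.tsv --out report/
```

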