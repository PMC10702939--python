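# chaoswolf

Chaos-integrated grey wolf optimizers for wrapper feature selection on
binary document-term matrices, built for depression detection in short
social-media texts — and for anyone who needs an explainable, reproducible
wrapper feature selector for high-dimensional binary data.

## The problem and the method

Detecting depressive posts is cast as a search problem: a document is a
binary bag-of-words row (term present / absent), and the model must find a
small subset of the vocabulary on which a k-nearest-neighbor classifier
separates depressive from non-depressive posts. A population of candidate
solutions ("wolves"), each a vector in [0, 1]^M, is evolved by a grey wolf
optimizer (GWO) with dimension-learning-based hunting (DLH):

- **Leader-following move.** The three fittest wolves α, β, δ pull every
  wolf via D_k = |C_k·X_k − X|, X_k' = X_k − A_k·D_k, candidate =
  (X_α' + X_β' + X_δ')/3, with A = 2·a·r₁ − a, C = 2·r₂ and a decreasing
  linearly from 2 to 0.
- **DLH move.** Each wolf also builds a per-dimension candidate from a
  random neighbor within the radius ‖X − X_GWO‖ and a random population
  member: X_d + rand·(X_{n,d} − X_{r,d}). The better of the two candidates
  replaces the wolf only if it strictly improves it.
- **NI-GWO** replaces the uniform draw r₁ with a deterministic schedule
  r₁ = α − t·(α/MaxIter), α = 2.
- **CNI-GWO1–4** inject a chaotic map orbit (circle, logistic or iterative)
  in place of uniform draws: at population initialization (variant 1), or
  in the C coefficient of the α / β / δ leader (variants 2–4, C = 2z).

A wolf position decodes to a feature mask (coordinate > 0.5) and is scored

    fitness = w₁ · KNN-accuracy + w₂ · (M − |S|)/M,   w₁ = 0.9, w₂ = 0.1,

so accuracy dominates while smaller subsets break ties — the selected words
*are* the model's explanation. The evaluation module supplies
confusion-matrix metrics (accuracy, precision, sensitivity, F-measure,
MCC), best/mean/worst summaries over repeated runs, box-plot quartiles,
and the Friedman rank test (χ² with tie correction; at α = 0.05 and
8 algorithms the rejection threshold is χ²₀.₉₅(7) = 14.067).

A synthetic generator produces class-imbalanced binary corpora with a
planted informative feature subset, so the entire pipeline is testable and
benchmarkable without any real data.

## Worked example

```sh
chaoswolf simulate --n-docs 400 --vocab-size 80 --n-informative 10 \
    --seed 7 --out-dir data/
chaoswolf optimize --variant cni2 --map logistic --pop 30 --iters 100 \
    --seed 1 --dtm-dir data/ --out run.json
```

prints

```
cni-gwo2: fitness=0.9975 val_acc=1.0000 test_acc=0.9625 features=2
```

meaning: the search kept 2 of 80 terms, the masked 5-NN classifier scores
100 % on the inner validation hold-out, the combined fitness is
0.9·1.0 + 0.1·(78/80) = 0.9975, and the untouched 20 % test split is
classified at 96.25 % accuracy. `run.json` lists the selected terms and
indices, the best-so-far fitness per iteration and all effective
parameters. The same from Python:

```python
import chaoswolf as cw

dtm, truth = cw.generate_dtm(cw.SynthSpec(seed=3))
cfg = cw.OptimizerConfig(variant="cni-gwo2", map_spec=cw.ChaoticMapSpec("logistic"), seed=1)
res = cw.detect(dtm, cfg)
print(res["validation_accuracy"], res["n_selected"], res["test_metrics"].accuracy)
```

`chaoswolf compare --variants nigwo,cni1,cni2,cni3,cni4 --runs 20 ...`
reproduces the full repeated-run protocol: a Best/Mean/Worst/feature-count
table, quartile summaries, and the Friedman test across variants.

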