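# tcmrank

Syndrome-element ranking for Traditional Chinese Medicine (TCM) medical
cases: a multitask mixture-of-experts (MMOE) ranking network coupled to a
two-tower match network, plus hand-crafted co-occurrence features and
top-k ranking metrics, exercised end-to-end on synthetic medical-case
corpora with planted symptom–element structure.

## Who this is for

Clinical-informatics and recommender-systems researchers who want a
self-contained, CPU-only reference implementation of the
MMOE + match-network + mimic-interaction ranking architecture — and of the
confidence / lift / TF-IDF feature engineering that accompanies it — with
every gradient hand-verified and every experiment seeded.

## The model

Each case has four token-list symptom fields (engraving symptoms, tongue,
moss, pulse) and a set of true syndrome elements (~62 candidates).  Every
(case, candidate element) pair is one binary sample; the model ranks all
candidates per case.

* **Main network:** field-averaged embeddings `E`, experts
  `f_i(E)` combined per task by softmax gates `g^k(E)`,
  `ŷ^k = σ(t^k(Σ_i g^k_i f_i(E)))`.
* **Match network:** a two-tower auxiliary scorer `ŷ^m` over the symptom
  side and the element side (concat head, or cosine head with per-side
  L2-normalized outputs `p_u, p_v`).
* **Coupling:** auxiliary loss, match-output-as-feature, and a mimic
  mechanism — global augmentation vectors `a_u, a_v` trained on positive
  pairs toward the opposing tower's embedding (stop-gradiented):

  `Loss = loss_main + λ₁·loss_match + λu·loss_u + λv·loss_v`

* **Statistics:** confidence `F1 = N/T_zz`, `F2 = N/T_zs`, lift
  `L = F2/(T_zs/T_total)`, and `TF-IDF = (N/S_zz)·log(Y_zz/(H_zs+1))`,
  aggregated per case by sum / average / 10-slot padding.
* **Metrics:** AUC, RelaImpr, Hits@10, the piecewise MeanRank penalty, and
  MRR = 1/MeanRank, averaged over 5 seeded runs.

The networks are plain NumPy with hand-written analytic gradients (checked
against finite differences in the test suite).  See `docs/methods.md` for
the full model account, parameter defaults, and design decisions.

## Worked example

The package reproduces the published worked example of the feature
pipeline — aggregating a sample's per-token statistic values into
sum / average / padding features:

```sh
$ tcmrank worked-example
F1   sum=0.7326  average=0.0814  [0.0821, 0.0698, 0.0850, 0.0855, 0.0575, -1.0000, -1.0000, 0.0653, 0.0945, 0.0985]  PASS
F2   sum=2.9585  average=0.3287  [0.3343, 0.2703, 0.3099, 0.3379, 0.2497, -1.0000, -1.0000, 0.2805, 0.3900, 0.3960]  PASS
L    sum=9.6800  average=1.0756  [1.0938, 0.8844, 1.0139, 1.1056, 0.8170, -1.0000, -1.0000, 0.9178, 1.2759, 1.2958]  PASS
TFIDF  sum=1.2836  average=0.1426  [0.1823, 0.1550, 0.1888, 0.1900, 0.1277, -1.0000, -1.0000, 0.0910, 0.1061, 0.1366]  PASS
PASS
```

Each row is one statistic: the sum and average run over all nine token
values of the sample's four fields, and the padding vector keeps the first
seven engraving slots (−1 when absent) followed by the tongue, moss and
pulse field averages.

A full synthetic experiment from the shell:

```sh
tcmrank simulate --n-cases 2000 --seed 7 --out-dir run/
tcmrank featurize --corpus run/corpus.jsonl --out-dir run/
tcmrank train --corpus run/corpus.jsonl --fusion full --runs 5 --out-dir run/
```

or from Python:

```python
import tcmrank as tr

cases, truth = tr.generate_corpus(tr.GeneratorConfig(n_cases=2000, seed=7))
vocab = tr.build_vocabulary(cases)
report, runs = tr.run_experiment(
    cases, vocab,
    tr.ModelConfig(fusion="full", embedding_dim=16, n_experts=4,
                   expert_layer_sizes=(32, 16), tower_layer_sizes=(16,),
                   match_tower_sizes=(32, 16, 16)),
    tr.TrainConfig(n_runs=5, epochs=12, learning_rate=1e-2, batch_size=1024),
)
print(report.summary_table())
```

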