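# mrifusion

Multi-parametric MRI multi-sequence feature-fusion classification of
ovarian-cancer subtype: high-grade serous carcinoma (HGSOC) versus
clear cell carcinoma (OCCC).

The two subtypes demand opposite treatment sequencing (chemotherapy-
first for HGSOC, surgery-first for the largely platinum-resistant
OCCC), but preoperative subtyping normally requires invasive biopsy.
This package implements a non-invasive image-based pipeline: paired
contrast-enhanced T1 (T1+C) and T2-weighted (T2WI) volumes are rigidly
aligned to a template, 2D slices feed one MBConv
(EfficientNet-B2-style) feature extractor per sequence, the per-
sequence feature vectors are fused late (concatenation by default),
and three fully connected heads — T1, T2, fused — each emit a logit
s_i with probability σ(s_i). Training minimizes

    L = L_ALL + L_T1 + L_T2,

the sum of per-branch binary cross-entropies on logits, with
reciprocal-count weighted sampling (weight 1/N_c per class), AdamW
(decoupled decay 1e-4), and a warm-up/cosine learning-rate schedule

    lr(e) = base_lr · e / warmup                      for e ≤ warmup
    lr(e) = base_lr · ½[cos(π (e−warmup)/(N−warmup)) + 1]   otherwise.

A patient missing a sequence still receives predictions from the
remaining branch. Because the clinical cohort behind the method is
private, the package ships a phantom generator whose cohorts carry the
same statistical structure — class signal split complementarily
between the T1-like (lesion rim) and T2-like (lesion core) volumes —
so every stage is testable end to end.

## Worked example

```python
from mrifusion.experiment import (SyntheticExperimentConfig,
                                  run_synthetic_experiment)

out = run_synthetic_experiment(SyntheticExperimentConfig(seed=1))
print(out["history"][["epoch", "L", "L_ALL", "L_T1", "L_T2", "val_auc"]].tail(1))
print({k: round(out[f"auc_{k}"], 4) for k in ("fused", "t1", "t2")})
```

This generates a 120-patient phantom cohort (class ratio 212:99, both
effects 3 sigma), splits it 76/19/25 (the 198:50:63 reference
proportions), trains the reduced extractor at 96×96 for 10 epochs, and
prints:

```
 epoch         L     L_ALL      L_T1      L_T2   val_auc
    10  1.696383  0.538404  0.622855  0.535124  0.948718
{'fused': 1.0, 't1': 0.9926, 't2': 1.0}
```

i.e. the training loss decomposes into the fused and auxiliary branch
terms, validation AUC has climbed from chance to ≈0.95 within ten
epochs, and on the held-out test patients the fused branch separates
the subtypes at least as well as either single sequence — the ordering
the fusion design is meant to produce.

A command-line interface covers the same pipeline on files:

```
mrifusion simulate --n 120 --seed 7 --out cohort/
mrifusion preprocess --manifest cohort/manifest.csv --template-seed 0 --out aligned/
mrifusion train --manifest aligned/manifest.csv --epochs 10 --out run/
mrifusion evaluate --checkpoint run/checkpoint.pkl --manifest aligned/manifest.csv --branch fused --out run/
mrifusion crossval --manifest cohort/manifest.csv --k 5 --out cv/
```

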