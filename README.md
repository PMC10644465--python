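# carbosite

Protein carbonylation — the irreversible oxidation of K/R/T/P side chains by
reactive oxygen species — marks loss of protein function and is implicated in
aging and neurodegenerative disease. Predicting which candidate residues are
carbonylated from sequence alone is a heavily class-imbalanced problem: known
un-carbonylated sites outnumber carbonylated ones by factors of 5 to several
hundred, and classifiers trained naively collapse onto the majority class.

`carbosite` implements a **two-way rebalancing strategy** for this setting,
plus the surrounding pipeline:

1. **DR features.** Each candidate site is cut into a 21-residue window and
   encoded by distance-based residue counts: the 20 single-residue counts
   `D_0` plus, for each pair distance `k = 1..d_max`, the 400 ordered
   residue-pair counts `D_k` (vector length `20 + 400·d_max`).
2. **Optimal sampling scale.** With `m` positives and `M` negatives, both
   classes are resampled to a common size `s` minimising the sum of the
   oversampling ratio `s/m` and the undersampling ratio `M/s`:
   `s = round(√(mM))`, clamped to `[m, M]`.
3. **Attention-based undersampling.** A sample's attention diagonal — its
   row-softmax-normalised cosine self-similarity — is low for representative
   samples and high for outliers. Stage 1 keeps the `⌈(s+M)/2⌉` most
   representative negatives; stage 2 re-computes attention over those
   negatives pooled with all positives and keeps the `s` negatives least
   similar to the pool (least positive-like).
4. **GAN-based oversampling.** A small generator/discriminator MLP pair
   (pure numpy, seeded) is trained adversarially on the scaled positive
   vectors; the generator maps Gaussian noise to synthetic positives until
   the positive class also has `s` members.
5. **Gaussian-kernel SVM** (`K(x,z) = exp(−‖x−z‖²/2σ²)`) on the exactly
   balanced training set, with sensitivity `TP/P`, specificity `TN/N` and
   the pairwise ranking AUC (ties ½) for evaluation, via stratified
   cross-validation or an external test set.

Baselines (`none`, plain random undersampling, SMOTE) and the ablation arms
(random undersampling + GAN, attention + SMOTE) are included, as are seeded
synthetic generators for imbalanced feature clouds and motif-biased peptide
windows, so the whole method is testable without external downloads.

## Worked example

```bash
# 1000 synthetic un-carbonylated + 10 carbonylated K-centred 21-mers
carbosite simulate --n-neg 1000 --n-pos 10 --motif-bias 0.5 --seed 1 --out windows.txt

# DR features (d_max=3 -> 1220 columns + label)
carbosite features --windows windows.txt --dmax 3 --out features.csv

# two-way rebalance: s = round(sqrt(10*1000)) = 100
carbosite rebalance --features features.csv --strategy attention_gan --seed 1 --out balanced.csv
```

which prints

```
wrote 1010 windows to windows.txt
wrote 1010 x 1220 feature matrix to features.csv
s=100: kept 100 negatives, synthesized 90
wrote 200 rows to balanced.csv
```

— the 1000 negatives were reduced to the 100 most informative, the 10
positives were grown to 100 (10 real + 90 generated), and the training set
is exactly balanced at the optimal scale. A cross-validated run and an
imbalance-ratio sweep over IR ∈ {5, 10, 100, 333}:

```bash
carbosite train --windows windows.txt --strategy attention_gan --folds 5 --seed 1
carbosite sweep --irs 5,10,100,333 --seed 1 --scales 20,40,80,100,120,250,500,1000
```

The sweep writes a `method,residue,IR,s,sen,spe,auc` CSV (plus an AUC vs
sampling-scale curve when `--scales` is given) under `runs/`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's analytically checkable headline quantity — the
optimal sampling scale for the extreme-imbalance setting (m=3, M=1000) — by
running the library, and writes it as JSON.

## Layout

- `src/carbosite/seq_features.py` — windows, DR encoding, min-max scaling
- `src/carbosite/rebalance.py` — optimal scale, attention/random undersampling, SMOTE
- `src/carbosite/gan.py` — numpy GAN (generator, discriminator, Adam)
- `src/carbosite/classify.py` — RBF-SVM wrapper, Sen/Spe/AUC, cross-validation
- `src/carbosite/synthetic.py` — seeded synthetic fixtures
- `src/carbosite/pipeline.py`, `cli.py` — orchestration and the `carbosite` CLI
- `docs/methods.md` — modelling assumptions, defaults, and known limitations
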