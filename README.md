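# modfus

Multimodal fusion of structural brain MRI and clinical-rating-scale text
prompts for Parkinson's disease (PD) vs healthy control (HC) classification.

Clinical scales (MDS-UPDRS motor section, STAI, ESS, CDT) and T1-weighted
MRI capture complementary views of the same disease process, but their
formats — a handful of discrete scores vs a dense 3-D volume — make naive
feature concatenation a weak fusion strategy. `modfus` implements a
prompt-based alternative for researchers studying multimodal neuroimaging
diagnosis:

1. **Scores → text.** Each scale score is binned against severity
   thresholds, the label ("Mild" … "Serious") is substituted into a sentence
   template (e.g. *"The subject noted Moderate (ESS) drowsiness during the
   day."*), and each sentence is expanded into N = 8 lexically diverse
   paraphrases by a deterministic substitution bank.
2. **Contrastive alignment.** Text and image encoders are pretrained with a
   symmetric temperature-scaled objective over the batch cosine matrix
   S\[b,k\] = cos(f_tb, f_ik):

       L_t→i = Σ_b −log( exp(S[b,b]/τ) / Σ_k exp(S[b,k]/τ) ),   τ = 0.1,
       L     = (L_t→i + L_i→t) / 2,

   pulling matched prompt/volume pairs together in a shared 512-d space.
3. **Bidirectional cross-modal attention.** Token sequences interact through
   8-head attention in both directions — I\* = softmax(Q_I K_Tᵀ/√d)·V_T and
   T\* = softmax(Q_T K_Iᵀ/√d)·V_I — computed from the same inputs in one
   pass (depth 1 by default).
4. **Attention-reduced classifier.** \[I\*; T\*\] is collapsed by a softmax
   self-attention reduction (α = softmax(QKᵀ/√d), F̂ = row-mean of αV) and
   classified by a two-layer softmax network, trained with
   L = λ·(1 − cos(Ī\*, T̄\*)) + (1 − λ)·BCE, λ = 0.54.

Evaluation is stratified K-fold cross-validation with ACC/precision/recall/
F1, Mann–Whitney AUC, and mean ± population dispersion per metric. Because
the clinical cohorts this method targets are access-restricted, the package
ships a **synthetic cohort simulator**: a latent severity scalar drives both
class-shifted scale scores and a planted lesion in an ellipsoidal brain
phantom, so every stage — prompts, pretraining, fusion, cross-validation,
attention maps — runs end to end with no external data. Neural components
run on a small, self-contained reverse-mode tensor engine over numpy; no GPU
or deep-learning framework is required.

## Worked example

```python
import modfus
from modfus.cohort import CohortConfig, simulate_cohort
from modfus.evaluation import run_cv

scales = modfus.load_scale_definitions()          # shipped severity bands
config = CohortConfig(n=60, score_effect=2.0, image_effect=0.5, seed=7)
cohort, _ = simulate_cohort(config, scales)
cohort = cohort.with_prompts(scales, n=8, seed=13)
print(cohort.prompt_sets[0].sentences["ESS"])

clf = modfus.MultimodalFusionClassifier(
    shared_dim=64, d_model=32, pretrain_epochs=10, epochs=15,
    batch_size=16, lr=1e-3, random_state=0,
)
report = run_cv(cohort, clf, K=5, seed=5)
for metric, value in report.format().items():
    print(f"{metric:>9}: {value}")
```

Output:

```
The subject noted Significant (ESS) drowsiness during the day.
      ACC: 0.900 ± 0.062
      AUC: 0.960 ± 0.050
       F1: 0.916 ± 0.054
precision: 0.943 ± 0.070
   recall: 0.893 ± 0.054
```

The cohort plants a 2-SD class shift in the scale scores and a coupled
lesion-intensity reduction in the volumes; the report shows the pipeline
recovering that signal under leakage-free 5-fold cross-validation (each fold
rebuilds its vocabulary and re-pretrains on its own training subjects, which
the `run_cv` harness verifies through provenance tags). `±` values are the
population dispersion across folds. A `random_state` fixes every source of
randomness, so reruns reproduce these numbers exactly.

## Command line

```bash
modfus simulate --n 200 --seed 7 --out cohort_dir        # NIfTI + CSV + manifest
modfus prompts  --table cohort_dir/cohort.csv --n 8 --seed 7 --out prompts.jsonl
modfus pretrain --data cohort_dir --out ckpt.npz --seed 7
modfus train    --data cohort_dir --init ckpt.npz --out model.npz --seed 7
modfus evaluate --data cohort_dir --folds 5 --seed 7 --out report.json
modfus attn-map --ckpt model.npz --subject S0003 --data cohort_dir --out heat.png
```

All stages accept `--config cfg.yaml`; unknown keys are rejected with the
offending key path, and every run writes a resolved-config snapshot.
Severity thresholds, labels and templates live in a user-overridable YAML
(`--scales`).

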