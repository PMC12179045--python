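# vesselkd

Multi-teacher knowledge distillation for vessel segmentation, with a
self-contained synthetic vascular benchmark.

Three specialist U-Net teachers — trained on the full vasculature, on thick
vessels only, and on thin vessels only — are distilled into a single student
network. Teacher logits are temperature-softened (`sigmoid(z/T)`), clamped,
and compared to the student's probabilities with a per-pixel binary KL
divergence; the per-teacher losses are averaged and combined with a
(optionally penalized) hard-label loss:

```
total = alpha * mean_k KL(teacher_k || student) + (1 - alpha) * penalty * hard
```

Everything runs on CPU: the networks are built on a small numpy
reverse-mode autodiff engine bundled in `vesselkd.nn` (no deep-learning
framework required).

## Package layout

- `vesselkd.synthetic` — branching vessel phantoms on textured backgrounds,
  with ground truth partitioned into thin/thick masks by a skeleton +
  distance-transform width classifier.
- `vesselkd.models` — standard and Lite U-Nets, closed-form parameter / MAC /
  size accounting, bottom-right zero padding to 16-aligned shapes.
- `vesselkd.losses` — the hard-label loss zoo (Dice, SoftDice, Tversky,
  Focal, FocalTversky, DiceBCE, Combined, Combo, BCE).
- `vesselkd.distill` — softening, clamping, binary KL, loss aggregation.
- `vesselkd.metrics` — pixel-wise ACC/SEN/SPE/F1/IoU with micro-aggregation.
- `vesselkd.pipeline` — teacher/student training, ablation sweeps
  (temperature, penalty, loss, teachers, lite), checkpointing.
- `vesselkd.nn` — the autodiff tensor, layers, and Adam.
- `vesselkd.benchmarks` — published benchmark tables used for reporting.

## CLI

```bash
# generate a synthetic dataset (images + gt + thin + thick masks)
vesselkd synth --out data/demo --n-train 8 --n-val 2 --n-test 4 --seed 1

# train the three specialist teachers
for role in original thick thin; do
  vesselkd train-teacher --data data/demo --role $role \
      --run-dir runs/teachers --epochs 30
done

# distill them into a student
vesselkd distill --data data/demo --teacher-dir runs/teachers \
    --run-dir runs/student --temperature 3.0 --alpha 0.5 --penalty 5 \
    --epochs 30

# evaluate and sweep
vesselkd eval --data data/demo --checkpoint runs/student/student.npz
vesselkd sweep --data data/demo --kind temperature --grid 2,3,4,5,7 \
    --teacher-dir runs/teachers --epochs 30
vesselkd report --run-dir runs --out results.csv
```

Real datasets are read from the same layout
(`<root>/<split>/{images,gt,thin,thick}/`), or from a flat
`<root>/{images,gt}/` directory with a known dataset name supplying the
published ordered split counts.

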