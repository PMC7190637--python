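# tissuefp

Patient-identity representation learning for H&E-style tissue images.

Pathology cohorts rarely come with enough clean labels to train deep
networks directly, but they come with something free: every patch of a
slide is labeled by *which patient it came from*. `tissuefp` trains a
network to recognize individual tissue cores from image patches and treats
the pooled feature vector of its last convolutional stage as a **tissue
fingerprint** — a compact description of tissue architecture that transfers
to tasks the network was never trained on. The package is aimed at
computational-pathology researchers who want a small, fully inspectable
CPU implementation of this idea, with a synthetic cohort generator that
makes every stage testable at desk scale.

## The method

Tissue cores (1600x1600 px at 0.5 um/px) are split into left and right
halves. Patches (224x224) from the left halves train the network to
predict the core index y = i; the right halves are held out to monitor
generalization and stop training. For a pair of images of core *i* with the
same morphology but different staining styles, the loss is

    loss(Image_i1, Image_i2, y=i) = CE(c_i1, y) + CE(c_i2, y)
                                    + gamma * d2_FP(FP_i1, FP_i2)

where `CE` is softmax cross-entropy over core indices, `FP` is the
fingerprint, and `d2_FP` is the squared Euclidean distance between the
L2-normalized fingerprints (gamma = 0.5). The distance term makes the
fingerprint insensitive to staining style while cross-entropy keeps it
patient-specific. Fingerprint quality is measured with a **matching game**:
compute fingerprints for left halves in one style and right halves in
another, match each left half to its nearest right half in fingerprint
space, and score the fraction of cores matched to themselves (chance is
1/N; 0.48% for a 208-core array).

The fingerprints then feed a small multiple-instance head (512x8 linear,
ReLU, 8x1 linear, tanh) that maps a bag of patch fingerprints from one
patient's slide to a marker score in [-1, 1]; the patient score is the mean
over patches, trained with squared error against clinical ±1 labels and
early-stopped on patient-level AUC of a held "overfitting" group under
5-fold cross-validation.

A synthetic cohort generator provides the test bed: patients with known
texture phenotypes (gland fraction, nuclear density and radius, stroma
wavelength and anisotropy), multiple cores per patient, two parametric
"site styles" of the same morphology, whole-slide-like mosaics with
background/epithelium/stroma/fat masks, and marker labels coupled to the
gland fraction. See `docs/methods.md` for the model and its assumptions.

## Worked example

Train a tiny fingerprint network on a synthetic dual-style cohort and play
the matching game across styles:

```python
import numpy as np
from tissuefp.synthgen import make_cohort
from tissuefp.trainfp import TrainConfig, build_training_data, train_fingerprint_network
from tissuefp.nn import build_tiny_cnn
from tissuefp import matcheval as me

cohort = make_cohort(n_patients=32, cores_per_patient=2, core_px=640, seed=1)
data = build_training_data(cohort)

model = build_tiny_cnn(n_identities=data.n_cores, fingerprint_dim=32, seed=1)
cfg = TrainConfig(mode="style_paired", steps=1000, lr=3e-3, lr_decay_at=0.6,
                  batch_size=16, monitor_interval=100, patience=10, seed=1)
log = train_fingerprint_network(data, model, cfg)

left = me.cohort_half_fingerprints(model, data, "left", "siteA", stride=56)
right = me.cohort_half_fingerprints(model, data, "right", "siteB", stride=56)
result = me.score_matching(left, right, data.layout)
print(f"core accuracy    {result.core_accuracy:.3f}")
print(f"patient accuracy {result.patient_accuracy:.3f}")
print(f"chance           {me.chance_accuracy(data.n_cores):.4f}")
```

Output (about three minutes on one CPU core):

```
core accuracy    0.328
patient accuracy 0.625
chance           0.0156
```

Left halves are fingerprinted in one site style and right halves in the
other, so the score measures *style-invariant* patient recognition: a third
of 64 cores find their own other half — 21x above the 1.6% chance level —
and pooling both cores per patient raises the hit rate to 62%.
Training the same budget with gamma = 0 (no style pairing) yields a clearly
lower accuracy and a larger inter-style fingerprint distance, which is the
mechanism the composite loss exists to fix.

A command-line interface wraps the same steps:

```
tissuefp synth cohort --patients 16 --seed 1 --out cohort/
tissuefp train-fp --patients 16 --steps 400 --seed 1 --out run/
tissuefp match --patients 16 --model run/ --seed 2 --out match.json
```

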