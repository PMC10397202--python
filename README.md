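# podscape

Multi-scale behavioural phenotyping of postoperative-delirium-like (POD)
behaviour in mice, driven by 3-D skeleton trajectories and movement labels.

Postoperative delirium is hard to study in animal models because the same
surgery produces heterogeneous outcomes: only some animals develop
delirium-like behaviour, and those that do split into hyperactive and
hypoactive psychomotor subtypes. `podscape` implements an analysis pipeline
that phenotypes animals on three scales — **pose** (frame-level kinematics),
**behaviour** (movement-module composition of a session) and **action
sequence** (object-investigation bouts) — and diagnoses delirium-like
animals without predefined thresholds. A synthetic-session generator with
ground truth makes every stage testable without the original recordings.

The package is aimed at computational-ethology practitioners who already
have keypoint trajectories (e.g. from multi-view DeepLabCut-style tracking)
and per-frame movement labels from an upstream movement-segmentation tool,
and want the downstream statistics.

## The analysis

**Pose scale.** From a T×16×3 skeleton (16 named body parts, mm, 30
frames/s), 13 pose features are computed: nose–tail length, neck and back
heights, fore/hind limb widths, per-frame 3-D speeds of back, nose, both
front claws and the body centroid, acceleration, angular velocity of the
tail-root→neck axis, and the spine angle. Each feature's distribution is
summarized as a 50-bin probability mass function (PMF), and each PMF is
reduced to 7 descriptor statistics (mean, median, SD, 25%/75% quantiles,
min, max), giving a 13 × 7 = 91-dimensional "eigenvalue" vector per animal.
Group PMFs are compared with a two-sample Kolmogorov–Smirnov test on
n = 500 samples resampled from each curve's empirical distribution function:
D = max |F₀(x) − G₀(x)| over the pooled sorted sample.

**Behaviour scale.** Each session's movement labels (40 classes, M1–M40)
become a fraction vector xᵢ ∈ Δ³⁹. Model animals are diagnosed against
controls by Ward clustering of z-scored fractions (two-cluster cut of the
clustergram); a model cluster strongly depleted of control samples is
labelled POD. Per-movement group differences use Welch's t with Sidak
family-wise adjustment over the 40 classes. The significant movements
(14 under the designated profile) span the *delirium-like behaviour space*:
X is embedded into 3-D by t-SNE (perplexity 6), Y = f_tSNE(X), a linear
max-margin boundary (w, b) is fitted between the diagnosed groups, and each
animal gets a 1-D severity value sᵢ = (w·yᵢ + b)/‖w‖, oriented POD-positive.

**Action-sequence scale.** A frame investigates an object when the 2-D
nose–object distance is < 60 mm with the neck→nose direction at an acute
angle to the neck→object direction (*approach*), or < 30 mm with the back
above the object top (*climb*). Bouts are deep (climb, or carrying
sniff/touch/crab labels) or shallow, and the preference statistic is

    DSP = arcsin((T_deep − T_shallow) / (T_deep + T_shallow)) ∈ [−π/2, π/2].

**Subtypes and treatment.** POD animals are split into Hyper/Hypo by
k-means (k = 2) on the 3-D embedding of their standardized eigenvalue
vectors, named by their speed statistics. A logistic classifier
(regularization chosen by stratified 5-fold CV over 30 candidates) trained
on POD/non-POD fractions labels a treated group; the *incidence* is the
percentage labelled POD.

## Worked example

```python
import numpy as np
import podscape as pp

# simulate a cohort: 12 controls, 12 surgical-model animals of which 6
# carry the delirium-like movement composition
truth = ["POD-like"] * 6 + ["nonPOD-like"] * 6
control = [pp.movement_fractions(pp.generate_labels(pp.control_profile(), 18_000, seed=i))
           for i in range(12)]
model = [pp.movement_fractions(pp.generate_labels(
            pp.pod_profile() if t == "POD-like" else pp.nonpod_profile(),
            18_000, seed=100 + i))
         for i, t in enumerate(truth)]

diagnosis, space = pp.build_delirium_space(
    model, control, pp.DISCRIMINATIVE_CLASSES, seed=0)
print("diagnosis:", diagnosis.labels)
print("projection (POD):   ", np.round(space.projection_values[diagnosis.pod_mask], 2))
print("projection (nonPOD):", np.round(space.projection_values[~diagnosis.pod_mask], 2))
```

prints

```
diagnosis: ('POD', 'POD', 'POD', 'POD', 'POD', 'POD', 'nonPOD', 'nonPOD', 'nonPOD', 'nonPOD', 'nonPOD', 'nonPOD')
projection (POD):    [88.22 88.48 42.2  63.24 42.19 62.86]
projection (nonPOD): [-42.66 -68.25 -42.19 -86.11 -89.86 -60.04]
```

All six delirium-like animals are recovered, and the severity axis
separates the groups with no overlap: every POD animal projects positive,
every non-POD animal negative. Task-driven behaviour works the same way:

```python
arena = pp.novel_object_arena()
schedule = pp.InvestigationSchedule(
    bouts=(pp.ScheduledBout(101, 280, "novel", "deep"),
           pp.ScheduledBout(501, 560, "familiar", "shallow")),
    n_frames=1000)
traj = pp.generate_investigation_session(schedule, arena, pp.hypo_profile(), seed=1)
record = pp.investigation_record(traj, arena,
    labels=pp.generate_labels(pp.control_profile(), 1000, seed=2), deep_classes=())
print(f"T_deep={record.t_deep:.1f}s T_shallow={record.t_shallow:.1f}s DSP={record.dsp:.3f} rad")
```

```
T_deep=6.0s T_shallow=2.0s DSP=0.524 rad
```

The detector recovers the scheduled 6 s of deep and 2 s of shallow
investigation exactly, and the DSP equals arcsin(4/8) ≈ 0.524 rad — a
preference for deep investigation.

A command-line interface mirrors the library
(`podscape simulate | pose-features | metrics | investigate | diagnose |
subtype | dex-eval | run`); `podscape run --out-dir out --seed 1` executes
the whole synthetic study from a YAML config and writes CSV/JSON tables.

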