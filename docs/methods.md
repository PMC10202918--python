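# Methods

## Synthetic cohort model

The generator stands in for a two-group clinical EEG source-imaging
study.  Its unit of data is a subject's trial set x(v, t): current
density (arbitrary units) at `n_vertices` points of a registered unit
sphere, sampled at 400 Hz over an epoch of −1200…800 ms around the
target stimulus.

Each trial is the sum of

* **Evoked components** — temporal Gaussian envelopes confined to one
  cortical region each.  The defaults mirror the two stages of
  visuospatial target processing: an occipital component at 200 ms
  (width 25 ms, amplitude 1.0; the N1 latency range) and a parietal
  component at 325 ms (width 20 ms, amplitude 1.0; the P300 range).
  The spatial profile is the region indicator — uniform within the
  region, zero outside — which keeps the ground-truth footprint exact
  for localization scoring at the cost of a sharp boundary that real
  source estimates would smooth.
* **Per-subject amplitude scaling** a ~ N(1, subject_sd²), subject_sd
  0.2, applied to all components (floored at 0.05); this is the
  between-subject variability that makes leave-one-subject-out
  generalization non-trivial.
* **The planted effect** — in the patient group only, the component
  whose region is the ROI is additionally multiplied by δ ∈ [0, 1]
  (default 0.5).  The effective ROI amplitude a·δ is recorded per
  subject in the cohort table as the simulation ground truth.
* **Background noise** — spatially correlated Gaussian noise built by
  mixing 192 latent white-noise sources at quasi-uniform directions
  with Gaussian weights of angular distance (length scale 0.3 rad),
  rows normalized so the per-vertex SD is exactly `noise_sd` (default
  0.5, i.e. the single-trial effect-to-noise ratio at an ROI pixel is
  about one — hard enough that classification must pool space and
  time).  Temporal coloring is white by default; the 30 Hz lowpass of
  the preprocessing imposes the smoothness the classifier sees.

Clinical scores are generated as score = mean + sd·(ρ·z(a) +
√(1−ρ²)·ε) with z the standardized effective amplitude, so the
population correlation with the ground truth is exactly ρ (default
0.26, a realistic cognitive-score effect size; ρ = ±1 is noiseless).

What the generator does **not** emulate: realistic neural dynamics
(oscillations, 1/f spectra, latency jitter), inter-trial amplitude
variability beyond noise, volume-conduction leakage between regions,
and condition structure (cue validity, SOA) — trials are exchangeable
within subject.  Passing tests therefore demonstrate that the pipeline
recovers a planted, localized, time-locked group difference under
subject heterogeneity and spatially correlated noise; they do not
certify performance on clinical recordings.

All randomness flows from named integer seeds; per-subject streams are
spawned via `SeedSequence`, so cohorts are bit-identical across runs
and subjects can be regenerated lazily in any order.

## Preprocessing and volumization

Trials are lowpass-filtered below 30 Hz with a zero-phase
forward-backward Butterworth filter (order 4; the literature names only
the cutoff, the realization is ours) and baseline-corrected by
subtracting the per-vertex mean over −200…0 ms.

The sphere is flattened by the Mollweide equal-area projection.  The
auxiliary angle solves 2θ + sin 2θ = π sin(lat) by Newton iteration to
1e-12 with poles handled analytically.  Orientation convention:
longitude 0 at the anterior midline, occipital pole at ±π (the left and
right edges of the map), left hemisphere in the left half-plane; grid
row 0 is the top (north pole side), column 0 the left edge, pixels
0-based.  Vertex values are interpolated onto the uniform G×G grid by
barycentric (linear) interpolation inside the convex hull of the
projected vertices, nearest-vertex fill between hull and ellipse
boundary, zero outside the ellipse; the interpolation weights depend
only on geometry and are precomputed as one sparse operator.

3d volumes average the current density within sixteen half-open 50 ms
bins covering 0–800 ms (a sample at exactly 800 ms is excluded); 2d
images average 200–350 ms.  Each frame is z-scored over its in-ellipse
pixels (mean 0, SD 1; a constant frame maps to zeros).  Per-frame
scoring is the literal reading of "images were standardized" and keeps
frames comparable across bins; per-volume or per-dataset scoring are
the plausible alternatives we did not adopt.

## Classifier and training protocol

The classifier is a C3D-style stack: three blocks of (3×3×3 conv,
stride 1, same padding) → batchnorm → ReLU → max-pool, with pooling
2×2×1 then 2×2×2 twice (2d variant: 3×3 kernels, all pools 2×2),
followed by two fully connected ReLU layers and one sigmoid output
unit.  Full-scale channel widths are 64/128/256 with FC width 512;
the desk-scale variant used throughout the tests is 8/16/32 with FC 32.
Weights are Kaiming-initialized; training minimizes binary
cross-entropy with Adam (weight decay 1e-5).

Per held-out patient ("specific patient", SP) the two-stage protocol
runs: **pretraining** on all other subjects — classes undersampled to
1:1 at trial level, a 90/10 train/validation split, early stopping on
validation accuracy, best weights restored — then **fine-tuning** on
the SP's trials plus reserved control subjects withheld from every
pretraining fold (default 30% of controls), with the convolutional
blocks frozen (their outputs are computed once in evaluation mode and
cached; only the FC head trains) and learning rate and weight decay at
1/10 of the pretraining values; 80% of this set trains the head and
the remaining 20% is the evaluation split that produces all reported
accuracies.

The learning rate comes from a range test over [1e-8, 1]: every
candidate rate (13, geometric) is probed from the same initial weights
on the same mini-batch sequence for 15 steps, candidates whose loss
exceeds 4× the initial loss (or turns non-finite) are discarded as
divergent, and the largest rate whose tail loss ties the best within
10% is chosen.  Restarting per candidate removes the weight-drift
confound of single-pass sweeps; the largest-tied-rate rule reflects
that early training sits on a loss plateau where many rates are
statistically indistinguishable and the largest stable one descends
fastest per epoch.  On the desk-scale cohort it selects ~2e-3
consistently.

The implementation is a small explicit-layer numpy stack (im2col +
BLAS matmul convolutions in float32, col2im input gradients,
first-occurrence tie-breaking in max-pool).  Explicit layers are a
design requirement, not merely an implementation detail: the relevance
analyses rewrite each layer's backward rule.

## Explainability

All attributions are seeded from the pre-sigmoid logit (standard LRP
practice; the sigmoid is monotone so argmax structure is unchanged).

* **LRP**: batchnorm is folded into the adjacent convolution
  (evaluation-mode scale and shift merged into effective weights and
  bias), making each block affine + ReLU.  Fully connected layers use
  LRP-0, convolutions LRP-γ with γ = 0.25 (a conventional value;
  denominators stabilized by ε = 1e-9·sign).  Bias terms enter the
  denominator but are not redistributed, so conservation of total
  relevance is exact only in bias-free networks — which is how the
  conservation test is stated.  Max-pool routes relevance to the
  winning input; ReLU passes it through.
* **GradCAM** targets the last conv block's output by default; the map
  is ReLU-rectified and upsampled by linear interpolation.
* **GBP** gates the ReLU backward pass on both the forward activation
  and the upstream gradient; **GGCAM** is the elementwise product of
  the upsampled GradCAM map and the GBP gradient.

Aggregate heatmaps are simple means over the evaluation trials matching
a (group, correctness) cell, pooled across folds; an empty cell is
reported as missing, never as zeros.  ROI time courses and peak windows
are extracted from mean **|relevance|** over the ROI footprint: the
planted difference is an attenuation, so relevance at the effect voxels
contributes *negatively* to the patient score and a signed mean would
peak off-effect; magnitude matches the localization score, which is the
rank AUC of |relevance| against the planted mask (ROI footprint × bins
overlapping the effect window).

## Inverse stage

The optional forward/inverse chain uses a synthetic lead field (sensor
sensitivity decaying as a Gaussian of angular distance, spread 0.6 rad)
and depth-weighted minimum-norm estimation
x̂ = W Gᵀ (G W Gᵀ + λI)⁻¹ y with W_jj = ‖g_j‖^(−2p), p = 0.5, and λ
from the trace heuristic λ = tr(GWGᵀ)/(n_ch·SNR²) at SNR 3.  These are
conventional defaults, not reconstructions of any particular tool's
settings.  The default pipeline bypasses this stage and feeds the
simulated sources to the volumizer directly; the stage is exercised by
its own recovery tests (exact single-source localization on a
near-orthogonal toy, across-subject amplitude-recovery correlation
≥ 0.7 at 20 dB sensor SNR).

## Problem sizes and numerical choices

The canned desk-scale experiment uses 10 subjects/group × 40 trials ×
2,000 vertices, 24×24×16 volumes, channels 8/16/32, batch 16, up to 40
pretraining epochs (patience 8), three leave-one-subject-out folds, and
LRP + GGCAM heatmaps for every evaluation trial — about ten CPU-minutes
end to end.  The 24-pixel grid is the smallest that survives the three
pooling stages with room to spare and keeps the ROI footprint tens of
pixels wide; the full-scale 120-grid construction is exercised by its
own shape test.  Statistics (pooled-variance t, Fisher exact with the
point-probability rule, one-tailed Pearson p via the t transform)
delegate to scipy and are cross-checked against literal enumerations in
the tests.  Cohen's d uses the (n−1)-weighted pooled SD and the
patient − control sign convention.

Known limitations: accuracy estimates per fold rest on small
evaluation splits (tens of trials), so single-fold numbers are noisy;
the no-effect control run trains briefly by design and its "patient-
correct" cell can be empty (at chance accuracy a degenerate classifier
may predict one class throughout), in which case the all-samples
aggregate is the reported localization quantity; region indicators
make the planted footprint unrealistically sharp; and none of the
synthetic results transfer quantitatively to clinical EEG.

A caveat worth stating explicitly: with no planted effect (δ = 1) the
localization AUC of the saliency aggregates does **not** fall to
chance (measured ≈ 0.7 for both methods at desk scale).  This is a
property of the cohort model plus the attribution methods, not a bug:
both groups carry genuine evoked activity at the ROI/window, and
LRP/GGCAM magnitudes track input activity as well as model
sensitivity, so voxels with real signal outrank background even when
that signal carries no group information.  Chance-level scores arise
only for masks independent of the evoked structure (the unit tests
verify 0.5 ± 0.05 for seeded-noise heatmaps).  Interpreting heatmaps
on real data therefore requires the between-condition contrast — here,
the planted-window recovery at δ < 1 — rather than raw saliency
magnitude alone.
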