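# Methods

This note records the model, the numerical choices, what the synthetic data
does and does not emulate, and the package's own design decisions where the
design was genuinely open.

## Signal model and preprocessing

Raw streams are irregularly timestamped 3-axis series per (device, sensor):
accelerometer (m/s², gravity included), gyroscope (rad/s) and a software
orientation sensor (angles), nominally 100 Hz. Resampling is per-axis linear
interpolation onto a uniform grid — simple, exact on piecewise-linear
signals, and accurate to O(dt²) for band-limited motion at 100 Hz; no
low-pass filtering or drift compensation is applied, matching the
raw-data-in philosophy of the pipeline. The common grid runs from the latest
first-timestamp to the earliest last-timestamp of the selected streams, so
no extrapolation ever occurs. Device clocks are assumed synchronized.

Channels are stacked in a fixed canonical order (wrist before ankle;
accelerometer, gyroscope, orientation; axes x, y, z). The order itself is a
package convention — only the contiguity of one sensor's three axes matters,
because the first convolution strides vertically by 3.

## Network

One architecture serves both tasks. Defaults (`ModelSpec()`): 5
convolutional layers with 100/75/25/25/75 filters, first kernel (15, 3) with
vertical stride 3, later kernels (15, 1), no pooling, "valid" padding, ReLU,
dropout 0.5 after every layer, one hidden dense layer of 128 units, softmax
output. Training defaults (`TrainConfig()`): SGD, learning rate 1e-4, batch
size 30 sampled i.i.d. uniformly with replacement from the training pool, at
most 100 epochs, early stopping on validation loss with patience 10,
best-validation weights restored.

Open details were decided as follows: dense width 128 (configurable);
"valid" padding and no pooling; patience 10; ELU available as an
alternative activation; optional per-channel input standardization using
training-pool statistics (stored with the model). Batch normalization is not
implemented; the remaining counting-model variants (extra dense layers,
activation, input normalization, input shape via the vertical kernel extent)
are plain configuration switches.

The implementation is pure numpy: convolutions are evaluated as an im2col
gather plus one BLAS matmul per layer, with hand-written backpropagation
(verified against finite differences during development) and float32
parameters. Training is bitwise deterministic for a fixed seed on a fixed
BLAS configuration.

## Recognition aggregation

Stride between test windows is `max(1, round(W·(1−γ)))` — the overlap factor
is defined on windows, so some conversion to samples is needed; rounding
with a floor of 1 is the obvious one. Each time step takes the mode of the
hard argmax votes of covering windows (ties → lowest class index; steps
covered by no window inherit the nearest covered step's label). Smoothing
replaces any interior run of `Ek` flanked by one identical label on both
sides and shorter than `T_min(k)`; this includes null flanks, which is what
removes isolated spurious detections inside rest periods. Runs at the
sequence boundary have only one flank and are never altered. Replacements
are applied shortest-run-first, recomputing runs after each one, until a
fixpoint — this order makes the fixpoint unique and is what the equivalence
oracle in the tests transcribes. Null runs themselves are never removed.

## Counting

The start segment is the first `floor(w/2)` samples after a cue (half-open
sample intervals); a window is positive iff it contains the whole segment.
Counting windows slide at stride `max(1, round(w/20))`, dense enough that
every start segment is fully contained in several consecutive windows.
Detection probabilities are thresholded at 0.5. In the mode rule, run-length
modes break ties toward the larger length (conservative: favors confirming
runs); candidate-to-confirmed distance is measured start-to-start in window
positions, with "within M0/2" inclusive; candidates are compared against the
confirmed set only, in a single pass. `M1`/`M0` are computed per set. If no
run reaches the confirmed threshold, the longest run is kept as the single
confirmed start and a warning is logged. Binary smoothing never creates
1-bits, so the count can only decrease; it is idempotent whenever the
recomputed modes are unchanged (not guaranteed in general, and not assumed
anywhere).

## Synthetic data

The generator emulates the *statistical* structure the pipeline relies on,
not biomechanics:

* per exercise, a fixed pseudo-random loading of 3 harmonics of the
  repetition frequency across the 18 channels, phase-locked to the
  repetition start, plus a Gaussian "initiation transient" shortly after the
  start (the burst that begins a rep) — this is what makes both class
  identity and rep phase learnable;
* per-exercise base repetition intervals drawn once from 1.5–4 s; per
  subject a log-normal tempo factor (σ = 0.06), channel gains (σ = 0.15) and
  phase offsets (σ = 0.2); per rep a non-negative interval jitter (σ = 2%),
  so the shortest observed interval per exercise is well defined;
* constrained sets of 15 cued repetitions per exercise, rests of 4–8 s, a
  90–120 s null recording per subject; free ("reps flow together", truth
  kept separately from the cue channel) and 1-2-3 set schemes;
* gravity offset on accelerometer z; null/rest background as a leaky random
  walk (leak 0.98) plus white noise (σ = 0.1 signal units); timestamps at
  10 ms nominal steps with 1 ms Gaussian jitter.

It does **not** emulate: consistency between accelerometer and orientation
channels, axis cross-talk from device rotation, fatigue-dependent slowing,
inter-exercise similarity structure (signatures are independent draws, so
classes are roughly equidistant), or heavy-tailed sensor artifacts. Passing
benchmarks on this data therefore demonstrates that the pipeline machinery
is correct and that the models can learn quasi-periodic multi-channel
structure under subject shift — not that the reported real-world accuracies
transfer.

Defaults (12 subjects, seed 42) are the package's standard study conditions;
generation is byte-identical under a fixed seed (per-subject generators are
spawned from one seed sequence).

## Benchmarks and problem sizes

The bundled benchmarks and `scripts/acceptance.py` run on one CPU, so they
use a reduced configuration (`DESK_SPEC`/`DESK_TRAIN`): 3 conv layers with
24/16/16 filters, temporal stride 2 from the first layer on, dense 64,
dropout 0.2, input normalization, momentum-SGD (lr 0.02, momentum 0.9), at
most 15 epochs with patience 3. Recognition uses subject-grouped 5-fold
cross-validation over the 12 simulated subjects (training windows
non-overlapping, test voting at γ = 0.95); counting trains the ten
per-exercise counters on 9 subjects and scores the 30 sets of 3 held-out
subjects — a single grouped split rather than leave-one-subject-out, which
keeps the benchmark at ten trained counters instead of twelve times ten.
Full-scale defaults remain available through `ModelSpec()`/`TrainConfig()`.

## Degenerate inputs and tie-breaks (summary)

* Vote ties → lowest class index; equal-distance uncovered steps → earlier
  covered step.
* Window labeling: a set must cover at least half the window (ties at
  exactly half → earlier set), else null.
* Sequences with no 1-run: smoothing returns them unchanged with a warning;
  empty segments shorter than one counting window count 0 with a warning.
* Trailing samples shorter than one window are dropped, never padded.
* Odd counting windows use `floor(w/2)` start-segment samples.

## Known limitations

* No batch normalization; no GPU path; training large full-scale models on
  long recordings is slow in pure numpy.
* The reader for the externally released recording collection is a plug-in
  hook (`register_session_reader`) without a bundled adapter, as that
  collection's on-disk layout is not specified here.
* Counting assumes the recognized segment label is correct; mislabeled
  segments are routed to the wrong counter (reported as such in the
  evaluation tables).
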