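# Methods

## The problem and the approach

Acne severity guides stepwise therapy, but clinical grading scales show
poor inter-rater agreement. The approach implemented here expresses
severity as an 8-level ordinal *treatment-intensity* scale (level 1 "no
treatment necessary" through level 8 "should be on isotretinoin") and
combines two information channels:

1. **Lesion identification and counting.** An object detector finds nine
   categories of facial lesions (open/closed comedones, papules, pustules,
   nodules/cysts, atrophic and hypertrophic scars, melasma, nevi). The
   pooled inflammatory counts — I = papules + pustules, N = nodules/cysts —
   are mapped by a dermatologist-prior rule to a *grading interval*
   [lo, hi] ⊆ {1..8} rather than a single grade, because counts constrain
   severity without determining it.
2. **Whole-image ordinal classification.** A CNN maps the image to an
   8-dim softmax probability vector p.

The contribution under test is the *fusion*: the interval is applied to p
as a per-grade weight vector w, the prediction being
argmax_g p_g · w_g. With **fixed weights**, w is the binary interval mask
(1 inside, 0 outside), applied at inference only. With **learnable
weights**, one non-negative 8-vector per distinct interval (7 under the
default rule) is initialized to the ε-softened mask (0 → ε = 1e-4,
1 → 1, via a softplus parameterization that keeps weights non-negative)
and fine-tuned jointly with the network on the fused, renormalized
probabilities, so the prior can be sharpened or relaxed by the data.
Renormalization never changes the argmax; it is kept so the fused vector
is a probability distribution. Argmax ties break toward the lowest grade
(the conservative treatment choice).

## The count-to-interval rule

Thresholds (first match wins): N≥2 → [6,8]; N=1 → [5,7]; I≥30 → [5,6];
15≤I≤29 → [4,5]; 5≤I≤14 → [3,4]; 1≤I≤4 → [2,3]; I=0 → [1,2]. These
bands are this package's own calibration in the spirit of lesion-counting
scales; a YAML table can replace them, and the loader rejects any table
that is not exhaustive over count vectors. All intervals are at least two
grades wide so the prior guides rather than dictates. Increasing I or N
never lowers the interval, and only the three inflammatory categories
affect it. Counts can come from ground truth or from the detector at a
configurable score threshold; the source is an explicit pipeline flag.

## Synthetic data generator

The generator stands in for standardized frontal clinical photography so
the whole pipeline is testable end to end.

* **Canvas.** An elliptical face (semi-axes 0.33/0.42 of the side) on a
  neutral background, default side 256 px (a desk-scale stand-in for the
  multi-megapixel clinical originals; resolution is a config knob, 64 px
  is used for grading benchmarks), skin tone (224, 172, 150) with sd-2
  texture noise.
* **Facial zones.** The face is split into forehead (top 30% of the face
  height), a middle band (30–70%) whose central third is the midface and
  lateral thirds the cheeks, and the jaw (bottom 20%). Placement priors
  follow the clinical distribution patterns: closed comedones →
  forehead+midface, open comedones → forehead, atrophic scars → cheeks,
  hypertrophic scars → jaw, inflammatory lesions uniform over the face.
  Each center is drawn from the zone with probability 0.8 and uniformly
  over the face with probability 0.2.
* **Rendering.** Lesions are hard-edged parameterized ellipses with
  category-specific palette colors, sizes and styles (pustules carry a
  light center dot; atrophic scars are rings; melasma is alpha-blended),
  plus a per-lesion ±5 color jitter. This makes categories separable by a
  classical detector, which is the point: the pipeline must be testable
  without learned weights.
* **Overlap control.** A placement is rejected if it exceeds IoU 0.3 with
  a same-category box, or if either box of a cross-category pair would be
  covered beyond 60% — full occlusion would make a ground-truth box
  undetectable by construction. Persistent failure raises an error naming
  the category.
* **Grades.** A cohort samples one rule band uniformly, draws (I, N)
  inside it (papules are Binomial(I, 0.7) of the pool), adds Poisson
  non-inflammatory counts (closed comedones λ=4, open λ=3, atrophic
  scars λ=2, hypertrophic λ=0.8; melasma and nevi default to 0 so only
  the seven acne-related categories appear), and sets the grade to the
  interval midpoint (ties round half down) plus rounded N(0, 0.7²)
  jitter clamped into the interval. Generated grades are therefore always
  consistent with the rule — which is exactly the regime in which the
  fusion's value can be measured cleanly.
* **Seeding.** One master seed; subject i derives its own
  `SeedSequence([master, i])`, so any subject is reproducible in
  isolation and outputs are byte-identical across reruns.

What the generator does **not** emulate: photorealistic skin, lighting
and pose variation, lesion texture ambiguity, co-occurring dermatoses,
profile views. Passing tests therefore demonstrate the correctness and
internal consistency of the machinery and the directional value of
interval fusion when counts genuinely constrain severity — not clinical
performance on real photographs, which requires a learned detector and
real training data behind the same interfaces.

## Reference detector and detection metrics

The reference detector assigns each pixel to the nearest palette entry
(skin, background, the nine category colors, the pustule core color),
takes per-category connected components, gates them by area (≥ 0.25 of
the expected disc area), and splits components larger than 1.8 discs by
watershed on the distance transform, since adjacent same-color lesions
fuse into one blob. Red components containing core pixels are classified
pustule, otherwise papule. Scores decay linearly with mean color distance.
Thresholds are calibrated to the generator's palette; real photographs
require plugging a learned detector into the same `detect_lesions`
contract.

Evaluation is standard detection-benchmark practice: greedy one-to-one
matching per category in descending score order at IoU ≥ 0.5 (threshold
configurable; 0.5 is the conventional choice), pooled across images;
AP is the area under the all-point interpolated precision–recall curve
(monotone precision envelope, not 11-point); recall is TP/(TP+FN) at the
end of the ranking. Classes absent from ground truth are excluded from
the means (and logged) rather than counted as zero, to avoid
dataset-composition artifacts.

## Grader and training protocol

The grader is a compact CNN implemented in numpy: four 3×3 stride-2
convolution blocks (8, 16, 32, 32 channels, ReLU), global average
pooling, and a linear layer to 8 logits; He initialization, Adam
(β=0.9/0.999) with weight decay 1e-4 on convolution/linear weights,
cross-entropy loss, and a single-cycle cosine annealing of the learning
rate from 1e-3 to 1e-4 over the epochs. Augmentation: resize, random
crop, horizontal flip with probability 0.5, rotation uniform in ±20°
with empty corners filled with the skin tone (black corners would be a
trivial rotation cue). Evaluation preprocessing is resize + center crop,
deterministic. Two presets exist: the full-scale protocol
(256 → 224 px, 200 epochs, batch 32) retained as `GraderConfig.paper_mode()`,
and the desk protocol actually exercised by tests and benchmarks
(64 → 56 px, 60 epochs, batch 32), sized so a full benchmark seed trains
in about two minutes on one CPU. In learnable mode the interval-weight
parameters are trained jointly with the network; no weight decay is
applied to them.

Determinism: all randomness flows from seeded numpy generators
(init, shuffling, per-(epoch, batch) augmentation streams), so a given
machine reproduces predictions exactly; cross-platform bit-identity of
trained weights is not promised, and tests compare predictions.

## The synthetic grading benchmark

600 training / 150 test subjects at 64 px with grades generated from
counts through the default rule, intervals taken from ground-truth counts.
The unfused and fixed modes share one trained network (the mask only acts
at inference); the learnable mode trains its own. The benchmark reports
the test-set linear weighted kappa of each mode; the acceptance property
is directional (fusion should not hurt, across seeds), not a fixed kappa
value — at this scale the unfused grader is deliberately modest, which is
the regime where count priors help, mirroring the motivating observation
that lesion identification matters most at limited sample sizes.

## Agreement statistics

* **Linear weighted kappa** with agreement weights
  w(i,j) = 1 − |i−j|/(L−1): κ = (Σw·O − Σw·E)/(n − Σw·E), O the observed
  contingency, E the marginal product. The algebraically identical
  disagreement form serves as the independent test oracle. Two identical
  constant raters return 1.0 by convention (logged warning); missing
  ratings are dropped pairwise.
* **Rater selection**: per-rater mean of off-diagonal pairwise kappas,
  top-k by descending mean, ties broken by column order. **Consensus**:
  per-subject median over an odd-sized selected panel (three by default),
  which is always an integer grade.
* **ICC**: two-way random effects, absolute agreement, average measures —
  ICC(2,k) = (MSR − MSE)/(MSR + (MSC − MSE)/n) — chosen because the whole
  panel rates every subject and the consensus is an average-of-raters
  judgment; the single-measures form is a flag away. The 95% CI uses the
  Satterthwaite F approach for the single-measures coefficient stepped up
  by Spearman–Brown. Complete-case over subjects.
* **Simulated panel**: rater j rates clamp(round(g + bias_j +
  N(0, σ_j)), 1, 8). The default panel spans σ = 0.2–2.0 over seven
  raters as a clearly more consistent low-noise triple (0.2, 0.5, 0.8)
  plus four high-noise raters (1.4–2.0): the panel emulates a rating
  study whose premise is that a best subset of raters exists to be
  identified and then label the corpus. With an evenly spaced panel the
  third/fourth raters differ too little for reliable selection at 40
  subjects — a real property of kappa-based selection worth knowing, but
  not the regime the rater-selection design targets.
* **AI-vs-panel benchmark**: each trained variant is appended to the
  panel as a pseudo-rater and ranked by the same mean pairwise kappa.

## Numerical and degenerate-input choices

* Interval midpoint ties round half down (documented arbitrary choice).
* Kappa with zero expected disagreement raises unless both raters are
  identical constants (κ := 1.0); zero between-subject variance makes the
  ICC undefined; a perfect-agreement matrix returns a degenerate CI.
* IoU of identical float boxes is clamped to exactly 1 against float
  cancellation; degenerate (zero-area) boxes are rejected.
* Softmax probabilities are strictly positive, so a non-empty mask can
  never zero out the fused vector; an all-zero mask is an error.
* ε = 1e-4 keeps gradients alive for out-of-interval grades in the
  learnable path; the fixed path uses exact zeros.

## Known limitations

* The synthetic image domain is far easier than clinical photography;
  absolute kappa/AP values here say nothing about clinical performance.
* The count-to-interval thresholds are a calibration, not a clinically
  validated table.
* The reference detector is palette-bound by design.
* Learnable fusion is evaluated with ground-truth-derived intervals in
  the benchmark; detector-derived counts add noise that the benchmark
  does not measure (the pipeline flag exists to study it).
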