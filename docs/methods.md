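# Methods

`mvmar` implements and evaluates a metal-artifact-reduction (MAR) strategy
for kilovoltage CT of the head: instead of repairing the corrupted CT
directly, a synthetic CT (sCT) is generated from the patient's megavoltage
cone-beam CT (MV-CBCT), which is nearly artifact-free around metal because
the ~6 MV beam suffers almost no photoelectric beam hardening or photon
starvation.  Metal pixels themselves — which the MV scale cannot represent
(it saturates at 1400 HU) — are copied back from the original CT.  This
note records the models, the defaults, and the reasoning behind the design
choices; every number quoted here is computed by the test suite or by
`scripts/acceptance.py`, not asserted from memory.

## Pipeline

Given an aligned (CT, MV-CBCT) pair:

1. clamp MV to [-1000, 1400] HU and CT to [-1000, 3000] HU;
2. scale MV into (-1, 1) with each of three tanh variants (below) and
   translate each through the corresponding trained generator (or the
   deterministic surrogate);
3. fuse the three HU candidates per pixel by HU band (P4 fusion);
4. segment metal as (CT > 2500 HU) AND (MV > 300 HU) and overwrite those
   pixels with the CT values.

Registration is out of scope: synthetic pairs are intrinsically aligned,
and real data must be pre-registered by the user.

## Intensity scaling

Three shifted/scaled tanh transforms map HU into the network domain:

| method | CT side            | MV side            |
|--------|--------------------|--------------------|
| P1     | tanh(HU/400)       | tanh(HU/400)       |
| P2     | tanh(HU/300)       | tanh(HU/150)       |
| P3     | tanh((HU−1600)/960)| tanh((HU−800)/400) |

Each variant linearizes a different HU band (P2 soft tissue, P1 mid-range,
P3 bone/teeth), which is why the P4 fusion takes the P2 candidate below
400 HU, P1 in [400, 800) and P3 at or above 800 HU.  The inverse is
`shift + divisor·atanh(x)` followed by the modality clamp; inputs with
|x| ≥ 1 (possible for saturated network outputs) are clamped to
±(1 − 1e−7) and logged, while legitimate in-range values — including the
deeply saturated tanh(3000/300) — pass through untouched, so the round
trip is exact to well below 0.1 HU everywhere on the clamped range.

Band endpoints are half-open ([400, 800)) because the printed bands
double-cover the endpoints; the selector image that decides a pixel's band
is the P3 candidate by default (the variant most faithful at high HU),
with P1/P2/median available. Fusion operates in the HU domain, consistent
with the HU-banded way fusion quality is evaluated.

## Phantom simulator

The synthetic data generator stands in for clinical paired slices.  The
ground truth is a stylized axial head slice at the dental level on a fixed
128 mm field (any grid size samples the same anatomy): head outline,
posterior cranium base, mandible arc, seven teeth, oral cavity, two
parotids, spinal cord, and optional circular metal dentures
(aluminium/titanium/steel at 3000/3500/4000 HU ground truth).  Organ
centers are jittered ±2 mm per seed.

**kV-CT chain.**  Attenuation is decomposed into a water-like channel
(1 + HU/1000, plus a large density excess for metal) and a hardening
channel (the photoelectric excess of bone/metal, boosted by
(70 keV/E)^2.5 per spectrum bin).  Four energy bins (60–90 keV) are
projected (parallel beam, 256 angles), Poisson noise is applied at
2×10⁶ photons/ray, and the log-transformed counts pass through a standard
water-linearization correction before ramp-filtered FBP.  The
linearization removes cupping in water-like regions (soft-tissue MAE vs
truth ≈ 9 HU without metal) while bone/metal rays stay inconsistent —
exactly the residual that produces streaks.  Metal carries a density
excess (up to 90× water for steel) so rays through it genuinely starve,
reproducing the classic bright/dark streak pattern with severity graded by
material.

**MV-CBCT chain.**  The MV ground truth is a fixed strictly-increasing
piecewise-linear compression of the kV truth (soft-tissue slope 0.6,
saturating toward 1400 HU), mirroring how the CT-to-electron-density
relation differs between the modalities.  Projection is monochromatic
(no hardening → no streaks) with stronger Poisson noise
(2.8×10⁵ photons/ray), and the reconstruction is clamped to
[-1000, 1400] HU.

**What the simulator does not model:** scatter, detector response,
cone-beam geometry, helical sampling, anatomical variability beyond organ
jitter, and real tissue heterogeneity.  Passing tests therefore show that
the pipeline's logic and its artifact phenomenology are correct, not that
clinical image quality is reproduced.

**Streak artifact index.**  Streak severity is the 5–95 inter-percentile
HU spread over core soft tissue (eroded 3 px away from bone/air to avoid
partial-volume edges) within 30 mm of metal, minus the same spread on the
ground truth.  Without metal the index stays below 70 HU (the calibrated
no-metal threshold, set once from the no-metal distribution of both
simulators); with metal the kV index is typically in the hundreds while
the MV index stays at its noise floor.

## Translator

The cycle-consistent translator has the standard structure — two
generators, two least-squares discriminators, adversarial + λ·cycle (L1)
objective, λ = 10, Adam (β₁ = 0.5), batch training with a constant
learning rate followed by a decay phase.  "Attenuated by 1% per epoch" is
ambiguous; the default is the canonical linear ramp to zero over the decay
phase, with a geometric ×0.99 mode available.  An identity loss term
(|G_AB(b) − b| + |G_BA(a) − a|) is omitted from the default objective but
available by flag; the toy recipe enables it (weight 1) because, with
purely marginal per-pixel discriminators, it is the cheapest anchor
against the classic uniform-intensity-drift failure of adversarial
intensity mapping.

The networks are deliberately small *per-pixel residual intensity maps*
implemented in NumPy with manual backprop: a generator computes
`y = tanh(u + f(u))` with `u = atanh(x)` and `f` a small MLP, so it is
exactly the identity at `f = 0` and its output stays strictly inside
(-1, 1), keeping the inverse scaling finite.  Both the generator MLP and
the discriminators operate on the atanh (HU-scale) representation: in the
tanh domain, bone/teeth intensities of the two modalities differ by only
~0.02, too little for useful gradients, while in atanh space they are well
separated.  This architecture captures the degrees of freedom that matter
for the translation problem at toy scale — the two domains differ by a
monotone intensity transform plus noise — and makes training deterministic
on one CPU.  Spatial-context architectures (the U-Net family) would be
needed for real data, where artifacts are spatially structured; that is a
known limitation, not an oversight.

The toy benchmark trains at 64×64 on 100 synthetic pairs for 20 epochs
(batch 4, lr 1e-3 — higher than the clinical-mirror 2e-4 because the toy
runs see far fewer optimizer steps — and identity weight 1, above).
Success criterion: the trained
MV→CT translation has lower MAE against the CT truth than the raw MV
images ("identity baseline"); this holds for every tested seed, with MAE
dropping from ≈47 HU to ≈34–42 HU.

Because adversarial training is stochastic, a **surrogate translator**
ships alongside: the exact inverse of the simulator's MV compression map,
applied per pixel.  All fusion/MAR/metric tests run on the surrogate, so
pipeline correctness never depends on optimization behaviour.

## Imaging evaluation

PSNR uses MAX = 4000 HU (the CT dynamic range; configurable) and reports
+inf for identical inputs.  SSIM uses the standard constants (K₁ = 0.01,
K₂ = 0.03, L = 4000, 11×11 Gaussian window, σ = 1.5) with local moments
computed on the valid interior (no boundary padding), which keeps the
naive sliding-window oracle trivially comparable.  Banded variants select
pixels (or window centers) by the *reference* image's HU — the ground
truth defines tissue class.  Both metrics are verified against independent
brute-force formula evaluations to 1e−9 (PSNR) and 1e−6 (SSIM).

CT-number→RED conversion is piecewise-linear interpolation through a
monotone calibration table, flooring at RED 0 below the first knot and
extrapolating flat (logged) above the last.  Separate default curves ship
for CT and MV because their CT-ED relations differ; both are synthetic,
simulator-consistent placeholders spanning tissue (RED 0–1.456) plus
metal anchors (aluminium 2.43, titanium 3.73, steel 6.83 at the
simulator's material HUs).  Clinical users must supply scanner-specific
curves.

## Dosimetry

The toy dose engine sums 2–4 coplanar parallel beams (multiples of 90° so
every profile is verifiable against `exp(−k·depth)` in closed form), each
attenuating as exp(−k·∫RED·dl) with k = 0.005 /mm per unit RED,
normalized to the prescription (6000 cGy) at a stated point.  No scatter,
no buildup: just enough physics for RED differences to move DVH metrics.

Gamma analysis is global: normalization defaults to the reference dose
maximum (prescription-normalization by flag), low-dose cutoff defaults to
0% (a 10% flag exists), and the search is exhaustive within 3·DTA — any
farther test point has a distance term > 3 and cannot change pass/fail,
so the result equals a full exhaustive search exactly.  Optional ×4
linear up-sampling of the test grid can only increase the pass rate.
Loosening either criterion never lowers the rate (property-tested), the
ordering the clinical criteria pairs (2 mm/2% vs 1 mm/1%) always exhibit.

DVH metrics are interpolated order statistics: Dx is the dose exceeded by
exactly x% of the ROI volume, Vx% the ROI fraction at or above x% of
prescription, D0.1cc the dose exceeded by the hottest 0.1 cm³ (falling
back to Dmax with a warning for ROIs smaller than 0.1 cc, as happens for
the 2-D spinal-cord analog).  The comparison report covers PTV
(Dmean, D5, D95, V95%, V100%, V110%), mandible (D2, Dmean), oral cavity
and parotid (D50, Dmean), and spinal cord (D0.1cc).

## Problem sizes and determinism

Default study sizes — 128×128 phantoms (256 projection angles), 20 seeded
phantoms for the artifact dichotomy, 10 for end-to-end MAR, 3 training
seeds at 64×64 for the toy benchmark — were chosen so the full suite and
the acceptance script each complete in minutes on one CPU while keeping
every per-case margin wide.  All randomness flows through
`numpy.random.default_rng` seeds derived from a single global seed; reruns
are bit-identical for every deterministic stage.

## Known limitations

* The translator is an intensity map: it cannot use spatial context, so it
  denoises nothing and cannot fix spatially-structured residuals.
* The default RED curves and the simulator's material constants are
  self-consistent placeholders, not clinical calibrations.
* The dose engine is primary-beam only; absolute dose values are not
  clinically meaningful, only differences between plans computed on
  different images of the same anatomy.
* 2-D slices only; the clinical workflow's 3-D structures are represented
  by their slice analogs (e.g. D0.1cc on a slice ROI assumes 1 mm
  thickness).
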