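# Methods

## Problem and pipeline

Epicardial fat volumetry from Dixon cardiac MRI proceeds in four steps:
(1) reconstruct water (W) and fat (F) images from a two-echo gradient-echo
acquisition; (2) form the per-voxel fat fraction `FF = F/(F + W)`;
(3) within a reader-drawn outer epicardial boundary on each axial slice of
the analysis range, classify voxels with FF strictly above a fixed
threshold (0.35) as fat — this removes the low-FF blood of the chambers and
great vessels; (4) convert per-slice voxel counts to millilitres with the
voxel volume and integrate across slices. On a cine series, segmentation is
performed on the single frame whose acquisition time is closest to the
reference trigger delay (ties to the earlier frame); the other frames are
advisory for the reader, not quantified. The package implements this
pipeline plus the observer-variability statistics used to evaluate it, and
a synthetic cine phantom that supplies ground truth.

## The phantom

The phantom is a stylized nested-ellipsoid thorax, not a deformable human
atlas: blood pool inside a myocardial shell inside an epicardial fat rind,
a one-voxel parietal pericardium obtained by binary dilation of the
epicardial surface, a static paracardial fat slab just outside the
anterior pericardium, and two static lungs. It is deliberately simple —
its job is to exercise every pipeline stage with known truth and to
reproduce the one physiological contrast the cine technique exploits:
cardiac-attached tissue moves, paracardial fat does not.

**Geometry.** Default grid 64×64×40 voxels at 1.5×1.5×3.0 mm (the acquired
resolution of the emulated protocol; the 96×96×120 mm field of view is a
scaled-down thorax that keeps runtimes in seconds). Outer semi-axes
(mm): blood pool (20, 18, 28), myocardium (27, 24, 35), epicardial fat
(33, 29, 41), giving ≈69 ml of epicardial fat. A sizing check rejects grids
that cannot contain every shell plus the motion excursion, naming the
first shell that does not fit.

**Motion.** Frame `t` of `n` applies a longitudinal (apical, −z)
translation `d(t) = A·sin²(πt/n)` with `A = motion_amplitude_mm`
(default 12 mm, a typical atrioventricular-plane descent) and an in-plane
radial scaling `1 − c·sin²(πt/n)` with `c = contraction_fraction`
(default 0.12). The sin² time course peaks mid-cycle (systole analogue)
and returns smoothly to baseline; no published motion equations exist for
this protocol, so smoothness and the epicardial/paracardial contrast were
the design criteria. Static compartments are carved clear of the union of
all cardiac positions, so their voxel sets are frame-invariant by
construction.

**Signals and noise.** Each tissue has a nominal fat fraction and a total
signal; the defaults put every non-adipose tissue far below the 0.35
threshold (blood 0.02, myocardium 0.05, pericardium 0.10) and both fat
depots far above it (epicardial 0.80, paracardial 0.85), with the
contrast-enhanced blood pool as the brightest compartment (W+F = 1.0).
Channel noise is zero-mean Gaussian, independent per channel and frame,
clipped at zero (magnitude images at moderate SNR; no Rician correction).
The protocol's real SNR is not published, so `noise_sigma` is a free
parameter; 0.02 (2% of the blood-pool signal) is the default working
point. All randomness flows from `PhantomSpec.seed`; the anatomy is
seed-independent.

**Echoes.** `synthesize_echoes` applies
`S(TE) = (W + F·e^{iθ})·e^{i2πψTE/1000}`, `θ = 2πΔf·TE/1000`, with echo
times 2.3/3.9 ms and water–fat shift Δf = −220 Hz (3.5 ppm at 1.5 T,
configurable). The optional field map ψ is a deterministic smooth cosine
lobe with settable peak amplitude.

**What the phantom does not emulate** — and hence what passing tests do
not show about patient data: realistic anatomy (atria, vessels, the
AV-groove fat the motion cue matters most for), partial-volume voxels
(labels are hard assignments, so noiseless threshold recovery is exact by
construction), respiratory motion, flow and off-resonance artifacts,
contrast-agent kinetics, and human readers. Observer variability is
*simulated* as morphological boundary jitter, which captures the
"where exactly is the border" component of reader disagreement but not
systematic reader bias or slice-selection disagreement.

## Dixon inversion

Per voxel, the two complex echoes give four real equations in (W, F);
`separate_ideal` solves the 2×2 normal equations in closed form and clips
negative solutions (possible under noise) to zero. Echo pairs with
`θ₁ ≡ θ₂ (mod 2π)` are rejected as unable to separate the species.
Field-map estimation (region growing, graph cuts) is intentionally out of
scope: ψ is an input (`separate_with_fieldmap` demodulates it first), since
the package needs a correct reference inversion, not a replication of a
scanner vendor's reconstruction.

## Numerical choices

- FF denominator floor `eps` defaults to 10⁻⁶ of the peak channel signal;
  voxels at or below it get FF = 0 (void convention). Negative W/F inputs
  are clipped to zero with a logged count.
- The fat threshold is strict (`FF > 0.35`): a voxel exactly at the
  threshold is not fat ("over 35%").
- Frame selection minimizes |frame time − trigger delay| with ties broken
  toward the earlier frame.
- Volumes use the grid the segmentation ran on (the phantom's acquired
  1.5×1.5×3.0 mm grid by default; `quantify_volume` takes any spacing, so
  reconstructed-grid data work unchanged). Totals are computed as
  (total voxel count)·(voxel volume), which is the per-slice sum in exact
  arithmetic and bit-reproducible against count-based ground truth.
- Polygon ROIs are rasterized with even-odd fill; a voxel belongs to the
  ROI iff its centre is inside. Indices are 0-based, slice axis = z.
  Self-intersecting polygons are rejected.

## Statistics

Bland–Altman uses sample SD (n−1) of the per-slice differences
(first − second) and ±1.96 SD limits. Per-slice percentage errors are
normalized by the patient's total fat volume, taken as the mean of the two
measurements' totals — the convention such per-slice percentages usually
leave unstated, so it is documented rather than asserted against any
external figure. The ICC is the two-way random-effects, absolute-agreement,
single-measures form ICC(2,1) (the standard choice when observers are a
random sample), computed from ANOVA mean squares via pingouin, with
ICC(3,1) selectable; an all-identical table returns 1 by convention with a
warning. Category boundaries are half-open with the upper class winning:
poor < 0.5 ≤ moderate < 0.75 ≤ good < 0.9 ≤ excellent. BSA defaults to
Mosteller √(h·w/3600) (Du Bois selectable). The BMI regression is ordinary
least squares with the two-sided slope t-test (n−2 df); paired comparisons
use the paired t-test (identical pairs → p = 1 by convention) or the
Wilcoxon signed-rank test (exact for small tie-free samples; all-zero
differences are a degenerate-input error). Significance is declared at
P < 0.05.

## Simulated observer study

Five phantom "patients" (heart radii scaled 0.9×–1.1×, independent noise
seeds), two simulated observers, every 10th slice of each patient's
analysis range. Each (patient, observer, slice) draws one latent offset
u ~ U(−1, 1); at jitter level j the observer's ROI boundary on that slice
is dilated (u > 0) or eroded (u < 0) by `round(j·u)` voxel layers before
re-quantification. Using common random numbers across levels makes each
observer's error magnitude non-decreasing in j, so the between-observer
ICC is non-increasing in j by construction, and j = 0 reproduces the
ground truth exactly (ICC = 1). On the default 40-slice phantom this
yields 3 analysed slices per patient (15 paired data points); the
full-scale protocol (100 slices, 10 per patient, 50 points) is reproduced
arithmetically in the acceptance script rather than volumetrically, to
keep the default run in seconds.

## Known limitations

Two-point Dixon with a *known* field map only (no ψ estimation, no
multi-peak fat model, no T2*); Gaussian not Rician noise; hard tissue
labels (no partial volume); stylized anatomy; simulated rather than human
observers; no automatic epicardial border detection; paracardial fat is
present in the phantom but not quantified.
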