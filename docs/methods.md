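# Methods

## Isoeffect model

The linear-quadratic (LQ) isoeffect engine treats two regimens as
equivalent when they carry the same biologically effective dose,
BED = D·(1 + d/(α/β)). For a target fraction count n the isoeffective
photon total dose is the positive root of n·d·(1 + d/(α/β)) = BED; the
discriminant 1 + 4·BED/(n·α/β) is strictly positive for positive inputs, so
the closed form never needs a branch choice, and an independent bracketing
root-finder is kept in the test suite as an oracle. The model assumes a
slowly proliferating tumour: no repopulation/time factor, no
normal-tissue constraints, no tumour-control-probability layer.

**RBE convention.** The package uses a constant proton RBE (default 1.1,
values below 1 rejected) and defines the proton absorbed dose matching a
photon dose as photon/RBE, i.e. proton dose × 1.1 = photon-equivalent dose
in Gy (RBE). Fraction-size- or depth-dependent RBE is out of scope.

**α/β bracket.** Prostate α/β is uncertain; prescriptions are bracketed
with α/β ∈ {1, 3, 5} Gy and the max/min ratio of the bracketed totals is
reported. Ratios above 1.10 are flagged clinically significant; ratios in
(1.05, 1.10] are flagged borderline, comparable to dose-delivery error.
Below the reference fraction size the lowest α/β yields the lowest
equivalent dose; above it the ordering flips, so presentation columns
(min/mid/max) are *sorted* values, not a fixed α/β order.

**Rounding.** Ratios and all table values are computed from unrounded
doses; presentation rounding (doses to 0.1 Gy, ratios to 0.01) happens only
in `table_to_frame`. Independently published versions of this table follow
an unstated convention whose high-n totals sit up to ~1.7% below the direct
recomputation (their n = 44 row prints a 1.6 Gy fraction size where the
model requires the reference 1.8 Gy); the package reproduces the low-n
entries and all ratios at n = 1, 20, 45 to printed precision and makes no
attempt to force agreement elsewhere.

## Second-cancer risk

Risk is deliberately linear and age/sex/latency-free: mean organ equivalent
dose (Sv) × LAR coefficient (%/Sv). The neutron weighting factor (default
6.2) is a spectrum-averaged value suitable for combined external (treatment
head) and internal (in-patient) neutrons. Built-in coefficients exist only
for bladder (0.66 %/Sv) and rectum (0.19 %/Sv; a whole-colon coefficient
scaled by the rectum's 0.2 mass fraction) — other organs require
user-supplied coefficients. Combined risks are reported at two decimals in
percent, with raw values available (`decimals=None`). Organ labels are
normalised case-insensitively with a small synonym map. Printed dose tables
are rounded per column, so a table's `total` may differ from
external + internal by 1 mSv; the loader tolerates exactly that much.

## MLC fitting

One leaf pair per 0.5 cm row; rows tile the aperture's extent along the
stacking axis, anchored by default so the extent's lower bound is a leaf
boundary (the leaf-grid registration is not physically determined, so an
explicit `anchor` option exposes the alternative). Tips are the outermost
crossings of the row-midline with the aperture — for non-convex rows this
spans any interior island, matching what a single leaf pair can do.
Scalloping is quantified as the symmetric-difference area via exact polygon
clipping; the tests verify it against a cell-centre rasterisation oracle at
0.01 cm and check that halving the leaf width never increases the error for
convex apertures. Leaf-end transmission, edge scatter, and leaf divergence
are not modelled.

## Plan dosimetry

Voxel membership is centre-in-structure (no partial volumes), which
summary means inherit. Normalisation is a uniform rescale to the mean CTV
prescription (default 76 Gy (RBE)); field combination rescales each field
to a per-field CTV mean (default 34.5 Gy) before summing, making the
two-field CTV mean 69 Gy an exact identity rather than a numerical
accident. DVHs are cumulative only, evaluated at bin edges (default
0.1 Gy) as the percentage of voxels at or above each edge; `volume_at_dose`
returns the tabulated value at exact edges and the conservative next-edge
value between them. Grids/masks round-trip through NRRD via SimpleITK in a
right-handed patient frame (x left-right, y anterior-posterior, z
inferior-superior) with voxel-centre origins. The packaged cohort summary
table is a fixture transcribed as printed; its anterior-rectal-wall mean
under both MLC techniques duplicates the CTV row and is inconsistent with
the corresponding standard-of-care value — it is preserved, not corrected.

## Cost model

Fractions are delivered from a Monday start, `fractions_per_week` per week
(default 5), with the remaining days of each started week counted inside
the delivery span: span = n + (7 − fpw)·⌊(n − 1)/fpw⌋, which reduces to
n + 2·⌊(n − 1)/5⌋ for the weekday calendar and to exactly n for daily
treatment. Planning days (default 5) extend a course but cancel in any
between-regimen savings. Savings are day-difference × per-diem rates,
unrounded; defaults are $51–71 meals, $80–185 lodging, $200 wages (a
$52,100 annual income over 260.5 workdays). Going from 44 to 25 weekday
fractions saves 27 calendar days and $5400 in wages. Facility-side revenue
effects are not modelled.

## Synthetic data

The generators are pure functions of their spec (seed included) and exist
to make every pipeline runnable and testable without patient data.

**Plans.** A 64×40×40 grid at 0.5 cm spacing (32×20×20 cm) holds an
ellipsoidal CTV at the centre (semi-axes drawn so the volume lands in the
clinical 46.3–81.8 cm³ interval), an anterior bladder, a posterior
elongated rectum, and two lateral femoral-head spheres. Each of the two
opposed lateral fields has a depth profile with a 70% entrance plateau, a
flat SOBP plateau, and a sigmoid distal falloff, times a product of
error-function lateral penumbrae (σ = 0.35 cm, widened 6% for the MLC-only
variant as a stylised scalloping/air-gap effect), plus 1% multiplicative
noise. Sampled water-equivalent ranges (22.0–27.1 cm) and SOBP widths
(8–10 cm) are mapped onto the phantom so each field's range ends 0.7 cm
past the contralateral CTV edge — the choice a planner makes — which is
what gives the organs-at-risk their realistic ~⅓-of-prescription
(femoral heads) and low-mean (bladder, rectum) doses. This is a shape
model, not transport: no Bragg-peak physics, no heterogeneities, no
scatter, so passing tests demonstrate the correctness of the dosimetry
operations, not dosimetric realism of any particular patient.

**Neutron tables.** Anchored to the packaged per-organ Monte Carlo values;
log-normal noise (default 5%) is resampled per organ until the structural
signature holds (MLC-only external below, internal above the
standard-of-care values), failing loudly if the noise makes that
impossible. With zero noise the anchors are returned exactly (totals as
exact component sums).

**Apertures.** A radial Fourier perturbation of a circle,
r(θ) = R(1 + Σₖ aₖ cos(kθ + φₖ)), harmonics 2–6, amplitudes scaled by an
irregularity parameter, damped 1/k and capped so r > 0 (which guarantees a
simple curve).

## Problem sizes

Defaults keep everything interactive: equivalence tables are closed-form
(milliseconds); synthetic plans are ~10⁵ voxels per field; the MLC property
checks use 100 random convex apertures with oracle rasterisation at 0.01 cm
on a subsample. The full test suite runs in well under a minute.
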