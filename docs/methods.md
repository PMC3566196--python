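# Methods

## Physical model of the phantom

Every lumen is a rigid circular tube carrying fully developed laminar
pulsatile flow driven by a band-limited periodic pressure gradient.
Writing the driving gradient (−dp/dz) as a Fourier series
G(t) = Re[Σₙ Gₙ e^{i n ω₀ t}] with ω₀ = 2π/T, the axial velocity is the
steady Poiseuille parabola for G₀ plus, per oscillatory harmonic, the
Womersley solution

u_n(r,t) = Re[ (Gₙ / iρωₙ) (1 − J₀(Λₙ r/R)/J₀(Λₙ)) e^{iωₙt} ],
Λₙ = i^{3/2} αₙ,  αₙ = R √(ωₙ ρ/μ),

with volumetric flow
Qₙ(t) = Re[ (Gₙ πR²/iρωₙ)(1 − 2J₁(Λₙ)/(Λₙ J₀(Λₙ))) e^{iωₙt} ].
Harmonics are capped at 8 so the 32-phase sampling stays alias-free.
The CSF channel is a circular tube, not an annulus around the cord;
this preserves the exact analytic oracle (annular geometry is out of
scope). A separable "plug" disc type (one temporal waveform, optional
radial amplitude profile) complements the Womersley discs for encoding
and segmentation tests, where a single shared waveform shape is the
defining condition.

Velocity maps to image phase as φ = πv/VENC, wrapped into (−π, π];
noise is Gaussian in the phase image (adequate at the simulated SNRs
and simpler than complex-Rician bookkeeping); decoding inverts
v = VENC·φ/π with no unwrapping — the operator is assumed to have
chosen VENC high enough for the lumina of interest on each series.
Partial-volume effects are approximated by pixel-centre sampling (a
pixel is lumen iff its centre lies inside the disc), which keeps the
flow oracle exact on the same discretization the quantification uses.
Fluid defaults: blood ρ = 1.05 g/cm³, μ = 0.04 P; CSF ρ = 1.0007,
μ = 0.01 P. The cardiac period defaults to 1.0 s (configurable); pixel
area defaults mimic a 140 mm FoV at 256 matrix.

The default exam carries ten lumina on a 160×160 grid (0.03 cm
pixels): internal carotids at 75 % and vertebrals at 25 % of an
800 ml/min tCBF, jugulars at 70 % and three secondary veins at a
combined 10 % of tCBF — the remaining 20 % is deliberately unmeasured
venous return that the steady-state correction must absorb — and a
purely oscillatory CSF channel whose first-harmonic gradient amplitude
(0.020 mmHg/cm, peak-to-peak 0.040) sits at the physiological scale of
cervical CSF pulsation. Artery/vein pulsatility fractions (0.5/0.25/
0.10 of the steady gradient) produce arterial waveforms far more
pulsatile than venous ones, as in vivo.

## Segmentation

PUBS scores each pixel by the Pearson correlation between its
velocity-time series and a unit-norm reference taken from a seed pixel;
the lumen is the seed's 4-connected component above threshold.
Defaults: threshold 0.85 (inclusive — pixels exactly at threshold are
kept), minimum region 2 px, anticorrelated pixels rejected (so
arteries and veins sharing a waveform shape but opposite sign never
merge); a polarity option admits |r| ≥ threshold for the CSF channel,
whose flow reverses over the cycle on the low-VENC series. The
threshold and statistic are package choices, exposed in `PubsConfig`.
"Semi-automated" means exactly one seed pixel per lumen, supplied by
the caller; there is no automatic vessel detection, manual editing, or
multi-slice propagation. Static background pixels have zero temporal
variance and are excluded outright. Aliased (wrapped) pixels get no
special handling. Note the physics: multi-harmonic Womersley lumina
have radially varying waveform *shape*, so rim pixels decorrelate from
the centre reference even without noise; exact recovery is expected
(and tested) only for separable lumina.

## Flow quantification

q(t) sums pixel velocities over the mask times the pixel area
(ml/min). All cycle integrals use the trapezoidal rule with periodic
closure on the 32-phase grid — on a uniform grid the full-cycle
integral reduces to mean·T, which is exact for band-limited periodic
signals; the cumulative integral carries the usual O(Δt²) error
(≈ 0.3–2 % for harmonics 1–2 at 32 phases). Venous waveforms are
stored outflow-positive and CSF caudal-positive via an explicit
per-label sign map. Drainage percentages use cycle-mean flows, one
number per subject. The CSF stroke volume integrates the positive lobe
of the mean-subtracted waveform by default (the pure back-and-forth
displacement); a raw-lobe mode exists for waveforms with a physical
steady component.

## Volume balance, pressure gradient, compliance

The venous correction is multiplicative — V′ = V · mean(A)/mean(V) —
modelling unmeasured channels as parallel pathways proportional to the
measured ones (an additive-offset mode is provided). After it,
mean(A − V′) = 0 exactly and the volume-change waveform closes to
round-off (< 1e-9 ml, asserted). The balance subtracts the CSF
waveform's oscillatory component; any residual steady CSF offset (bulk
flow or eddy-current bias in real data) would otherwise reopen the
closure that the venous correction enforces. ICVC is max − min of the
cumulative waveform (rather than the excursion from the cycle-start
baseline, which depends on the arbitrary trigger phase).

The pressure gradient is recovered per interior CSF pixel (full
4-neighbourhood inside the mask) as G = ρ∂v/∂t − μ∇²v, i.e. the
driving gradient −∂p/∂z, so its sign matches the phantom's prescribed
harmonics; the 5-point Laplacian is exact on the steady parabola and
the cyclic centred time difference attenuates harmonic n by
sin(nω₀Δt)/(nω₀Δt) (0.6 % at n = 1, 32 phases). The median across
interior pixels (mean available) is robust to rim pixels, where both
the finite-difference stencil and partial-volume effects are worst —
at α = 10 the Stokes boundary layer is ~R/α·√2 thick, about one pixel
at the tested resolutions. Recovery error on noiseless phantoms at 12
px/radius is < 0.5 % relative RMS across α ∈ {2, 5, 10}.

Compliance index CI = ICVC/(PTP-PG · d) and MRICP = a/CI + b. The
constants are calibration, not physics: d converts a gradient
amplitude (mmHg/cm) into an effective pressure fluctuation, and (a, b)
parameterize the inverse compliance–pressure law. The defaults
(d = 1.8 cm, a = 73 mmHg, b = 0) are chosen so that group-mean inputs
of the packaged tables land in the reported ranges; they are
under-determined by published group means alone (mean-of-ratios vs
ratio-of-means differ by ~8 %) and nothing in the validation depends
on them — the inverse law CI·(MRICP − b) = a is checked exactly
whatever the constants. MRICP is capped (default 100 mmHg, with a
warning) in the vanishing-compliance limit.

## Synthetic cohorts

`generate_cohort` draws per-subject summaries (tCBF, jugular fraction,
secondary split, ICVC, PTP-PG, CSF SV) from normal distributions
clipped to physical bounds, with matched pair IDs across the two
groups. Clipping (winsorizing) rather than renormalized truncation
keeps the configured means essentially intact (a renormalized
truncation at [0, 100] would shift a mean-60.9/sd-21 fraction by −1.4)
and produces a point mass at zero for the secondary fractions —
matching the zero-inflation of those channels in real cohorts.
Feasibility (jugular % + secondary % ≤ 100) is enforced by shrinking
the secondary split proportionally, leaving the headline jugular
fraction undistorted. Group defaults are the study's printed means and
SDs; the secondary-split SDs and CSF-SV SDs are not printed as
summaries, so the split uses sd = mean and CSF SV the SD of the
printed per-subject values. MRICP is derived from each subject's ICVC
and PTP-PG through the calibration, so the inverse law holds exactly
per synthetic subject. What the generator does *not* emulate: within-
pair correlation beyond the shared pair label, covariance between
variables (each is drawn independently), measurement error structure,
or age/sex effects — so passing cohort tests demonstrates calibration
of the statistics under independence, not robustness to real
covariance structure.

## Statistics

Continuous variables use the two-step rank procedure: pool both
groups, convert to midranks (missing values excluded, n reported),
then fit ranks ~ group with a random intercept per matched pair and
test the group effect two-sided. For balanced complete-pair data this
REML fit with an *unconstrained* pair variance component is
algebraically the paired t-test on within-pair rank differences, and
is computed in that closed form (the constrained-at-zero boundary case
would otherwise change the standard error unpredictably and inflate
the empirical size); incomplete pairs fall back to a numerical MixedLM
fit, with a paired-t fallback on complete pairs if it fails to
converge, flagged in the result. Empirical size at nominal 0.05 over
1000 null cohorts (n = 15/15) is ~0.05.

Mann–Whitney U uses an exact permutation p for pooled n ≤ 12 — a
rank-sum counting DP over doubled midranks, valid with ties (the
permutation null is symmetric because reflecting ranks preserves tie
structure) — and the tie- and continuity-corrected normal
approximation above that. The switch at 12 keeps enumeration cost
trivial while the approximation is accurate (< 0.02 vs enumeration on
tie-free data just above the switch). Spearman correlation is Pearson
on midranks with the t approximation (n − 2 df). Two-sided α = 0.05
throughout; no multiplicity correction. Which continuous variables get
the mixed model vs the ordinal grades getting Mann–Whitney follows the
report layout in `pipeline.reproduce_tables`.

## Fixtures and the reproduction report

The packaged tables store the printed per-subject values verbatim
(including a row-order quirk in the control listing and "n.a." grades
for three subjects, loaded as missing and excluded pairwise), guarded
by SHA-256 checksums. The report recomputes every printed group cell
and flags agreement within max(one unit of the summary's printed
precision, half a unit of the per-subject printed precision) — the
latter is the worst-case mean shift induced by the per-subject values
themselves being printed rounded; the control-group MRICP mean is the
one cell that needs it (printed 8.77 at two decimals from one-decimal
inputs; recomputed 8.75). Exact mixed-model p-values of the original
analysis are not a reproduction target (software and REML details
unprinted); the battery reproduces the procedure and its published
qualitative pattern.

## Problem sizes

Defaults used by the test suite and the acceptance script: 160×160
(default exam) and 48–80 px grids (single-disc phantoms) at 32 cardiac
phases; 12 px/radius for finite-difference oracles; 50 segmentation
replicates at SNR 10; 1000 null and 500 alternative cohorts for the
size/power checks. These sizes put discretization errors well below
the stated tolerances while keeping any single check in seconds.

## Known limitations

No k-space/MR physics (TE/TR, flip angle, eddy currents, Maxwell
terms), no background-phase correction, no vessel wall motion or
compliance, no DICOM ingestion, no multi-slice handling, no automatic
vessel classification. The compliance/ICP calibration is nominal, not
subject-specific; MRICP values are meaningful relatively, not as
absolute invasive-equivalent pressures. The spinal cord within the
low-VENC field of view is treated as static background.
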