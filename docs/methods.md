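# Methods

This note documents the models implemented in `cryor`, the assumptions
behind them, the defaults that matter, and what the synthetic-data
scenarios do and do not emulate.

## Photocycle chain model

Flash-photolysis data are modeled as a sequential, unbranched
first-order chain (e.g. K → M1 → M2 → recovered ground). With rate
constants kᵢ = 1/τᵢ the populations follow the closed-form Bateman
cascade

  P_m(t) = (∏_{i<m} kᵢ) Σ_{i≤m} e^{−kᵢt} / ∏_{j≠i, j≤m}(kⱼ − kᵢ),

starting with unit population in the initial state. The solution is
singular for equal rates, so schemes whose lifetimes are closer than a
relative 1e-9 are rejected with an instruction to perturb one of them
rather than silently regularized. Branched schemes are rejected, not
approximated: the CryoR photocycle used here is sequential, and a
branching fit would not be identifiable from the packaged data. Whether
an unresolved intermediate sits between K and M1 is left open; the
simulator accepts both two- and three-state chains.

Difference-absorbance matrices are assembled as
ΔA(λ, t) = Σ_s S_s(λ) P_s(t), with per-state difference spectra S_s
built from Gaussian bands *in wavelength* (nm). Spectral bands of
retinal proteins are closer to Gaussian in energy; the wavelength
parameterization is an approximation adopted because all the axes in
this problem domain are reported in nm, and nothing downstream depends
on the band shape tails.

## Global lifetime analysis (decay-associated spectra)

The global fit uses variable projection: for trial nonlinear parameters
(lifetimes, optionally IRF width σ and time zero t₀) the basis
φᵢ(t) = exp(−t/τᵢ) ⊛ N(t₀, σ) is formed analytically,

  φ(t) = ½ exp(σ²/2τ² − (t−t₀)/τ) · erfc((σ/τ − (t−t₀)/σ)/√2),

evaluated through `erfcx` on the branch where `erfc` underflows; the
per-wavelength amplitudes (the DAS) are then the linear least-squares
solution, and only the small nonlinear parameter vector is iterated
(`scipy.optimize.least_squares`, TRF, bounded). Lifetimes are optimized
in log space — they span femtoseconds to minutes — and reported sorted
ascending with asymptotic standard errors from the projected Jacobian.
Default starting lifetimes come from the peaks of a quick
lifetime-distribution analysis (10 points/decade), padded with
log-spaced guesses; this makes the fit self-starting on all packaged
scenarios. There is no constant-offset basis function: a non-decaying
background ends up in the residuals by design, which the residual
diagnostics expose.

The model class contains the generator exactly (for noiseless in-class
data the fit residual is at machine precision), so parameter-recovery
tests measure the effect of noise and of IRF/lifetime correlations, not
model error.

## Lifetime-distribution maps

The model-free analysis solves, per wavelength,

  min_x ‖Φx − d‖² + α²‖x‖²,  Φ[t,g] = e^{−t/τ_g},

on a log-spaced lifetime grid (default 30 points/decade spanning
0.5× the first positive delay to 2× the last). Amplitudes are
unconstrained in sign, so ground-state bleach and product bands appear
with opposite polarity. The identity (zeroth-order Tikhonov) penalty is
used rather than a derivative penalty; the published analysis delegates
this to external software without stating its functional, so the
simplest penalty whose behavior is fully testable was chosen, and the
solution is computed once per α from the SVD of Φ. α is chosen by the
discrepancy principle at the declared noise level when the data carry
one (`metadata["noise_sigma"]`, set by every generator), and by GCV
otherwise. Transition lifetimes are read from the local maxima of the
band-averaged |amplitude| distribution — the maximum-amplitude reading
rule — with maxima below 5% of the global maximum suppressed as noise
ripple.

Times ≤ 0 (pre-excitation samples of IRF-limited data) are excluded
from the LDM design; the exponential basis carries no IRF convolution.
On the femtosecond scenarios this biases distributions near the IRF
width, which is why the LDM serves as initializer and cross-check while
the IRF-aware global fit provides the reported lifetimes.

## PSS thermal recovery

Slow recovery series are fitted to A(t) = offset − amplitude·e^{−t/τ}
by nonlinear least squares (lmfit) with data-driven starting values.
Following the measurement protocol, 100 s (the LED-on period) is
subtracted from the spectrometer time stamps before fitting. For a
monoexponential this shifts only the amplitude (by e^{offset/τ}), not
τ — the correction matters for reporting amplitudes, and the test suite
pins this invariance down explicitly. A flat series has no
identifiable τ and is rejected.

## Coherent-oscillation spectra

Residuals (data − global-fit reconstruction) are averaged over a
wavelength band — the analysis targets the wings of the ESA and GSB
bands, where oscillations are strongest relative to the exponential
background — then linearly detrended, Hann-tapered and transformed on a
uniformly sampled time window (enforced to 1% spacing tolerance).
Power is normalized so Parseval's identity holds exactly against the
windowed time-domain signal. Frequencies convert to wavenumbers with
c = 2.99792458×10¹⁰ cm/s exactly.

The resolution floor is 1/(c·T) for window duration T. A reported
spectral peak below the floor corresponds to an oscillation period
longer than the analyzed window — it cannot represent an observed
oscillation and is flagged `window-artifact`. This is the rule that
assigns the 32 cm⁻¹ feature of the low-pH scenario to the analysis
window rather than to a vibrational mode, while the 128 cm⁻¹ mode
(260 fs period) is resolved. Zero-padding (8×) refines the reported
peak positions by interpolation; it does not change the floor, which
depends only on the physical window length.

## pH titration model

Spectral species are ordered acidic → alkaline and weighted by a
sequential-protonation scheme: species s carries weight
∏_{j<s} 10^{n_j(pH − pKa_j)}, normalized to sum to 1 (computed in log
space). With Hill coefficients n_j = 1 this is the standard
Henderson–Hasselbalch ladder, and it reproduces a direct mass-balance
equilibrium calculation to rounding error (tested). The
620 ↔ 540 transition of CryoR1 is reported not to be a simple
counterion protonation; Hill coefficients are therefore exposed per
transition but default to 1, and a parallel-equilibria variant was
deliberately not implemented — with the packaged data the two schemes
are not distinguishable, and an untestable code path is worse than a
documented absence.

The joint titration fit optimizes pKa values and one visible Gaussian
band per species (center, σ, amplitude ≥ 0) against all spectra
simultaneously, over a fit window of 320–780 nm that excludes the
aromatic 280-nm band. Initialization is heuristic — candidate peak
positions pooled from the extreme- and mid-pH spectra, assigned red to
blue — and the fitted species are re-sorted red → blue so that index 0
is always the most acidic form. λmax tracking interpolates the discrete
maximum parabolically (flat tops and edge maxima fall back to the
discrete argmax, flagged); the total shift is λmax(lowest pH) −
λmax(highest pH) within a 450–700 nm visible window, which excludes the
deprotonated-RSB band at 400 nm just as the published shift refers to
the visible absorption maximum.

## Photoswitch (PSS / blue-light quenching) model

Steady-state illumination is modeled with two photoactive species,
ground and M. The M1/M2 distinction is collapsed because only the
minutes-lived component survives on the 100-s protocol timescale; a
millisecond intermediate never accumulates under continuous-wave LEDs.
Within a protocol step the rates are constant and the exact solution

  G(t) = G_ss + (G₀ − G_ss)e^{−κt}, κ = k_GM + k_MG + k_th,
  G_ss = (k_MG + k_th)/κ

is used per segment (verified against a stiff ODE integrator to 1e-8).
Photoexcitation rates are k = φ · j · σ, with photon flux
j = P·λ/(h·c·A) at the LED center wavelength, cross section
σ = (1000·ln10/N_A)·ε from the extinction scale (default
50 000 M⁻¹cm⁻¹ per unit band amplitude), and the analytic Gaussian
overlap of the species bands with a unit-area Gaussian LED line
(catalog center, default 25 nm FWHM, default beam area 1 cm²). The
LED centers and powers (565 nm / 1.05 mW, 420 nm / 0.19 mW, 100 s) are
the published protocol; emission width, beam geometry and quantum
yields are not published. φ_forward = 0.3 is a typical microbial-
rhodopsin photoreaction yield; φ_back = 0.75 was set so that 100 s of
the weak 420-nm LED returns >95% of the protein to the ground state,
matching the reported complete dark-state recovery under blue light.
The thermal rate defaults to 1/942 s⁻¹ (20 °C recovery).

## Patch-clamp charge analysis

Charges are trapezoidal integrals of baseline-corrected current over
per-pulse windows on the native sampling grid (no resampling; at the
scenario's 5 kHz sampling the quadrature error is ≤0.5%, tested against
the analytic pulse integral). The baseline is the mean current before
the first pulse. "Until the photocurrents ceased" is operationalized as
a charge floor: accumulation stops at the first pulse below 1% of the
first pulse's magnitude (the published protocol gives no numeric
criterion). Signs follow the electrophysiology convention (negative =
inward); totals are never rectified.

The subpopulation estimate implements the charge-ratio constraint
system exactly as printed (α, β, p_non-prot = α(1−β)/(α−β)). The
algebra assumes the charge-to-fraction proportionality constant is
voltage-independent and the total protein count constant. α = β is a
removable singularity of the formulas and is reported as indeterminate;
fractions outside [0,1] are reported but flagged invalid rather than
clipped, because they indicate inconsistent input charges.

## Motif extraction and filtering

Position mapping uses global Needleman–Wunsch alignment (biopython's
`PairwiseAligner`, BLOSUM62, gap open 10 / extend 1) instead of the
profile-HMM machinery of the original database search: for within-family
mapping onto a single reference the pairwise alignment is adequate,
deterministic and dependency-free. The aligner's first optimal traceback
is always taken, so motifs are reproducible for fixed inputs and
scoring; ties between co-optimal alignments are broken by the aligner's
internal traceback order. Anchor positions are 1-based indices into the
packaged *mature* bacteriorhodopsin sequence (conventional mature
numbering: T46, R82, D85, T89, D96, D212, K216 read TRDTDDK); users
supplying a precursor sequence with signal peptide must renumber, since
the cleavage cannot be auto-detected reliably. Non-standard residues
(B, Z, U, O, J) map to X.

Candidacy requires only R at position 1 and K at position 7 — the
published screen names only those two letters — with R/D at positions
2/6 reported as "full RRXXXDK match" in the notes rather than gating.
Duplicate removal compares residue strings only (metadata is ignored).
Greedy identity reduction processes records in length-descending order
and absorbs a record into the first representative with identity above
the threshold, where identity = alignment matches / shorter length
(edlib global alignment); the published pipeline delegates this step to
CD-HIT, whose exact definition differs in detail, so the definition
used here is stated and tested against a brute-force all-pairs oracle.

## Synthetic scenarios: scope and fidelity

The packaged scenarios encode the study conditions: recovery lifetimes
942 s (20 °C) and 3318 s (5 °C) sampled every 120 s over 5 h after a
100-s illumination; excited-state decays 0.4/10 ps (pH 10.5) and
0.5/25 ps (pH 3.5) under a 50-fs-σ Gaussian IRF with ESA/GSB/SE band
structure; a 3-ps linear-timescale oscillation measurement carrying
128 cm⁻¹ (damping 0.5 ps) and 32 cm⁻¹ components on the ESA/GSB wings;
K → M1 → M2 flash kinetics with millisecond/sub-second/minutes
lifetimes; wild-type vs R57T M decays of 300 s vs 3 s at pH 8 (the
100× ratio); titration species at 620/540/400 nm with pKa 5.8 and 10.3
(chosen so the acid form dominates below pH 6 and the visible λmax
shift is 80 nm); and a ±40 mV charge table with nonprotonated fractions
1/3, 2/3, 0.8 at −40/0/+40 mV (α = 2, β = 0.5). Noise defaults are
0.002 OD for steady-state spectra, 0.05 mOD for TA matrices and 1 pA
for photocurrents — visible in every plot yet small enough that the
fits are parameter-limited, not noise-limited; the published work does
not state instrument noise figures, so these are declared choices.
Photocurrent pulses are unit-integral biexponentials (2 ms rise, 15 ms
decay) depleted by 0.5 per pulse; the real pulse shape and depletion
are not published.

What the generators deliberately do not emulate: spectro-temporal chirp
and solvent/cross-phase artifacts around time zero, wavelength-dependent
IRF, detector baseline drifts, scattering contributions at the
excitation wavelength, non-Gaussian band shapes, series-resistance and
liquid-junction effects in the recordings, and any structural or
cryo-EM observables. Passing the packaged tests therefore demonstrates
correctness of the estimators on well-specified signals with realistic
noise, not robustness to every instrument pathology of real data.

## Problem sizes

The parameter-recovery suites use 20 seeded replicates per scenario;
datasets are 81×87 (fs TA), 161-point 3-ps oscillation windows averaged
from 81 wavelengths, 73×90/100 (flash), 251×18 (titration) and
150-point recovery series — sizes at which every stage runs in seconds
on one core while keeping all fits comfortably overdetermined.

## Known limitations

- The LDM basis ignores the IRF; femtosecond-scale distribution peaks
  are biased near the IRF width (the global fit is authoritative there).
- The greedy identity filter is order-dependent by construction, as is
  any greedy clustering; results are deterministic but need not match
  CD-HIT cluster-for-cluster.
- The titration fit assumes one visible Gaussian band per species;
  species with structured or strongly asymmetric bands would need a
  multi-band extension.
- The photoswitch model has no intensity saturation or photodegradation
  terms; it cannot represent photofatigue by design.
- `reversal_voltage` interpolates linearly between bracketing samples;
  strongly rectifying current–voltage relations need denser sampling.
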