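# Methods

## The coordinate system: time ↔ NCV-ratio

Developmental progression is tracked by the nucleocytoplasmic volume ratio
(NCV-ratio): total nuclear volume over cell volume. Nuclei are treated as
spheres (V = πd³/6) and the per-stage cell volume is the embryo volume
divided by the cell count. The time ↔ NCV map is a shape-preserving
monotone piecewise-cubic Hermite interpolant (PCHIP) through per-time
averaged observations; the inverse is obtained by solving the forward
cubic exactly, so `inverse(forward(t)) = t` to machine precision across
the fitted support. Outside the observed time range both directions clamp
to the boundary values — volumes are never extrapolated. An optional
accessible-cytoplasm fraction (default 0.30 when used) accounts for the
~70% of cytoplasmic volume excluded by yolk and lipids; NCV values
reported against total embryo volume use fraction 1.

The nuclear import flux is F_total(t) = dV_nuc/dt · Σ[P], with the volume
derivative taken from the same spline and negative local derivatives
(measurement noise) clamped to zero: the model describes net import during
nuclear growth. Internal units are liters, molar, mol and hours (µm³
inputs are converted at 1 µm³ = 1e-15 L, centralized in `units`).

## Nuclear fraction and T_embryo1/2

The filtration assay yields per-protein relative signals in a
nuclei-enriched supernatant and a nuclear-depleted flow-through at each
stage. The 2-cell-stage supernatant (negligible nuclear content) is
subtracted per protein from every supernatant measurement — per replicate
where the replicate measured the reference stage, otherwise using the
across-replicate mean — with negatives clipped to zero. The nuclear
fraction NF = S_sup/(S_sup + S_flow) is undefined (missing, not zero)
when both signals vanish.

NF is fitted against NCV with a two-parameter bounded logistic

    NF(v) = NF_oocyte / (1 + exp(−k (v − v_half))),

the upper asymptote pinned to the protein's oocyte nuclear fraction, the
lower asymptote zero, v_half hard-bounded to [0, 1] and k > 0. All
replicate points enter one joint fit (bounded trust-region least squares,
deterministic multi-start from midpoint seeds 0.001/0.01/0.1/0.5/0.9 with
two slope initializations each). Fits with an observed NF range below
0.05 are flagged degenerate — no transition is observable — and yield no
half-time. T_embryo1/2 is the volume map's inverse at the fitted midpoint;
midpoints outside the fitted NCV range clamp to the boundary time with a
warning. The fit runs on linear NCV; since NCV grows roughly
exponentially, steepness values are large in absolute terms and only the
midpoint is interpreted downstream.

## Importin-affinity proxy

RanQ69L (GTP-locked Ran) releases substrates from importin β, so a
protein's pulldown signal decays with added RanQ69L in proportion to its
Ran-sensitive importin binding. Within each replicate the bound fraction
at level x is f(x) = S(x)/(S(x) + S(0)), which equals 0.5 at x = 0 by
construction. Normalization is two-stage: division by the per-condition
bait/carrier signal when provided, then per-level rescaling so the median
bound fraction of flagged background proteins (glycolytic and
mitochondrial proteins that do not bind importin) is 0.5 at every level;
the procedure is idempotent. The per-replicate affinity proxy is the
least-squares slope of f = 0.5 + m·x with the intercept fixed —
more negative slope, tighter importin binding.

Replicate slopes are integrated against T_embryo1/2 by one-component
canonical correlation analysis, cross-validated: proteins with at least
two observed replicate slopes are shuffled with the run seed, split into
10 contiguous folds, and each fold is projected with an axis trained on
the other folds (missing replicate values mean-imputed within training
folds only). Because each fold's canonical scores are defined only up to
an affine transform, held-out scores are passed through the training-fold
linear map from score to T_embryo1/2 before concatenation, then negated
so that a higher proxy means higher affinity (earlier entry). This
calibration makes a perfect shared latent reproduce |r| = 1 exactly. Its
cost is a null-correlation spread of order √(p/n) per dataset (p = 3
replicates): on pure-noise replicates at n = 1000 the absolute correlation
of the concatenated projections is typically 0.04–0.06 but can exceed 0.1
in single draws, so null behavior is assessed on means over independent
datasets.

Absolute concentration calibration bins normalized log10 ion signals into
bins of width 1/3, takes the median log10 reference concentration per
populated bin, and fits median concentration against the median bin
signal with a robust M-estimator (Ramsay's E_a norm, a = 1.65). Using the
within-bin median signal as regressor makes the fit exact for a noiseless
power law; with 10% hundred-fold outliers the slope stays within a few
percent where ordinary least squares does not.

## Competitive-import model

Substrate binding to importin is taken at Langmuir-competition
equilibrium. With cytoplasmic concentrations [P_cyto,i] and dissociation
constants K_Di (∞ for inert species), the occupancy of total importin by
substrate i is

    θ_i = ([P_cyto,i]/K_Di) / (1 + Σ_j [P_cyto,j]/K_Dj),

and the import flux partitions as dP_nuc,i/dt = θ_i · F_total(t) with
P_cyto,i = P_i − P_nuc,i. The total importin concentration cancels from
the flux partition (free substrate ≈ total cytoplasmic substrate); it is
carried in the state at its configured 1.5 µM so that
[I] + Σ[IP_cyto,i] = [I_0] is reported identically. Integration uses an
adaptive explicit Runge–Kutta (RK45, rtol 1e-6, atol 1e-12 M × V);
cytoplasmic amounts are floored at zero inside the right-hand side, and
θ_i vanishing as a substrate depletes makes the floor self-limiting. For
n ≤ 5 the adaptive solution agrees with an independent fixed-step Euler
reference at dt = 1e-3 h within 0.5% of each substrate's total amount.

Default embryo composition: 4,600 nuclear species at 44 nM each (10% of
proteome mass) with ln K_D ~ Normal(−18, 2) (K_D in molar, median
exp(−18) ≈ 15 nM), one inert 1.8 mM cytoplasmic pool, ~2 mM total, in a
1.2 mm-diameter egg. Runs at reduced n scale the per-species nuclear
concentration to preserve the nuclear mass, keeping the competition
regime comparable; the test and acceptance runs use 500 substrates for
runtime. Entry half-time is the first 0.5-crossing of the nuclear
fraction of the substrate's total amount, linearly interpolated between
grid points, and reported missing — never as the final time — when import
saturates below 50%. Nuclear concentration profiles P_nuc,i(t)/V_nuc(t)
require a positive nuclear volume on the output grid (profiles start
after the first nucleus forms); their peak times order strictly by
affinity (1 nM before 30 nM before 1 µM) in both the embryo regime and a
droplet regime whose flux comes from a logistic droplet nuclear-volume
curve.

## Droplet imaging

Frames carry a reference channel (mCherry-NLS import standard) and a
probe channel (GFP-tagged protein). The nucleus is segmented on the
smoothed reference channel by Otsu threshold, keeping the largest
connected component (≥ 20 px) with holes filled; when the reference lacks
contrast (relative contrast < 0.2 — the rare case of the probe entering
first) the probe channel is used. The nuclear ROI is dilated (default
5 px) and the cytoplasmic integrated intensity is the dilated minus the
nuclear integrated intensity; means divide by the respective areas. RNC =
m_nuc/(m_nuc + m_cyto) is 0.5 in a well-mixed droplet and is
scale-invariant under global gain.

RNC(t) is fitted with RNC = b + (A − b)/(1 + exp(−k(t − t_half))), the
baseline b fixed at 0.5 (well-mixed premise) unless the first observed
RNC deviates from 0.5 by more than 0.15, in which case the baseline is
freed. T_droplet1/2 is the sigmoid midpoint parameter — the time at which
RNC is halfway between baseline and plateau; the absolute-0.5-crossing
reading coincides with it when the baseline is 0.5. The per-droplet
ΔT_droplet1/2 = t_half(probe) − t_half(reference) (positive = slower than
mCherry-NLS) cancels droplet-level extract variability exactly in the
noiseless case; the cohort summary is the median across droplets.

## Complex coherence and rank statistics

Complexes with at least five members carrying a defined T_embryo1/2
contribute the sample SD of their members' entry times. The null draws,
for each retained complex, random member sets of the same size without
replacement from the pool of all measured proteins (default 100 draws per
complex; a single-draw mode mirrors a one-shot null). Observed and null
SD distributions are compared with the two-sample Wilcoxon rank-sum
(Mann–Whitney) test, two-sided, exact for small tie-free samples.
Spearman rank correlations use average-rank ties; for n ≤ 10 the
two-sided p-value is computed by full enumeration of all n! permutations,
otherwise by the t approximation.

## Synthetic data

The generators are pure functions of their parameters and seed
(regeneration is byte-identical) and write a ground-truth JSON sidecar.
The default embryo geometry follows NCV(t) = 1.2e-5 · exp(0.18 t) from
2 h to 45 h with cell counts doubling every 3.3 h (capped at 16,384) and
nucleus diameters back-computed from the target volume — reproducing a
~30 µm zygote nucleus, ~18 µm nuclei around the ~4,000-cell stage, and an
oocyte-like final NCV of ~0.04. Embryo proteomics: 18 timepoints, 5
replicates, true T1/2 uniform on 10–40 h, oocyte NF uniform on 0.6–0.95,
a 2% cytoplasmic-retention background planted in every supernatant, and
multiplicative lognormal channel noise at 5% CV. Titration: bound
fractions 0.5 + m·x (+ Gaussian noise, σ = 0.03, clipped to [0, 1]) over
normalized Ran levels 0–10, slopes a monotone logistic map of the planted
ln K_D into (−0.05, 0), background proteins at slope 0, and a planted
T1/2 sharing the ln K_D latent. Droplet frames: a centered disk nucleus
growing 6→14 px inside a uniform cytoplasm at 100 counts, nuclear
intensity following the planted RNC sigmoid, Gaussian read noise at 10%
of contrast. Complex catalogs: within-complex SD = (1 − coherence) × pool
SD with complex centers dispersed so every member's marginal distribution
matches the pool — at coherence 0 the construction reproduces the null
exactly, which is what makes the type-I calibration test meaningful.

What the generators do not emulate: peptide-level quantification and
reporter-ion artifacts, compositional coupling between proteins in a
multiplexed run, chromatic aberration/PSF/bleaching in imaging, z-stacks
and focus selection, multi-nucleus droplets, and ortholog-mapping noise
in complex catalogs. Passing recovery tests therefore demonstrates the
correctness of the estimators under the stated noise models, not
robustness to every artifact of real data.

## Numerical choices and limitations

Tolerances: ODE rtol 1e-6 / atol 1e-12 M; sigmoid fits use bounded
`least_squares` with deterministic multi-starts (no randomness in any
fit); tie-breaking in ranks is the average-rank convention; the first
0.5-crossing defines half-times when trajectories touch 0.5 repeatedly.
Degenerate inputs yield flagged statuses (degenerate/failed) rather than
exceptions wherever a cohort fit must continue past a bad protein.

Known limitations: the import model ignores explicit nuclear-pore
kinetics, Ran-gradient dynamics, exportins, importin isoforms and
phosphoregulation — affinity to a single importin pool is the only
ordering mechanism. The affinity proxy is a relative quantity; no
physical K_D is derived from it. The CV-CCA projection inherits the
√(p/n) null spread discussed above. Droplet analysis assumes one nucleus
per droplet and a single focused frame per time point.
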