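# Methods

This note documents the models, defaults and numerical choices behind
`protacprofiler`, and what the synthetic-data tests do and do not show.

## Chromatographic descriptors

All capacity factors are decadic logarithms of k′ = (t_R − t₀)/t₀.
Measurements with t_R ≤ t₀ (non-retained solutes) or t₀ ≤ 0 are
rejected, never silently clamped.

**Calibration lines.** BRlogD = 3.31 · log k′₆₀ + 2.79 (C18 phase) and
clog k_w^IAM = 0.92 · BRlogD − 1.03 are fixed published calibrations of
the chromatographic systems, shipped as named constants in
`config.PipelineConfig` so a laboratory running different columns can
recalibrate without touching code. Δlog k_w^IAM is defined exactly as
measured minus predicted, so the self-consistency
Δ(clog k_w^IAM(b) + d, b) = d holds to machine precision.

**log k_w^IAM extrapolation.** The IAM line (log k′ vs % organic over
the 10–50% design) is extrapolated to 0% organic — the pure-aqueous
convention implied by the *w* subscript. Because other conventions
exist, the evaluation point is a parameter (`at_fraction`) rather than
a constant.

**Chamelogk** uses exactly the 50/60/70% points for the linear trend;
extra compositions are ignored with a warning since including them
would change the published definition of the index. The extrapolation
to 100% organic has high leverage (≈ ×2.9 noise amplification on a
single measurement), which is why the recovery tests quote mean errors
over a 50-compound cohort rather than per-compound bounds.

**Ionization class.** Retention on the polymeric phase is depressed by
ionization. The profile maximum m over pH {2, 7, 12} is the reference;
a pH counts as depressed when m − log k′₈₀(pH) exceeds 0.3 log units —
a threshold chosen to sit clearly above retention-time reproducibility
noise, configurable. NEUTRAL (dominantly neutral at pH 7) takes
priority whenever the pH-7 retention is within the threshold of the
maximum. A consequence of using the profile maximum as reference is
that an ampholyte depressed at both extremes necessarily has its
maximum at pH 7 and therefore reports NEUTRAL; the AMPHOTERIC label is
retained in the enum but is reachable only under a different (non-
default) reference convention.

## Noncompartmental pharmacokinetics

AUC is the linear trapezoid from the first to the last observed sample
with no extrapolation to infinity: the conservative default when the
terminal slope is not estimated. A linear-log variant (log-trapezoid on
strictly declining positive segments) is selectable. Concentrations
that are NaN or negative are treated as below the limit of
quantification and dropped with a warning. F% compares dose-normalized
AUCs; truncation bias largely cancels in the oral/IV ratio when both
arms share a sampling grid, which is why even the sparse 8-point design
recovers F well.

## Conformer descriptors

**Radius of gyration** is mass-weighted over all atoms including
hydrogens by default (an unweighted mode is provided); masses and
Bondi van der Waals radii ship in a replaceable `RadiiTable`.

**Shrake–Rupley SASA** places a golden-spiral (Fibonacci) lattice of
test points — deterministic, no RNG, default 960 points — on each
atom's inflated sphere (r_vdW + probe); a point is accessible when it
lies outside every other atom's inflated sphere, and the atom's area is
4π(r_vdW+probe)² times the accessible fraction. Because the lattice is
fixed in space, coordinates are first expressed in a canonical
principal-axis frame (axes ordered by variance, signs fixed by the
third moment, right-handed), which makes the areas invariant under
rigid motion to machine precision for molecules in generic position.
Accuracy at 960 points is well inside 2% of a 10⁶-point Monte-Carlo
occlusion oracle on small test molecules.

**3D PSA** sums the per-atom SASA over the classical polar surface
atom set: N, O, and H bonded to N or O. Sulfur is excluded — the
convention of topological PSA's polar set — so thioether/thiazole
sulfur contributes nothing; this is a documented assumption, since 3D
PSA tools differ on it. Probe radii 0 Å (bare van der Waals polar
surface) and 1.4 Å (water) are both reported. When bond topology is
absent (XYZ input), hydrogen attachment is inferred by distance
(< 1.2 Å to the nearest heavy atom); heavy–heavy bonds are never
invented.

**Intramolecular hydrogen bonds** are donor–H···acceptor triples with
N/O donors and acceptors, H···A ≤ 2.5 Å and D–H···A angle ≥ 120° by
default — relaxed Mills–Dean-style geometric criteria, fully
configurable, since published "default" detection settings vary across
visualization tools.

## Ensemble analysis

Ensembles are summarized by medians and IQRs of R_gyr and 3D PSA 1.4 Å
— medians because the property distributions are skewed and often
multimodal. Density is estimated with a plain 2D histogram (default
bins 0.25 Å × 5 Å²) rather than a KDE: histograms conserve counts
exactly and give deterministic maxima. The maximum bin breaks ties
toward lower PSA then lower R_gyr; the representative conformer of that
bin is the frame closest to the bin center in z-scored coordinates,
ties toward the lowest frame id. The folded/low-polarity fraction
counts frames with R_gyr < 7 Å and 3D PSA 1.4 Å < 200 Å²; these guide
thresholds are visualization aids for real degrader ensembles, not
validated cutoffs, and are configurable. The chameleon contrast is the
polar-minus-nonpolar difference of the median quantifiers.

## Property relations

Relations are simple OLS fits; r² is the squared Pearson correlation,
identical to the coefficient of determination for a univariate fit. The
efflux ratio enters untransformed (fitting log ER is a documented
alternative). Outlier exclusion is always a declarative list of
compound ids — mirroring how an analyst declares an outlier in a plot —
never automatic. Bioavailability boundaries F = 1% and F = 5% are
assigned to the lower-severity class because the published strict
inequalities on both sides leave the boundary open.

## Synthetic data

The generators produce inputs with exactly the statistical structure
each stage assumes, plus ground-truth sidecars; recovery tests read
truth only from the sidecars.

* *Retention*: log k′ linear in % organic (intercept U(2.5, 3.5),
  slope U(−0.06, −0.04) per %, the plausible range for this assay
  design), a planted chameleonic offset (default 0.8) added at 100%
  organic, Gaussian noise on the log scale, fixed dead time 1 min.
* *Ensembles*: self-avoiding biased random walks of beads (bond 1.5 Å,
  separation cutoff 1.0 Å); a compactness parameter in [0, 1] mixes an
  isotropic step with a pull toward the running centroid, relaxed
  geometrically on clashes so generation always terminates and the
  cutoff is respected. Elements are a per-compound draw (default 25%
  N/O); bonds are the chain. Median R_gyr falls strictly with
  compactness up to ≈ 0.6, where the packing limit saturates the
  response — sweeps therefore stay in [0, 0.6]. These chains are
  geometric toys: they reproduce the fold-and-bury-polarity phenomenon
  the descriptors must detect, but nothing about real degrader
  energetics, so passing tests validate the measurement machinery, not
  conformational predictions for real molecules.
* *PK*: one-compartment curves (default F = 20%, CL = 1 L/h/kg,
  V = 5 L/kg, ka = 1.5/h, i.e. t½ ≈ 3.5 h) at the study's dosing
  design (30 mg/kg oral, 5 mg/kg IV); multiplicative lognormal noise
  keeps concentrations positive. The dense grid runs to 72 h (≈14
  elimination half-lives) so trapezoid truncation is negligible; the
  8-point design (0–16 h, front-loaded) represents a realistic sparse
  in vivo schedule.
* *Property tables*: log k′₈₀ uniform on [0.2, 1.6], ER = −2 ·
  log k′₈₀ + 6 + noise (floored at 0.1), F% = 30 · exp(−ER/2). The
  helper `noise_sd_for_target_r2` converts a population r² target into
  the noise level.

Every generator draws from its own RNG stream derived from the master
seed via a fixed label, so adding a generator never perturbs the
others, and repeat runs are byte-identical.

The **synthetic reference table** (`synthetic_reference.py`) is a
deterministic, RNG-free stand-in for the 11-compound experimental
series: residuals are projected orthogonal to the regression design and
rescaled so the planted relations hold exactly (r² = 0.58 for
ER ~ log k′₈₀ with the declared outlier excluded; r² = 0.53 for
EPSA ~ Δlog k_w^IAM), with every chameleonicity index above 0.6,
exactly five compounds above F = 5%, EPSA above 120 Å² and ETR near
0.7. Analyses of this table exercise the real code path end to end but
carry no per-compound experimental information.

## Problem sizes and known limitations

Default test/analysis sizes — 100-frame ensembles of 30-bead chains,
240–960 surface points, 50-compound retention cohorts, 1000-seed
relation replicates — were chosen so each stage's statistical claim is
resolvable with margin; they are not tuned to any external budget.

Known limitations: SASA is O(n²·points) without spatial indexing, fine
for small-molecule/degrader-sized inputs but not for proteins; the
canonical-frame trick guarantees rigid-motion invariance only for
molecules in generic position (degenerate inertia tensors fall back to
an arbitrary but deterministic frame); the ionization classifier
cannot report AMPHOTERIC under the default reference (see above); and
no automatic outlier detection or multivariate modeling is provided by
design.
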