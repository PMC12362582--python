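# protacprofiler

Physicochemical, pharmacokinetic and conformational profiling for
chameleonic degraders (PROTACs) and other beyond-Rule-of-5 molecules.

Heterobifunctional degraders sit far outside the oral-drug property
space: high molecular weight, large topological polar surface area, and
yet some of them are orally bioavailable. The working explanation is
*chameleonicity* — the molecule folds into a compact, low-polarity
conformation in nonpolar environments (membrane core) and opens up in
water. This package implements the descriptor toolchain used to
quantify that behavior and relate it to in vivo outcome, for teams
profiling VHL/CRBN degrader series:

* **Chromatographic descriptors** from HPLC retention. With the
  capacity factor k′ = (t_R − t₀)/t₀ (log₁₀ throughout):
  - BRlogD = 3.31 · log k′₆₀ + 2.79, an octanol/water log D surrogate
    (C18 phase, 60% acetonitrile);
  - log k′₈₀ PLRP-S, a membrane-core (toluene/water) partitioning
    surrogate on a polymeric phase, plus an ionization class from its
    pH 2/7/12 profile;
  - log k_w^IAM, immobilized-artificial-membrane lipophilicity
    extrapolated to fully aqueous eluent, and the polarity descriptor
    Δlog k_w^IAM = log k_w^IAM − (0.92 · BRlogD − 1.03), with values
    above 1.5 flagged as excessive polarity;
  - **Chamelogk** = Exp. log k′₁₀₀ − Ext. log k′₁₀₀: the measured
    capacity factor at 100% organic minus the 50/60/70% linear
    extrapolation; above 0.6 the compound is a strong chameleon;
  - ETR = EPSA/TPSA, a polarity-masking index.
* **Noncompartmental pharmacokinetics**: trapezoid AUC and oral
  bioavailability F% = (AUC_oral/dose_oral)/(AUC_iv/dose_iv) · 100, with
  very low (<1%), low (≤5%) and medium/high (>5%) classes.
* **Conformer-ensemble descriptors**: mass-weighted radius of gyration,
  deterministic Shrake–Rupley solvent-accessible surface area, 3D polar
  surface area at probe radii 0 and 1.4 Å (N, O and H-on-N/O atom set),
  intramolecular hydrogen-bond detection, and ensemble-level analysis —
  medians, 2D density maps over the (R_gyr, 3D PSA) plane, density-
  maximum conformers and polar-vs-nonpolar solvent contrasts.
* **Property relations**: OLS relations between descriptors and ADME
  readouts (the key one being the inverse efflux-ratio / log k′₈₀
  PLRP-S correlation) with declarative outlier exclusion, and the
  lipophilicity/polarity plane that localizes the orally bioavailable
  region.
* **Synthetic data generators** for every input, with ground-truth
  sidecars, so the entire pipeline is testable offline. A deterministic
  synthetic stand-in for the 11-compound reference series (built to its
  published aggregate statistics) supports end-to-end analysis without
  redistributing experimental tables.

## Worked example

Run the numbered analyses (each regenerates its inputs from seeded
generators and writes tables under `results/`):

```sh
python analysis/01_simulate_inputs.py --seed 42
python analysis/02_chromatographic_descriptors.py
python analysis/03_bioavailability.py
python analysis/04_conformational_analysis.py
python analysis/05_property_relations.py
```

Output of the last three steps:

```
planted F = 20%: mean recovered 20.05%, mean relative error 2.5% (8-point design, 5% assay CV)

polar: 100 frames, median R_gyr 2.08 Å, median 3D PSA 1.4 Å 39.6 Å², density max frame 89
nonpolar: 100 frames, median R_gyr 3.34 Å, median 3D PSA 1.4 Å 49.3 Å², density max frame 5
polar - nonpolar contrast: ΔR_gyr = -1.26 Å, Δ3D PSA = -9.7 Å²
negative ΔR_gyr = ensemble folds in the polar medium (planted chameleonic bias detected)

ER ~ log k'80 PLRP-S (excl. B-4): slope -8.00, r2 = 0.58 (n = 10)
EPSA ~ Δlog kw_IAM: r2 = 0.53 (n = 11)
strong chameleons: 11/11; medium/high F% (>5): 5/11
excessive polarity (Δlog kw_IAM > 1.5): ['A5-1', 'A5-4']
```

Reading this: the noncompartmental calculator recovers the planted oral
bioavailability to within a few percent under realistic assay noise;
the conformational stage detects the planted polar-solvent folding bias
as a negative median-R_gyr contrast; and on the reference stand-in the
efflux ratio falls with membrane-core lipophilicity (r² = 0.58 once the
declared outlier B-4 is excluded), every compound is a strong chameleon,
and exactly the five methylated analogs reach medium/high F%.

A command-line interface exposes the same stages
(`protacprofiler descriptors|pk|conformers|ensemble|relate|simulate|run`);
`protacprofiler run` orchestrates them and writes a JSON run manifest.

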