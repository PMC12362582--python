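#!/usr/bin/env python
"""Generate the synthetic study inputs for the downstream analyses.

Emits, under results/sim/:
  retention.csv / retention_truth.csv  -- chromatographic observations for
      50 compounds with a planted chameleonic offset of 0.8 and 0.02
      log-unit retention noise;
  pk.csv / pk_truth.csv                -- oral + IV one-compartment curves
      (8-point design, 5% assay CV) with planted F = 20%;
  compounds.csv / compounds_truth.csv  -- an 11-compound property table
      with a planted efflux/lipophilicity line (noise set for r2 = 0.6);
  ensemble_polar.pdb / ensemble_nonpolar.pdb -- 100-frame bead-chain
      conformer ensembles with a polar-solvent folding bias.
"""

import argparse
from pathlib import Path

from protacprofiler import synthetic as syn
from protacprofiler.io import write_pdb_multimodel

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main(seed: int) -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    retention_cfg = syn.GeneratorConfig(
        seed=seed, n_compounds=50, chamelogk_true=0.8, retention_noise_sd=0.02
    )
    obs, truth = syn.gen_retention(retention_cfg)
    obs.to_csv(OUT / "retention.csv", index=False)
    truth.to_csv(OUT / "retention_truth.csv", index=False)
    print(f"retention: {len(obs)} rows, {truth.shape[0]} compounds, "
          f"planted Chamelogk {retention_cfg.chamelogk_true}")

    pk_cfg = syn.GeneratorConfig(seed=seed, n_compounds=11)
    obs, truth = syn.gen_pk(pk_cfg, timepoints=syn.EIGHT_POINT_TIMEPOINTS,
                            noise_sd=0.05)
    obs.to_csv(OUT / "pk.csv", index=False)
    truth.to_csv(OUT / "pk_truth.csv", index=False)
    print(f"pk: {len(obs)} samples, planted F {truth.f_true_percent[0]:.0f}%")

    sd = syn.noise_sd_for_target_r2(-2.0, *syn.LOGK80_RANGE, 0.6)
    table_cfg = syn.GeneratorConfig(
        seed=seed, n_compounds=11,
        relation_params=syn.RelationParams(slope=-2.0, intercept=6.0,
                                           noise_sd=sd),
    )
    obs, truth = syn.gen_property_table(table_cfg)
    obs.to_csv(OUT / "compounds.csv", index=False)
    truth.to_csv(OUT / "compounds_truth.csv", index=False)
    print(f"property table: {len(obs)} compounds, planted slope "
          f"{truth.slope[0]}, noise sd {sd:.3f} (population r2 0.6)")

    ens_cfg = syn.GeneratorConfig(seed=seed, n_frames=100, chain_length=30,
                                  compactness_polar=0.6,
                                  compactness_nonpolar=0.15)
    for solvent in ("polar", "nonpolar"):
        frames = syn.gen_ensemble(ens_cfg, solvent)
        write_pdb_multimodel(frames, OUT / f"ensemble_{solvent}.pdb")
        print(f"ensemble ({solvent}): {len(frames)} frames of "
              f"{ens_cfg.chain_length} beads")


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=42)
    main(parser.parse_args().seed)
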