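#!/usr/bin/env python
"""Property-space analysis of the simulated conformer ensembles.

Per-frame radius of gyration and 3D PSA (probe 1.4 Å) are computed for
the polar- and nonpolar-solvent ensembles, summarized as medians and
density maps, and contrasted across solvents — the chameleonic
signature being a more compact, less polar-exposed ensemble in the
polar medium (the folding bias planted by the generator).

Writes results/conformer_descriptors.csv, results/ensemble_summary.csv and
results/density_map_<solvent>.csv.
"""

import numpy as np
import pandas as pd
from pathlib import Path

from protacprofiler.conformers import describe_conformer
from protacprofiler.ensembles import (
    SamplingMethod,
    SolventClass,
    chameleon_contrast,
    density_map,
    summarize_ensemble,
)
from protacprofiler.io import (
    read_conformers,
    write_conformer_descriptors_csv,
    write_ensemble_summary_csv,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    summaries = {}
    all_rows = []
    for solvent, cls in (("polar", SolventClass.POLAR),
                         ("nonpolar", SolventClass.NONPOLAR)):
        frames = read_conformers(ROOT / "sim" / f"ensemble_{solvent}.pdb")
        described = [describe_conformer(f, n_points=240) for f in frames]
        all_rows += [("SYN-001", solvent, "SMD", d) for d in described]
        summaries[solvent] = summarize_ensemble(
            described, "SYN-001", cls, solvent_label=solvent,
            method=SamplingMethod.SMD,
        )
        dmap = density_map(described)
        pd.DataFrame(
            dmap.counts,
            index=np.round(dmap.x_edges[:-1], 3),
            columns=np.round(dmap.y_edges[:-1], 1),
        ).to_csv(ROOT / f"density_map_{solvent}.csv")
        s = summaries[solvent]
        print(f"{solvent}: {s.n_frames} frames, median R_gyr "
              f"{s.median_rgyr:.2f} Å, median 3D PSA 1.4 Å "
              f"{s.median_psa14:.1f} Å², density max frame "
              f"{s.density_max_frame}")

    write_conformer_descriptors_csv(all_rows, ROOT / "conformer_descriptors.csv")
    write_ensemble_summary_csv(list(summaries.values()),
                               ROOT / "ensemble_summary.csv")

    d_rgyr, d_psa = chameleon_contrast(summaries["polar"],
                                       summaries["nonpolar"])
    print(f"polar - nonpolar contrast: ΔR_gyr = {d_rgyr:.2f} Å, "
          f"Δ3D PSA = {d_psa:.1f} Å²")
    print("negative ΔR_gyr = ensemble folds in the polar medium "
          "(planted chameleonic bias detected)" if d_rgyr < 0 else
          "no folding contrast detected")


if __name__ == "__main__":
    main()
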