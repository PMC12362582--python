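#!/usr/bin/env python
"""Compute the chromatographic descriptor suite on the simulated retention
tables and check the chameleonicity recovery against the ground truth.

Reads results/sim/retention.csv, writes results/descriptors.csv and prints
the mean absolute Chamelogk recovery error.
"""

import numpy as np
import pandas as pd
from pathlib import Path

from protacprofiler.chromatography import compute_descriptors
from protacprofiler.io import read_retention_csv, write_descriptors_csv

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    measurements = read_retention_csv(ROOT / "sim" / "retention.csv")
    records = compute_descriptors(measurements)
    write_descriptors_csv(records, ROOT / "descriptors.csv")

    truth = pd.read_csv(ROOT / "sim" / "retention_truth.csv").set_index(
        "compound_id"
    )
    errors = [
        abs(rec.chamelogk - truth.loc[rec.compound_id, "chamelogk_true"])
        for rec in records
    ]
    strong = sum("strong_chameleon" in rec.flags for rec in records)
    print(f"descriptors for {len(records)} compounds -> results/descriptors.csv")
    print(f"Chamelogk recovery: mean |error| = {np.mean(errors):.4f} "
          f"(retention noise 0.02 log units)")
    print(f"strong chameleons (Chamelogk > 0.6): {strong}/{len(records)}")


if __name__ == "__main__":
    main()
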