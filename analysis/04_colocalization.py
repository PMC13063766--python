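#!/usr/bin/env python
"""Single-plaque peptide co-localization.

Reads the sampled plaque table produced by 02_truncation_recovery.py,
computes per-group Pearson correlation matrices on log-transformed
abundances across plaques, and compares the strength of inter-peptide
co-occurrence between groups (mean off-diagonal r). Writes the matrices
under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from abmsi.io import write_tables
from abmsi.plaques import log_pearson_matrix

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table_path = OUT / "plaque_table.csv"
    if not table_path.exists():
        raise SystemExit("run 02_truncation_recovery.py first (needs plaque_table.csv)")
    table = pd.read_csv(table_path)
    results = {}
    summary = []
    for group, sub in table.groupby("group"):
        R = log_pearson_matrix(sub)
        # restrict the summary to variants actually present in the group
        present = [c for c in R.columns if np.isfinite(R[c]).sum() > 1]
        Rp = R.loc[present, present].to_numpy()
        off = Rp[~np.eye(len(Rp), dtype=bool)]
        summary.append(
            {"group": group, "n_plaques": len(sub), "n_variants": len(present),
             "mean_offdiag_r": float(np.nanmean(off))}
        )
        results[f"correlation_{group}"] = R.reset_index(names="variant")
    df = pd.DataFrame(summary)
    print(df.round(3).to_string(index=False))
    write_tables({**results, "colocalization_summary": df}, OUT)
    print(f"wrote correlation matrices under {OUT}")


if __name__ == "__main__":
    main()
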