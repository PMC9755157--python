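"""Simulate the deployment; record stream to scratch, summary to results."""

import pandas as pd

from common import get_study, outdir
from hyraxnet.simulate import write_records_csv


def main():
    data = get_study()
    write_records_csv(data.records, outdir("scratch") / "records.csv")
    enc = data.truth.encounters
    rows = []
    for phase, sub in enc.groupby("phase"):
        rows.append(
            {
                "phase": phase,
                "n_encounters": len(sub),
                "encounters_per_day": len(sub) / data.phase_config.n_days,
                "mean_duration_s": sub["duration_s"].mean(),
                "median_duration_s": sub["duration_s"].median(),
                "share_cross_group": sub["cross_group"].mean(),
            }
        )
    out = outdir("results") / "01_simulation_summary.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
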