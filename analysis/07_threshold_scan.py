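"""Activity-threshold scan: where does the network change character?

Re-runs the active/passive split at several candidate thresholds and
tracks mean strength and cosine similarity to the shortest-threshold
baseline network; the chosen threshold sits just before the largest
single-step cosine drop.
"""

import pandas as pd

from common import get_study, outdir
from hyraxnet.compare import threshold_scan

CANDIDATES = (600, 900, 1500, 2400, 3600, 5400)


def main():
    data = get_study()
    scan = threshold_scan(data.records, CANDIDATES, data.phase_config)
    df = pd.DataFrame(
        {
            "threshold_s": scan.thresholds,
            "mean_strength": scan.mean_strength,
            "cosine_to_baseline": scan.cosine_to_baseline,
        }
    )
    out = outdir("results") / "07_threshold_scan.tsv"
    df.to_csv(out, sep="\t", index=False, float_format="%.5f")
    print(df.to_string(index=False))
    if scan.no_drop:
        print(f"no dominant drop (max step {scan.max_drop:.4f}); wrote {out}")
    else:
        print(f"chosen threshold {scan.chosen:.0f} s (drop {scan.max_drop:.4f}); wrote {out}")


if __name__ == "__main__":
    main()
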