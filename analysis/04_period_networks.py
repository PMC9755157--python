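"""Per-period network summaries over the 54 day/night networks."""

import pandas as pd

from common import get_study, outdir
from hyraxnet.metrics import edge_density, node_centralities
from hyraxnet.workflow import build_period_networks


def main():
    data = get_study()
    nets = build_period_networks(data)
    rows = []
    for period, net in enumerate(nets):
        cent = node_centralities(net)
        rows.append(
            {
                "period": period,
                "phase": "day" if period % 2 == 0 else "night",
                "n_edges": int((net.weights > 0).sum() // 2),
                "density": edge_density(net),
                "mean_degree": cent["degree"].mean(),
                "mean_strength": cent["strength"].mean(),
                "mean_eigenvector": cent["eigenvector"].mean(),
            }
        )
    df = pd.DataFrame(rows)
    out = outdir("results") / "04_period_networks.tsv"
    df.to_csv(out, sep="\t", index=False, float_format="%.5f")
    day = df[df["phase"] == "day"]
    night = df[df["phase"] == "night"]
    print(
        f"wrote {out}: mean strength day {day['mean_strength'].mean():.3f} "
        f"vs night {night['mean_strength'].mean():.3f}; "
        f"mean density day {day['density'].mean():.3f} vs night {night['density'].mean():.3f}"
    )


if __name__ == "__main__":
    main()
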