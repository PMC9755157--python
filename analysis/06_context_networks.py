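"""Phase x context network correlations (day/night x active/passive)."""

import numpy as np
import pandas as pd

from common import SEED, get_study, outdir
from hyraxnet.compare import context_correlations
from hyraxnet.nullmodels import PermConfig
from hyraxnet.workflow import build_context_networks, make_ensemble

N_PERM = 1000


def main():
    data = get_study()
    nets = build_context_networks(data)
    ensemble = make_ensemble(data, PermConfig(n_perm=N_PERM, seed=SEED + 3))
    sim = context_correlations(nets, ensemble)
    rows = []
    for i, a in enumerate(sim.labels):
        for j, b in enumerate(sim.labels):
            if j <= i:
                continue
            rows.append(
                {
                    "network_a": a,
                    "network_b": b,
                    "cosine": sim.cosine[i, j],
                    "p_perm": sim.p_perm[i, j],
                    "p_adj": sim.p_adj[i, j],
                }
            )
    df = pd.DataFrame(rows)
    out = outdir("results") / "06_context_cosine.tsv"
    df.to_csv(out, sep="\t", index=False, float_format="%.5f")
    strengths = {k: float(np.sum(v.weights) / 2) for k, v in nets.items()}
    print(df.to_string(index=False))
    print(f"total SRI mass per network: {strengths}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
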