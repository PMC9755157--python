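"""Pre-processing summary: events per period, phase and context."""

import pandas as pd

from common import get_study, outdir


def main():
    data = get_study()
    ev = data.events
    ev.to_csv(outdir("scratch") / "events.tsv", sep="\t", index=False)
    summary = (
        ev.groupby(["period", "phase", "context"])
        .size()
        .rename("n_events")
        .reset_index()
    )
    out = outdir("results") / "02_event_counts.tsv"
    summary.to_csv(out, sep="\t", index=False)
    share = ev["context"].value_counts(normalize=True).rename("share").reset_index()
    share.to_csv(outdir("results") / "02_context_shares.tsv", sep="\t", index=False)
    print(f"wrote {out} ({len(ev)} events)")


if __name__ == "__main__":
    main()
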