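#!/usr/bin/env python
"""Strand-exchange gel quantification: per-lane %JM, %NC and total yield."""

import argparse
from pathlib import Path

import pandas as pd

from idpsitemap.gel import strand_exchange_yields


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    df = pd.read_csv(args.data / "gel.tsv", sep="\t")
    rows = []
    for lane_id, grp in df.groupby("lane_id"):
        raw = dict(zip(grp["band"], grp["raw"]))
        bg = dict(zip(grp["band"], grp["background"]))
        q = strand_exchange_yields(raw, bg)
        rows.append({"lane_id": lane_id, "pct_lds": q.pct_lds, "pct_jm": q.pct_jm,
                     "pct_nc": q.pct_nc, "total_yield": q.total_yield})
        print(f"lane {lane_id}: lds {q.pct_lds:5.1f} %  JM {q.pct_jm:5.1f} %  "
              f"NC {q.pct_nc:5.1f} %  total yield {q.total_yield:5.1f} %")
    pd.DataFrame(rows).to_csv(args.out / "gel_yields.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
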