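#!/usr/bin/env python
"""Score and rank candidate pockets by druggability.

Reads a pocket-descriptor CSV (site_id, A_nonpolar, S_max[, gamma,
A_druglike, C]) or falls back to a demo descriptor set spanning a strongly
druggable pocket down to an undruggable control, then ranks by
D_g = gamma * A_nonpolar * A_druglike / S_max + C.
"""

import argparse
from pathlib import Path

from fibriddi import druggability as dr


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--pockets", default=None, help="pocket descriptor CSV")
    ap.add_argument("--cutoff", type=float, default=dr.DRUGGABLE_CUTOFF_DEFAULT)
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    if args.pockets:
        pockets = dr.load_pockets_csv(args.pockets)
    else:
        pockets = [
            dr.PocketDescriptor("site1", a_nonpolar=450.0, s_max=4000.0),
            dr.PocketDescriptor("site2", a_nonpolar=300.0, s_max=4000.0),
            dr.PocketDescriptor("site3", a_nonpolar=217.0, s_max=4000.0),
            dr.PocketDescriptor("worst", a_nonpolar=44.0, s_max=4000.0),
        ]
    table = dr.ranking_table(pockets, args.cutoff)
    table.to_csv(args.out / "druggability.tsv", sep="\t", index=False)
    for _, r in table.iterrows():
        print(f"rank {r['rank']}: {r.site_id}  Dg = {r.Dg:.2f}  ({r['class']})")


if __name__ == "__main__":
    main()
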