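#!/usr/bin/env python
"""Residue-depth perturbation under ligand binding.

Generates before/after residue chains whose geometry expansion plants a
known 1-2 A depth decrease, recomputes the quasi-sequence-order depth
profiles on both, and reports the realized per-chain and overall drops
together with the chain-count relevance categories of the three sites.
"""

import argparse
from pathlib import Path

import pandas as pd

from fibriddi import depth, synth


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--drop", type=float, nargs=2, default=(1.0, 2.0))
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    before, after, truth = synth.gen_depth_chains(args.seed, depth_drop=tuple(args.drop))
    pb, _ = depth.residue_depth(before, "unbound")
    pa, _ = depth.residue_depth(after, "ligand-bound")
    dd, summary = depth.depth_perturbation(pb, pa)
    depth.profile_table(pb).to_csv(args.out / "depth_unbound.tsv", sep="\t", index=False)
    depth.profile_table(pa).to_csv(args.out / "depth_bound.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"chain": k[0], "pos": k[1], "dD": v} for k, v in sorted(dd.items())]
    ).to_csv(args.out / "depth_perturbation.tsv", sep="\t", index=False)

    for cid, drop in truth.per_chain_drop.items():
        print(f"chain {cid}: planted mean drop {drop:.2f} A")
    print(f"overall mean depth decrease: {summary['mean']:.2f} A "
          f"(max |dD| {summary['max_abs']:.2f} A)")
    for site, c in (("site1", 6), ("site2", 3), ("site3", 3)):
        print(f"{site}: {c} chains -> {depth.chain_relevance(c)} relevance")


if __name__ == "__main__":
    main()
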