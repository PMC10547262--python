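"""Factor-binding contact screen on replicated synthetic genomes.

For each seeded replicate: plant anchors, simulate the contact map, compute
O/E, enumerate CRE pairs at short (0.1-1 Mb) and long (1-10 Mb) range, and
rank the planted factor against 10 independent decoys by Mann-Whitney
F = U/(n1*n2). Reports how often the planted factor tops both strata.

Run:  python analysis/02_contact_screen.py [--seed 1 --n-seeds 5]
"""

import argparse
from pathlib import Path

from ulitools import io, studies

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-seeds", type=int, default=5)
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = studies.screen_recovery_study(args.seed, n_seeds=args.n_seeds)
    io.write_table(table, args.out / "screen_recovery.tsv",
                   "per-seed screen recovery: planted F, Bonferroni p_adj, rank vs decoys")

    for stratum, grp in table.groupby("stratum"):
        print(f"{stratum}: planted F = {grp['planted_F'].mean():.3f} "
              f"(rank 1 in {(grp['planted_rank'] == 1).sum()}/{len(grp)} seeds), "
              f"decoy |F-0.5| max = {grp['decoy_F_max_dev'].max():.3f}")
    top_both = (table.groupby("seed")["planted_rank"].max() == 1).mean()
    print(f"planted factor tops both strata in {top_both:.0%} of seeds")
    print(f"wrote {args.out / 'screen_recovery.tsv'}")


if __name__ == "__main__":
    main()
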