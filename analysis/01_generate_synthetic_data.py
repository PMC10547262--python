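"""Generate the synthetic study dataset with planted ultra-long-range structure.

Builds a 3 x 30 Mb toy genome at 10-kb bins with 300 anchor CREs among 2100,
central enrichment e = 2 and stripe factor s = 1.4 on a power-law Poisson
contact map (depth 100 = one mean count per pixel at 1 Mb), one planted
factor and 10 decoys. Writes the full text dataset plus the ground truth.

Run:  python analysis/01_generate_synthetic_data.py [--seed 1]
"""

import argparse
from pathlib import Path

from ulitools import io, synth

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "synthetic")
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    bins, truth, matrix, peak_sets, labels = synth.generate_dataset(args.seed)
    io.write_bins(bins, out / "bins.tsv")
    io.write_triplets(matrix, out / "contacts.tsv")
    io.write_bed(truth.anchors, out / "anchors.bed")
    io.write_bed(truth.cres, out / "cres.bed")
    for name, peaks in peak_sets.items():
        io.write_bed(peaks, out / f"factor_{name}.bed")
    io.write_table(labels, out / "factor_labels.tsv", "ground-truth factor labels")
    truth.to_json(out / "truth.json")
    io.write_manifest(out, "synth", dict(seed=args.seed), args.seed)

    print(f"genome: {len(bins.chroms)} chromosomes, {bins.n_bins} bins at "
          f"{bins.resolution / 1000:.0f} kb")
    print(f"contacts: {matrix.total_count():.0f} total counts")
    print(f"CREs: {len(truth.cres)} ({len(truth.anchors)} anchors), factors: "
          f"{', '.join(peak_sets)}")
    print(f"wrote dataset to {out}")


if __name__ == "__main__":
    main()
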