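"""Text-format readers/writers and run manifests.

All tabular output is TSV with '#' header lines naming columns and units.
Formats: BED3+ / narrowPeak (0-based half-open), bin tables as
chrom/start/end TSV, contact triplets as "bin1_id  bin2_id  count" TSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import BinTable, ContactMatrix, OEMatrix

__all__ = [
    "read_bed",
    "write_bed",
    "write_bins",
    "write_triplets",
    "write_oe_triplets",
    "write_table",
    "write_manifest",
]

NARROWPEAK_COLS = ["chrom", "start", "end", "name", "score_int", "strand",
                   "signalValue", "pValue", "qValue", "peak"]


def read_bed(path, assembly: BinTable | None = None) -> pd.DataFrame:
    """Read BED3+ or narrowPeak intervals; validated, sorted, 0-based half-open.

    For 10-column narrowPeak input the ``signalValue`` column (7th) becomes
    the ``score``. Errors name the offending line.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            if assembly is not None and chrom not in assembly.chrom_slices:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            row = {"chrom": chrom, "start": start, "end": end}
            if len(parts) >= 10:            # narrowPeak: signalValue is field 7
                row["score"] = float(parts[6])
            elif len(parts) >= 5:
                row["score"] = float(parts[4])
            rows.append(row)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"]
                      if rows and "score" in rows[0] else ["chrom", "start", "end"])
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "score"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_bins(bins: BinTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# bin table, 0-based half-open, resolution={bins.resolution} bp\n")
        bins.df[["chrom", "start", "end"]].to_csv(fh, sep="\t", header=False, index=False)


def write_triplets(matrix: ContactMatrix, path) -> None:
    coo = matrix.upper.tocoo()
    with open(path, "w") as fh:
        fh.write("# bin1_id\tbin2_id\tcount (upper triangle, bin ids 0-based)\n")
        for i, j, c in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i}\t{j}\t{c:g}\n")


def write_oe_triplets(oe: OEMatrix, path) -> None:
    """Export defined O/E pixels (upper triangle) in the triplet dialect."""
    with open(path, "w") as fh:
        fh.write("# bin1_id\tbin2_id\toe_value (upper triangle, defined pixels only)\n")
        for chrom in oe.bins.chroms:
            s = oe.bins.chrom_slices[chrom]
            dense = oe.dense[chrom]
            iu, ju = np.triu_indices(dense.shape[0])
            vals = dense[iu, ju]
            ok = np.isfinite(vals) & (vals != 0)
            for i, j, v in zip(iu[ok] + s.start, ju[ok] + s.start, vals[ok]):
                fh.write(f"{i}\t{j}\t{v:.6g}\n")


def write_table(df: pd.DataFrame, path, header_note: str = "") -> None:
    with open(path, "w") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        fh.write("# " + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def write_manifest(out_dir, stage: str, params: dict, seed: int,
                   inputs: list | None = None) -> Path:
    """Record resolved parameters, seed, and input checksums for a run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "seed": seed,
        "parameters": {k: (v if isinstance(v, (int, float, str, bool, list, type(None)))
                           else str(v)) for k, v in params.items()},
        "inputs": {str(p): _checksum(Path(p)) for p in (inputs or []) if Path(p).exists()},
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return path
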