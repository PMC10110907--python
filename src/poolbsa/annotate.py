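"""Relate SNPs to gene models, QTL intervals, and fixed-width windows.

Coordinates are 1-based inclusive throughout (VCF convention); BED input
is converted from its 0-based half-open form on read. Gene proximity uses
gap distance to the nearest gene edge (0 inside the gene, 1 for direct
adjacency), ignoring strand.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


def _parse_gff3_attributes(attrs: str) -> dict[str, str]:
    out = {}
    for item in attrs.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_annotation(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read gene models from GFF3 or BED into a gene table.

    The format is inferred from the extension unless given. Only GFF3
    records of type ``gene`` are kept. BED intervals (0-based half-open)
    become 1-based inclusive. Returns a frame with columns
    ``gene_id, chrom, start, end, strand`` sorted by (chrom, start).
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "bed" if suffix == ".bed" else "gff3"
    fmt = fmt.lower()
    if fmt not in ("gff3", "bed"):
        raise AnnotationError(f"unknown annotation format {fmt!r}")

    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "gff3":
                    if len(fields) != 9:
                        raise ValueError("expected 9 tab-separated fields")
                    if fields[2] != "gene":
                        continue
                    attrs = _parse_gff3_attributes(fields[8])
                    gene_id = attrs.get("ID") or attrs.get("gene_id")
                    if not gene_id:
                        raise ValueError("gene record lacks an ID attribute")
                    start, end = int(fields[3]), int(fields[4])
                    strand = fields[6]
                else:
                    if len(fields) < 3:
                        raise ValueError("expected at least 3 BED fields")
                    start = int(fields[1]) + 1  # 0-based half-open -> 1-based
                    end = int(fields[2])
                    gene_id = fields[3] if len(fields) > 3 else f"bed_{lineno}"
                    strand = fields[5] if len(fields) > 5 else "."
                if start > end:
                    raise ValueError(f"start {start} > end {end}")
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": fields[0],
                    "start": start,
                    "end": end,
                    "strand": strand,
                }
            )
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    return genes.sort_values(["chrom", "start"], kind="stable").reset_index(
        drop=True
    )


def read_intervals(path: str | Path) -> pd.DataFrame:
    """Read labelled intervals (e.g. QTL regions) from a TSV or BED.

    TSV columns: ``label, chrom, start, end`` (1-based inclusive); a
    ``.bed`` extension switches to BED coordinate conversion with the
    name field as label.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        genes = read_annotation(path, fmt="bed")
        return genes.rename(columns={"gene_id": "label"})[
            ["label", "chrom", "start", "end"]
        ]
    df = pd.read_csv(path, sep="\t")
    required = {"label", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(f"{path}: missing columns {sorted(missing)}")
    return df[["label", "chrom", "start", "end"]]


def assign_genes(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    max_dist: int = 3000,
) -> pd.DataFrame:
    """Assign each SNP to every gene within ``max_dist`` bp.

    Distance is 0 when the SNP lies inside the gene span, else the gap to
    the nearest gene edge (adjacent base = 1 bp). A SNP may match several
    overlapping genes; a SNP with no gene in range gets a single
    intergenic record with missing ``gene_id`` and ``distance``.
    """
    rows = []
    for chrom, snp_group in snps.groupby("chrom", sort=False):
        chrom_genes = genes[genes["chrom"] == chrom]
        pos = snp_group["pos"].to_numpy()[:, None]
        if len(chrom_genes):
            start = chrom_genes["start"].to_numpy()[None, :]
            end = chrom_genes["end"].to_numpy()[None, :]
            dist = np.maximum(start - pos, 0) + np.maximum(pos - end, 0)
            within = dist <= max_dist
        else:
            within = np.zeros((len(snp_group), 0), dtype=bool)
            dist = within.astype(int)
        gene_ids = chrom_genes["gene_id"].to_numpy()
        for i, (_, snp) in enumerate(snp_group.iterrows()):
            hits = np.flatnonzero(within[i])
            if hits.size == 0:
                rows.append(
                    {
                        "chrom": chrom,
                        "pos": int(snp["pos"]),
                        "gene_id": None,
                        "distance": np.nan,
                    }
                )
            for g in hits:
                rows.append(
                    {
                        "chrom": chrom,
                        "pos": int(snp["pos"]),
                        "gene_id": gene_ids[g],
                        "distance": int(dist[i, g]),
                    }
                )
    return pd.DataFrame(rows, columns=["chrom", "pos", "gene_id", "distance"])


def overlap_intervals(
    snps: pd.DataFrame, intervals: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Containment of SNPs in labelled intervals (inclusive boundaries).

    Returns ``(membership, counts)``: one membership row per (SNP,
    interval) containment, and per-interval SNP counts (intervals with no
    SNPs report zero).
    """
    rows = []
    for _, iv in intervals.iterrows():
        in_iv = snps[
            (snps["chrom"] == iv["chrom"])
            & (snps["pos"] >= iv["start"])
            & (snps["pos"] <= iv["end"])
        ]
        for _, snp in in_iv.iterrows():
            rows.append(
                {
                    "label": iv["label"],
                    "chrom": snp["chrom"],
                    "pos": int(snp["pos"]),
                }
            )
    membership = pd.DataFrame(rows, columns=["label", "chrom", "pos"])
    counts = (
        membership.groupby("label").size()
        if len(membership)
        else pd.Series(dtype=int)
    )
    count_table = pd.DataFrame(
        {
            "label": intervals["label"],
            "n_snps": [
                int(counts.get(label, 0)) for label in intervals["label"]
            ],
        }
    )
    return membership, count_table


def window_max(
    lrt_table: pd.DataFrame,
    window: int = 100_000,
) -> pd.DataFrame:
    """Per-window maxima of the LRT statistics and significant-SNP counts.

    Windows are non-overlapping, anchored at position 1 on each arm:
    window k spans [k*window + 1, (k+1)*window]. All windows from the
    start of the arm through the last SNP-bearing window are emitted;
    empty windows carry missing maxima and zero counts.
    """
    stat_cols = [c for c in ("LRT1", "LRT2", "LRT4") if c in lrt_table.columns]
    out = []
    for chrom, group in lrt_table.groupby("chrom", sort=False):
        win_idx = (group["pos"].to_numpy() - 1) // window
        n_windows = int(win_idx.max()) + 1
        for k in range(n_windows):
            in_win = group[win_idx == k]
            row = {
                "chrom": chrom,
                "start": k * window + 1,
                "end": (k + 1) * window,
                "n_snps": int(len(in_win)),
            }
            for col in stat_cols:
                row[f"max_{col}"] = (
                    float(in_win[col].max()) if len(in_win) else np.nan
                )
            if "significant" in lrt_table.columns:
                row["n_significant"] = int(in_win["significant"].sum())
            out.append(row)
    return pd.DataFrame(out)
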