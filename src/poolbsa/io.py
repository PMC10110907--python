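"""Pool count tables, study designs, and site-level filters.

The central container is :class:`PoolCounts`: one row per biallelic SNP,
with per-pool reference-allele read counts and total depths, plus a
:class:`StudyDesign` describing how pools pair up into control/selected
pairs within populations and how populations group by exposure risk.

Counts travel as a tab-separated dialect with header::

    chrom  pos  ref  alt  <pool_id>:ref  <pool_id>:depth  ...

Missing values (".") are forbidden; zeros must be explicit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: The five major D. melanogaster chromosome arms kept by the default filter.
MAJOR_ARMS = frozenset({"2L", "2R", "3L", "3R", "X"})

SITE_COLUMNS = ["chrom", "pos", "ref", "alt"]


class PoolDataError(ValueError):
    """Raised for malformed or inconsistent pool count data."""


@dataclass(frozen=True)
class Pool:
    """A single sequenced pool of females."""

    pool_id: str
    population: str
    condition: str  # "control" or "selected"
    n_females: int

    def __post_init__(self) -> None:
        if self.condition not in ("control", "selected"):
            raise PoolDataError(
                f"pool {self.pool_id!r}: condition must be 'control' or "
                f"'selected', got {self.condition!r}"
            )
        if self.n_females < 1:
            raise PoolDataError(f"pool {self.pool_id!r}: n_females must be >= 1")


@dataclass
class StudyDesign:
    """Populations, exposure groups, and control/selected pool pairing.

    Parameters
    ----------
    populations
        Ordered ``(population_id, exposure_group)`` pairs; exposure group is
        ``"high"`` or ``"low"`` copper-exposure risk.
    pools
        One control and one selected :class:`Pool` per population.
    """

    populations: list[tuple[str, str]]
    pools: list[Pool]

    def __post_init__(self) -> None:
        groups = {g for _, g in self.populations}
        bad = groups - {"high", "low"}
        if bad:
            raise PoolDataError(f"unknown exposure group(s): {sorted(bad)}")
        pop_ids = [p for p, _ in self.populations]
        if len(set(pop_ids)) != len(pop_ids):
            raise PoolDataError("duplicate population ids in design")
        for pop in pop_ids:
            for cond in ("control", "selected"):
                matches = [
                    p for p in self.pools
                    if p.population == pop and p.condition == cond
                ]
                if len(matches) != 1:
                    raise PoolDataError(
                        f"population {pop!r} needs exactly one {cond} pool, "
                        f"found {len(matches)}"
                    )
        for p in self.pools:
            if p.population not in pop_ids:
                raise PoolDataError(
                    f"pool {p.pool_id!r} references unknown population "
                    f"{p.population!r}"
                )

    @property
    def population_ids(self) -> list[str]:
        return [p for p, _ in self.populations]

    def exposure_group(self, population: str) -> str:
        for pop, grp in self.populations:
            if pop == population:
                return grp
        raise KeyError(population)

    def pool_for(self, population: str, condition: str) -> Pool:
        for p in self.pools:
            if p.population == population and p.condition == condition:
                return p
        raise KeyError((population, condition))

    @property
    def pool_ids(self) -> list[str]:
        return [p.pool_id for p in self.pools]


@dataclass
class PoolCounts:
    """Per-SNP, per-pool reference read counts and depths.

    ``sites`` holds one row per SNP with columns ``chrom, pos, ref, alt``
    followed by ``<pool_id>:ref`` and ``<pool_id>:depth`` for every pool.
    """

    sites: pd.DataFrame
    pool_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pool_ids:
            self.pool_ids = [
                c[:-4] for c in self.sites.columns if c.endswith(":ref")
            ]
        self.validate()

    def validate(self) -> None:
        missing = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing:
            raise PoolDataError(f"missing site columns: {missing}")
        for pid in self.pool_ids:
            for suffix in (":ref", ":depth"):
                if pid + suffix not in self.sites.columns:
                    raise PoolDataError(f"missing column {pid + suffix!r}")
        if len(self.sites):
            dup = self.sites.duplicated(subset=["chrom", "pos"])
            if dup.any():
                row = self.sites[dup].iloc[0]
                raise PoolDataError(
                    f"duplicate site {row['chrom']}:{row['pos']}"
                )
            for pid in self.pool_ids:
                ref = self.sites[pid + ":ref"].to_numpy()
                depth = self.sites[pid + ":depth"].to_numpy()
                if (ref < 0).any() or (depth < ref).any():
                    bad = int(np.argmax((ref < 0) | (depth < ref)))
                    raise PoolDataError(
                        f"pool {pid!r}, row {bad}: need 0 <= ref_reads <= depth "
                        f"(got ref={ref[bad]}, depth={depth[bad]})"
                    )

    def __len__(self) -> int:
        return len(self.sites)

    def ref(self, pool_id: str) -> np.ndarray:
        return self.sites[pool_id + ":ref"].to_numpy(dtype=np.int64)

    def depth(self, pool_id: str) -> np.ndarray:
        return self.sites[pool_id + ":depth"].to_numpy(dtype=np.int64)

    def freq(self, pool_id: str) -> np.ndarray:
        """Reference-allele frequency estimate ref_reads / depth per site."""
        depth = self.depth(pool_id).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(depth > 0, self.ref(pool_id) / depth, np.nan)

    def subset(self, mask: np.ndarray) -> "PoolCounts":
        return PoolCounts(
            self.sites.loc[mask].reset_index(drop=True), list(self.pool_ids)
        )


# ---------------------------------------------------------------------------
# counts TSV dialect


def write_counts_tsv(counts: PoolCounts, path: str | Path) -> None:
    """Write counts in the pipeline's TSV dialect (explicit zeros, no '.')."""
    counts.sites.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> PoolCounts:
    """Read a counts TSV; malformed rows raise with their line number."""
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SITE_COLUMNS if c not in raw.columns]
    if missing:
        raise PoolDataError(f"{path}: header missing columns {missing}")
    pool_ids = [c[:-4] for c in raw.columns if c.endswith(":ref")]
    for pid in pool_ids:
        if pid + ":depth" not in raw.columns:
            raise PoolDataError(f"{path}: pool {pid!r} has :ref but no :depth")
    count_cols = [pid + s for pid in pool_ids for s in (":ref", ":depth")]
    out = raw[SITE_COLUMNS].copy()
    for col in ["pos"] + count_cols:
        values = raw[col].str.strip()
        ok = values.str.fullmatch(r"\d+")
        if not ok.all():
            line = int(np.argmax(~ok.to_numpy())) + 2  # 1-based + header
            raise PoolDataError(
                f"{path}:{line}: column {col!r} has non-integer value "
                f"{values.iloc[line - 2]!r}"
            )
        out[col] = values.astype(np.int64)
    # surface ref > depth with a line number before PoolCounts validation
    for pid in pool_ids:
        bad = out[pid + ":ref"] > out[pid + ":depth"]
        if bad.any():
            line = int(np.argmax(bad.to_numpy())) + 2
            raise PoolDataError(
                f"{path}:{line}: pool {pid!r} ref_reads exceeds depth"
            )
    return PoolCounts(out.reset_index(drop=True), pool_ids)


# ---------------------------------------------------------------------------
# study design files


def read_design(path: str | Path) -> StudyDesign:
    """Read a study design from YAML (``populations`` + ``pools`` lists)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        populations = [
            (str(p["id"]), str(p["exposure_group"])) for p in doc["populations"]
        ]
        pools = [
            Pool(
                pool_id=str(p["id"]),
                population=str(p["population"]),
                condition=str(p["condition"]),
                n_females=int(p["n_females"]),
            )
            for p in doc["pools"]
        ]
    except (KeyError, TypeError) as exc:
        raise PoolDataError(f"{path}: malformed design file ({exc})") from exc
    return StudyDesign(populations, pools)


def write_design(design: StudyDesign, path: str | Path) -> None:
    doc = {
        "populations": [
            {"id": pop, "exposure_group": grp} for pop, grp in design.populations
        ],
        "pools": [
            {
                "id": p.pool_id,
                "population": p.population,
                "condition": p.condition,
                "n_females": p.n_females,
            }
            for p in design.pools
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# VCF import


def import_vcf(
    path: str | Path,
    design: StudyDesign,
    sample_map: Mapping[str, str],
) -> PoolCounts:
    """Import biallelic SNPs from a multi-sample VCF with AD annotations.

    Indels and sites with more than two segregating bases are dropped.
    ``sample_map`` maps VCF sample names to pool ids; every VCF sample must
    be mapped, and every pool in the design must receive a sample.

    Reference reads are the first AD entry; depth is ref + alt AD.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unmapped = [s for s in samples if s not in sample_map]
    if unmapped:
        raise PoolDataError(f"VCF samples not in sample_map: {unmapped}")
    mapped_pools = {sample_map[s] for s in samples}
    missing = [pid for pid in design.pool_ids if pid not in mapped_pools]
    if missing:
        raise PoolDataError(f"design pools missing from VCF: {missing}")

    pool_order = [sample_map[s] for s in samples]
    rows: list[list] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            continue  # multiallelic: more than two segregating bases
        ref, alt = variant.REF, variant.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or alt not in "ACGT":
            continue  # indel or symbolic allele
        ad = variant.format("AD")
        if ad is None:
            raise PoolDataError(
                f"{path}: record {variant.CHROM}:{variant.POS} lacks the "
                "AD (allelic depth) FORMAT field"
            )
        ad = np.asarray(ad, dtype=np.int64)
        ad[ad < 0] = 0  # cyvcf2 encodes missing AD as negative
        row = [variant.CHROM, variant.POS, ref, alt]
        for ref_reads, alt_reads in ad[:, :2]:
            row.extend([int(ref_reads), int(ref_reads + alt_reads)])
        rows.append(row)

    columns = SITE_COLUMNS + [
        pid + s for pid in pool_order for s in (":ref", ":depth")
    ]
    sites = pd.DataFrame(rows, columns=columns)
    if len(sites) == 0:
        sites = sites.astype({"pos": np.int64})
    # reorder count columns to design pool order for stable downstream output
    ordered = SITE_COLUMNS + [
        pid + s for pid in design.pool_ids for s in (":ref", ":depth")
    ]
    return PoolCounts(sites[ordered], list(design.pool_ids))


# ---------------------------------------------------------------------------
# site filters


def filter_sites(
    counts: PoolCounts,
    design: StudyDesign,
    min_depth: int = 100,
    min_maf: float = 0.05,
    arms: Iterable[str] = MAJOR_ARMS,
) -> tuple[PoolCounts, dict[str, int]]:
    """Apply the site-level filters and report per-rule drop counts.

    A site survives when (i) it lies on one of ``arms``; (ii) every pool has
    depth >= ``min_depth``; (iii) the folded control-pool allele frequency
    is >= ``min_maf`` in at least one population. Each dropped site is
    attributed to the first rule it fails, in that order.

    Returns the filtered counts and a dict of drop counts keyed by rule.
    """
    arms = set(arms)
    n = len(counts)
    keep = np.ones(n, dtype=bool)
    dropped: dict[str, int] = {}

    on_arm = counts.sites["chrom"].isin(arms).to_numpy()
    dropped["chromosome_arm"] = int((~on_arm).sum())
    keep &= on_arm

    depth_ok = np.ones(n, dtype=bool)
    for pid in counts.pool_ids:
        depth_ok &= counts.depth(pid) >= min_depth
    dropped["min_depth"] = int((keep & ~depth_ok).sum())
    keep &= depth_ok

    maf_ok = np.zeros(n, dtype=bool)
    for pop in design.population_ids:
        pid = design.pool_for(pop, "control").pool_id
        p = counts.freq(pid)
        with np.errstate(invalid="ignore"):
            folded = np.fmin(p, 1.0 - p)
        maf_ok |= np.nan_to_num(folded, nan=-1.0) >= min_maf
    dropped["min_maf"] = int((keep & ~maf_ok).sum())
    keep &= maf_ok

    for rule, count in dropped.items():
        logger.info("filter_sites: dropped %d site(s) by rule %s", count, rule)
    logger.info("filter_sites: retained %d of %d site(s)", int(keep.sum()), n)
    return counts.subset(keep), dropped
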