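"""Read counting, depth normalization and background (input) subtraction.

Produces the region x dataset count table that feeds the transformation and
testing stages: per dataset an immunoprecipitated (IP) track and its matched
chromatin input (IN) track are counted over the same regions, each scaled to a
common sequencing depth, and the background-subtracted signal is
``max(IP - IN, 0)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import RegionSet
from .signal import SignalMatrix

#: Depth-normalization target: counts are scaled to this many mapped reads.
DEFAULT_DEPTH_SCALE = 10_000_000


@dataclass
class CountTable:
    """Region x dataset matrices of (depth-normalized) IP and IN read counts.

    ``ip`` and ``in_`` are DataFrames indexed by region id with one column per
    dataset id; ``library_sizes`` maps ``"<dataset>_IP"`` / ``"<dataset>_IN"``
    to total mapped reads (absent for tables loaded pre-normalized).
    """

    regions: RegionSet
    ip: pd.DataFrame
    in_: pd.DataFrame
    library_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.ip.columns) != list(self.in_.columns):
            raise ValueError("IP and IN tables must share dataset columns")
        if self.ip.shape != self.in_.shape:
            raise ValueError("IP and IN tables must have identical shape")
        if len(self.ip) != len(self.regions):
            raise ValueError("count rows must match the region set")

    @property
    def dataset_ids(self) -> list[str]:
        return list(self.ip.columns)


def count_reads(bam_path: str, regions: RegionSet) -> tuple[np.ndarray, int]:
    """Count aligned reads overlapping each region by >= 1 bp.

    Parameters
    ----------
    bam_path : str
        Coordinate-sorted, indexed BAM file.
    regions : RegionSet

    Returns
    -------
    counts : ndarray of int, shape (q,)
    library_size : int
        Total mapped reads in the file.

    Notes
    -----
    Any overlap of the read's aligned span counts; duplicates and multimappers
    are counted as present in the file. Unknown chromosomes yield a count of 0
    with a warning.
    """
    import pysam

    counts = np.zeros(len(regions), dtype=np.int64)
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        if not bam.has_index():
            raise ValueError(f"{bam_path}: missing BAM index (.bai); sort and index first")
        library_size = bam.mapped
        known = set(bam.references)
        warned: set[str] = set()
        for i, region in enumerate(regions):
            if region.chrom not in known:
                if region.chrom not in warned:
                    warnings.warn(f"{bam_path}: chromosome {region.chrom!r} not in BAM header")
                    warned.add(region.chrom)
                continue
            counts[i] = sum(
                1
                for read in bam.fetch(region.chrom, region.start, region.end)
                if not read.is_unmapped
            )
    return counts, library_size


def depth_normalize(
    raw: np.ndarray, library_size: int, scale: int = DEFAULT_DEPTH_SCALE
) -> np.ndarray:
    """Scale raw counts to a fixed sequencing depth (default 10 million reads)."""
    if library_size <= 0:
        raise ValueError("library_size must be positive (empty alignment file?)")
    return np.asarray(raw, dtype=float) * (scale / library_size)


def subtract_background(ct: CountTable) -> SignalMatrix:
    """Background-subtracted signal, ``max(IP - IN, 0)`` per cell.

    Negative differences reflect regions below background noise and are
    clamped to zero so the square-root transform downstream is defined.
    """
    values = np.maximum(ct.ip.to_numpy(dtype=float) - ct.in_.to_numpy(dtype=float), 0.0)
    return SignalMatrix(
        regions=ct.regions, dataset_ids=ct.dataset_ids, values=values, stage="raw"
    )


def read_counts_tsv(path: str) -> CountTable:
    """Load a count table in the ``region_id  <ds>_IP  <ds>_IN ...`` dialect."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ip_cols = [c for c in df.columns if c.endswith("_IP")]
    in_cols = [c for c in df.columns if c.endswith("_IN")]
    datasets = [c[:-3] for c in ip_cols]
    if not datasets or [c[:-3] for c in in_cols] != datasets:
        raise ValueError(
            "count TSV must pair <dataset>_IP and <dataset>_IN columns in order"
        )
    regions = _regions_from_ids(df.index)
    ip = df[ip_cols].set_axis(datasets, axis=1)
    in_ = df[in_cols].set_axis(datasets, axis=1)
    if (ip.to_numpy() < 0).any() or (in_.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    return CountTable(regions=regions, ip=ip, in_=in_)


def write_counts_tsv(ct: CountTable, path: str) -> None:
    out = pd.DataFrame(index=ct.ip.index)
    for ds in ct.dataset_ids:
        out[f"{ds}_IP"] = ct.ip[ds]
        out[f"{ds}_IN"] = ct.in_[ds]
    out.index.name = "region_id"
    out.to_csv(path, sep="\t")


def signal_from_frame(df: pd.DataFrame) -> SignalMatrix:
    """Raw-stage signal matrix from a region x dataset IP-IN table.

    Accepts already background-subtracted values (e.g. simulated counts);
    negatives are clamped to zero. Region ids come from the index.
    """
    values = np.maximum(df.to_numpy(dtype=float), 0.0)
    return SignalMatrix(
        regions=_regions_from_ids(df.index),
        dataset_ids=[str(c) for c in df.columns],
        values=values,
        stage="raw",
    )


def _regions_from_ids(ids) -> RegionSet:
    """Rebuild a RegionSet from ``chrom:start-end`` ids, or synthesize
    placeholder coordinates for opaque ids (counting was done elsewhere)."""
    from .regions import GenomicRegion

    regs = []
    for i, rid in enumerate(ids):
        rid = str(rid)
        chrom, start, end = "unknown", i, i + 1
        if ":" in rid and "-" in rid.rsplit(":", 1)[-1]:
            c, span = rid.rsplit(":", 1)
            s, _, e = span.partition("-")
            try:
                chrom, start, end = c, int(s), int(e)
            except ValueError:
                pass
        regs.append(GenomicRegion(chrom, start, end, name=rid))
    return RegionSet(regs)
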