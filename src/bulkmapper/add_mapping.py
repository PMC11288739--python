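"""Allele-depth-difference (ADD) mapping.

The mapping signal for one pooled bulk is, per biallelic SNP,

    ADD = |ref_reads - alt_reads| / (ref_reads + alt_reads)

which is 0 for a perfectly balanced site and 1 when the pool's reads are
fixed for one allele — the signature of complete linkage to the selected
phenotype.  Sites are pre-filtered by sequencing depth (within a multiple
of one standard deviation of the mean depth, to drop low-coverage noise
and collapsed-repeat pile-ups) and by the control bulk's ADD (> 0.3 marks
non-Mendelian artifacts).  The per-chromosome track is denoised with a
running median over the nearest k SNPs, and maximal runs of smoothed
values at/above a threshold are reported as linked regions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .model import BulkSite

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MappingParams:
    """Tunables of the ADD mapping stage.

    depth_sd_multiplier
        Half-width of the depth retention band in standard deviations.
    control_add_max
        Maximum ADD tolerated in the control bulk (strictly greater removed).
    window_k
        Number of nearest SNPs (by index, same chromosome) in the running
        median window.  2500 suits ~1M-SNP whole-genome tracks; scale down
        proportionally for sparser panels.
    region_threshold
        Minimum running median for a site to belong to a linked region.
        Slightly below 1 so isolated error reads do not fragment a fixed
        region; set to 1.0 for exact behavior.
    """

    depth_sd_multiplier: float = 1.0
    control_add_max: float = 0.3
    window_k: int = 2500
    region_threshold: float = 0.995

    def __post_init__(self) -> None:
        if self.depth_sd_multiplier <= 0:
            raise ValueError("depth_sd_multiplier must be positive")
        if not 0.0 <= self.control_add_max <= 1.0:
            raise ValueError("control_add_max must be in [0, 1]")
        if self.window_k < 1:
            raise ValueError("window_k must be >= 1")
        if not 0.0 <= self.region_threshold <= 1.0:
            raise ValueError("region_threshold must be in [0, 1]")


@dataclass
class AddTrack:
    """Ordered per-chromosome ADD values, optionally with running medians."""

    chrom: str
    positions: np.ndarray
    add_values: np.ndarray
    running_medians: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.add_values = np.asarray(self.add_values, dtype=float)
        if self.positions.shape != self.add_values.shape:
            raise ValueError("positions and add_values must have equal length")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValueError(f"positions on {self.chrom} not strictly increasing")
        if len(self.add_values) and (
            self.add_values.min() < 0 or self.add_values.max() > 1
        ):
            raise ValueError("ADD values must lie in [0, 1]")
        if self.running_medians is not None:
            self.running_medians = np.asarray(self.running_medians, dtype=float)
            if self.running_medians.shape != self.add_values.shape:
                raise ValueError("running_medians length mismatch")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class LinkedRegion:
    """A maximal run of SNPs whose running-median ADD clears the threshold."""

    chrom: str
    start: int
    end: int
    n_snps: int
    median_add: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")
        if self.n_snps < 1:
            raise ValueError("region must contain at least one SNP")


def allele_depth_difference(ref_reads: int, alt_reads: int) -> float:
    """|ref - alt| / (ref + alt); undefined (error) when both counts are zero."""
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = ref_reads + alt_reads
    if total == 0:
        raise ValueError("allele depth difference undefined for 0/0 counts")
    return abs(ref_reads - alt_reads) / total


def depth_filter(
    sites: Sequence[BulkSite], bulk: str, params: MappingParams
) -> List[BulkSite]:
    """Retain sites whose depth in ``bulk`` lies within mean +/- m*sd (inclusive).

    Mean and standard deviation (population formula) are computed over the
    input sites' depths in that bulk.
    """
    if not sites:
        raise ValueError("depth_filter requires at least one site")
    depths = np.array([s.depth(bulk) for s in sites], dtype=float)
    if depths.min() < 1:
        raise ValueError("all sites must have depth >= 1 in the analyzed bulk")
    mean = depths.mean()
    sd = depths.std()  # ddof=0
    lo = mean - params.depth_sd_multiplier * sd
    hi = mean + params.depth_sd_multiplier * sd
    kept = [s for s, d in zip(sites, depths) if lo <= d <= hi]
    logger.info(
        "depth_filter(%s): %d -> %d sites (band [%.2f, %.2f])",
        bulk, len(sites), len(kept), lo, hi,
    )
    return kept


def control_filter(
    sites: Sequence[BulkSite], control_bulk: str, params: MappingParams
) -> List[BulkSite]:
    """Drop sites whose ADD in the control bulk exceeds ``control_add_max``.

    The boundary is inclusive: ADD exactly at the cutoff is retained.
    """
    kept = [s for s in sites if s.add(control_bulk) <= params.control_add_max]
    logger.info(
        "control_filter(%s): %d -> %d sites (ADD <= %g)",
        control_bulk, len(sites), len(kept), params.control_add_max,
    )
    return kept


def build_tracks(sites: Sequence[BulkSite], bulk: str) -> List[AddTrack]:
    """Assemble per-chromosome ADD tracks (SNPs only) for one bulk.

    Sites must be sorted by (chrom, pos); non-SNP records are excluded.
    """
    by_chrom: Dict[str, List[BulkSite]] = {}
    for s in sites:
        if not s.is_snp:
            continue
        by_chrom.setdefault(s.chrom, []).append(s)
    tracks = []
    for chrom, group in by_chrom.items():
        tracks.append(
            AddTrack(
                chrom=chrom,
                positions=np.array([s.pos for s in group]),
                add_values=np.array([s.add(bulk) for s in group]),
            )
        )
    return tracks


def _nearest_k_medians(values: np.ndarray, k: int) -> np.ndarray:
    """Median over the k nearest indices (ties toward the lower index).

    The nearest-k window around index i is contiguous: for odd k it is
    symmetric, for even k the extra member sits on the lower-index side.
    At the chromosome edges the window shifts (never shrinks) so it always
    holds exactly min(k, n) members.
    """
    n = len(values)
    if n == 0:
        return values.copy()
    k = min(k, n)
    if k == 1:
        return values.astype(float).copy()
    windows = sliding_window_view(values, k)
    window_medians = np.median(windows, axis=1)
    starts = np.clip(np.arange(n) - k // 2, 0, n - k)
    return window_medians[starts]


def running_median(track: AddTrack, params: MappingParams) -> AddTrack:
    """Return a copy of ``track`` with nearest-k running medians filled in."""
    if len(track) == 0:
        raise ValueError("running_median requires a non-empty track")
    meds = _nearest_k_medians(track.add_values, params.window_k)
    return AddTrack(
        chrom=track.chrom,
        positions=track.positions.copy(),
        add_values=track.add_values.copy(),
        running_medians=meds,
    )


def call_linked_regions(
    track: AddTrack, params: MappingParams
) -> List[LinkedRegion]:
    """Maximal runs of consecutive sites with running median >= threshold."""
    if track.running_medians is None:
        raise ValueError("call_linked_regions requires running medians")
    above = track.running_medians >= params.region_threshold
    regions: List[LinkedRegion] = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            members = track.add_values[i : j + 1]
            regions.append(
                LinkedRegion(
                    chrom=track.chrom,
                    start=int(track.positions[i]),
                    end=int(track.positions[j]),
                    n_snps=j - i + 1,
                    median_add=float(np.median(members)),
                )
            )
            i = j + 1
        else:
            i += 1
    return regions
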