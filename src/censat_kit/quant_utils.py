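"""K-mer genome-size estimation and ChIP/input enrichment quantification.

Genome size follows the Lander-Waterman identity G = Knum / Kdepth,
where Knum is the total number of k-mer instances in the read set and
Kdepth the modal k-mer depth of the k-mer frequency histogram.  ChIP
enrichment is the fold change of mean ChIP/input coverage ratio inside
satellite array regions versus the rest of the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_core import Interval, logger
from .tr_annotation import encode_sequence


@dataclass
class KmerStats:
    k: int
    knum: int
    kdepth: int
    histogram: dict[int, int]
    genome_size: int

    def __post_init__(self):
        total = sum(d * c for d, c in self.histogram.items())
        assert total == self.knum, "histogram does not conserve k-mer count"


@dataclass
class CoverageTrack:
    """Binned coverage: per-chromosome value arrays tiling each chromosome."""

    bin_width: int
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def same_binning(self, other: "CoverageTrack") -> bool:
        if self.bin_width != other.bin_width:
            return False
        if set(self.values) != set(other.values):
            return False
        return all(len(self.values[c]) == len(other.values[c]) for c in self.values)

    def to_bedgraph_rows(self):
        for chrom in sorted(self.values):
            vals = self.values[chrom]
            for i, v in enumerate(vals):
                yield chrom, i * self.bin_width, (i + 1) * self.bin_width, float(v)

    @classmethod
    def from_bedgraph_rows(cls, rows, bin_width: int) -> "CoverageTrack":
        values: dict[str, dict[int, float]] = {}
        for chrom, start, end, value in rows:
            if (end - start) != bin_width and end % bin_width != 0:
                raise ValueError(f"row {chrom}:{start}-{end} violates bin width")
            values.setdefault(chrom, {})[start // bin_width] = value
        track = cls(bin_width=bin_width)
        for chrom, d in values.items():
            arr = np.zeros(max(d) + 1)
            for idx, v in d.items():
                arr[idx] = v
            track.values[chrom] = arr
        return track


def canonical_kmer_hashes(seq: str, k: int) -> np.ndarray:
    """Canonical (strand-min) base-4 hashes of all k-mers of a sequence;
    windows containing N are dropped."""
    codes = encode_sequence(seq.upper())
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = ~np.any(windows == 4, axis=1)
    fwd = windows @ powers
    # reverse complement: complement codes (3 - c) read right-to-left
    rc = (3 - windows[:, ::-1]) @ powers
    canon = np.minimum(fwd, rc)
    return canon[valid]


def kmer_histogram(reads, k: int = 17) -> KmerStats:
    """Exact canonical k-mer counting over a read set.

    ``reads`` is an iterable of nucleotide strings (or a mapping whose
    values are sequences).  k must be odd (no palindromic canonical
    ambiguity) and in [11, 31].  Reads shorter than k are skipped and
    logged.  Kdepth and genome size are filled in by the companion
    estimators.
    """
    if k % 2 == 0 or not (11 <= k <= 31):
        raise ValueError("k must be odd and within [11, 31]")
    if hasattr(reads, "values"):
        reads = reads.values()
    chunks = []
    n_skipped = 0
    for read in reads:
        if len(read) < k:
            n_skipped += 1
            continue
        chunks.append(canonical_kmer_hashes(read, k))
    if n_skipped:
        logger.info("skipped %d reads shorter than k=%d", n_skipped, k)
    if not chunks:
        raise ValueError("no reads of length >= k")
    all_hashes = np.concatenate(chunks)
    _, counts = np.unique(all_hashes, return_counts=True)
    depths, n_kmers = np.unique(counts, return_counts=True)
    histogram = {int(d): int(c) for d, c in zip(depths, n_kmers)}
    knum = int(all_hashes.size)
    kdepth = estimate_kdepth(histogram)
    return KmerStats(
        k=k,
        knum=knum,
        kdepth=kdepth,
        histogram=histogram,
        genome_size=estimate_genome_size(knum, kdepth),
    )


def estimate_kdepth(histogram: dict[int, int], smooth_window: int = 5) -> int:
    """Modal k-mer depth after the error peak.

    The depth maximizing the depth spectrum beyond the first local
    minimum is returned (with no valley — error-free data — the global
    region is used).  Because read starts are granular, neighbouring
    spectrum bins fluctuate together; the mode is therefore taken on a
    centred moving average (window ``smooth_window`` bins), which keeps
    the estimate an integer while stabilising it against bin noise.
    """
    if not histogram or all(c == 0 for c in histogram.values()):
        raise ValueError("empty k-mer histogram")
    depths = sorted(histogram)
    counts = [histogram[d] for d in depths]
    valley = None
    for i in range(1, len(counts) - 1):
        if counts[i] <= counts[i - 1] and counts[i] < counts[i + 1]:
            valley = i
            break
    min_depth = depths[valley + 1] if valley is not None else depths[0]

    max_depth = depths[-1]
    dense = np.zeros(max_depth + 1)
    for d, c in histogram.items():
        dense[d] = c
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(dense, kernel, mode="same")
    candidates = np.arange(min_depth, max_depth + 1)
    if len(candidates) == 0:
        candidates = np.array([max_depth])
    peak = smoothed[candidates].max()
    ties = candidates[smoothed[candidates] >= peak - 1e-9]
    # near-equal smoothed bins (common in sparse spectra): fall back to
    # the raw count, then to the smaller depth
    best = min(ties, key=lambda d: (-dense[d], d))
    return int(best)


def estimate_genome_size(knum: int, kdepth: int) -> int:
    """Lander-Waterman estimate G = floor(Knum / Kdepth)."""
    if kdepth < 1:
        raise ValueError("kdepth must be >= 1")
    return knum // kdepth


def chip_input_ratio(
    chip: CoverageTrack, input_track: CoverageTrack, pseudocount: float = 1.0
) -> CoverageTrack:
    """Per-bin (ChIP + pseudocount) / (input + pseudocount) ratio track."""
    if not chip.same_binning(input_track):
        raise ValueError("ChIP and input tracks have different binning")
    ratio = CoverageTrack(bin_width=chip.bin_width)
    for chrom in chip.values:
        ratio.values[chrom] = (chip.values[chrom] + pseudocount) / (
            input_track.values[chrom] + pseudocount
        )
    return ratio


def fold_enrichment(ratio: CoverageTrack, regions: list[Interval]) -> float:
    """Mean ratio in bins overlapping the regions over mean ratio elsewhere.

    A bin counts as overlapping when at least half of it lies inside a
    region.  Raises when the region set selects no bins or all bins.
    """
    if not regions:
        raise ValueError("empty region set: fold change undefined")
    inside_vals = []
    outside_vals = []
    by_chrom: dict[str, list[Interval]] = {}
    for iv in regions:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    bw = ratio.bin_width
    for chrom, vals in ratio.values.items():
        mask = np.zeros(len(vals), dtype=bool)
        for iv in by_chrom.get(chrom, []):
            for b in range(len(vals)):
                bin_lo, bin_hi = b * bw, (b + 1) * bw
                ov = max(0, min(bin_hi, iv.end) - max(bin_lo, iv.start))
                if ov * 2 >= bw:
                    mask[b] = True
        inside_vals.append(vals[mask])
        outside_vals.append(vals[~mask])
    inside = np.concatenate(inside_vals)
    outside = np.concatenate(outside_vals)
    if inside.size == 0 or outside.size == 0:
        raise ValueError("regions select none or all bins: fold change undefined")
    return float(np.mean(inside) / np.mean(outside))
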