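"""Tandem-repeat region detection, filtering, validation, and telomere calls.

The built-in detector is a k-mer-spacing periodicity scan: it is meant
for desk-scale genomes and simulated fixtures.  For real assemblies the
fidelity path is ingesting a TRF ``.dat`` file (``io_core.parse_trf_dat``)
and applying only the downstream filters defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import edlib
import numpy as np

from .io_core import GenomeSequences, Interval, logger

_ENCODE = np.full(256, 4, dtype=np.int64)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Map A/C/G/T to 0..3 and anything else to 4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class TandemRepeatRegion:
    """A genomic span composed of tandem copies of one consensus unit."""

    interval: Interval
    period: int
    copy_number: float
    cruseq: str
    mean_identity: float = float("nan")
    region_id: str = ""

    def __post_init__(self):
        if not self.region_id:
            iv = self.interval
            self.region_id = f"{iv.chrom}:{iv.start}-{iv.end}"


def _kmer_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-4 rolling hashes; windows containing N hashed to -1."""
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    hashes = windows @ powers
    bad = np.any(windows == 4, axis=1)
    hashes[bad] = -1
    return hashes


def _period_votes(codes: np.ndarray, k: int, min_period: int, max_period: int):
    """(position, gap) pairs where a k-mer recurs at a candidate period."""
    hashes = _kmer_hashes(codes, k)
    if len(hashes) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    order = np.argsort(hashes, kind="stable")
    sh = hashes[order]
    same = sh[1:] == sh[:-1]
    same &= sh[1:] >= 0
    gaps = order[1:] - order[:-1]
    keep = same & (gaps >= min_period) & (gaps <= max_period)
    return order[:-1][keep], gaps[keep]


def _match_fraction(codes: np.ndarray, start: int, end: int, period: int) -> float:
    """Fraction of i in [start, end-period) with codes[i] == codes[i+period]."""
    if end - start <= period:
        return 0.0
    a = codes[start : end - period]
    b = codes[start + period : end]
    return float(np.mean(a == b))


def _consensus_unit(codes: np.ndarray, start: int, end: int, period: int) -> str:
    n_full = (end - start) // period
    frames = codes[start : start + n_full * period].reshape(n_full, period)
    cons = []
    for col in range(period):
        counts = np.bincount(frames[:, col], minlength=5)[:4]
        cons.append("ACGT"[int(np.argmax(counts))])
    return "".join(cons)


def detect_tandem_repeats(
    sequence: str,
    min_period: int = 20,
    max_period: int = 2000,
    min_span_copies: int = 3,
    match_threshold: float = 0.8,
    chrom: str = "seq",
) -> list[TandemRepeatRegion]:
    """Detect tandem-repeat regions by k-mer spacing plus periodicity check.

    A region is reported when the fraction of positions matching at lag
    ``period`` is at least ``match_threshold`` over a span of at least
    ``min_span_copies`` full periods; the smallest period in range
    satisfying the criterion is chosen, and overlapping calls at one
    locus are merged keeping the longest span.
    """
    if min_period > max_period:
        raise ValueError("min_period exceeds max_period")
    if not sequence:
        raise ValueError("empty sequence")
    codes = encode_sequence(sequence.upper())
    n = len(codes)
    k = max(3, min(12, min_period))
    positions, gaps = _period_votes(codes, k, min_period, max_period)
    if len(positions) == 0:
        return []

    # Cluster voting positions: a gap in voting positions larger than the
    # local period ends a cluster.
    idx = np.argsort(positions, kind="stable")
    positions, gaps = positions[idx], gaps[idx]
    clusters = []
    cstart = 0
    for i in range(1, len(positions)):
        allowed = max(int(gaps[i - 1]), int(gaps[i])) + k
        if positions[i] - positions[i - 1] > allowed:
            clusters.append((cstart, i))
            cstart = i
    clusters.append((cstart, len(positions)))

    candidates = []
    for lo, hi in clusters:
        cpos = positions[lo:hi]
        cgap = gaps[lo:hi]
        period = int(np.bincount(cgap).argmax())
        # Prefer the smallest period in range that still satisfies the
        # match threshold: test divisors of the modal spacing.
        span_lo, span_hi = int(cpos[0]), int(cpos[-1]) + k + period
        span_hi = min(span_hi, n)
        best_p = None
        for d in range(min_period, period + 1):
            if period % d:
                continue
            if _match_fraction(codes, span_lo, span_hi, d) >= match_threshold:
                best_p = d
                break
        if best_p is None:
            continue
        period = best_p

        # Refine boundaries: extend outward one period at a time while the
        # newly added period-block still matches at the threshold.
        start, end = span_lo, span_hi
        while start - period >= 0:
            frac = _match_fraction(codes, start - period, start + period, period)
            if frac >= match_threshold:
                start -= period
            else:
                break
        while end + period <= n:
            frac = _match_fraction(codes, end - period, end + period, period)
            if frac >= match_threshold:
                end += period
            else:
                break
        span = end - start
        if span < min_span_copies * period:
            continue
        frac = _match_fraction(codes, start, end, period)
        if frac < match_threshold:
            continue
        candidates.append((start, end, period, frac))

    # Merge overlapping calls at the same locus: keep the longest span.
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
    kept: list[tuple[int, int, int, float]] = []
    for cand in candidates:
        start, end, period, frac = cand
        redundant = False
        for ks, ke, _, _ in kept:
            ov = max(0, min(end, ke) - max(start, ks))
            if ov > 0.5 * (end - start):
                redundant = True
                break
        if not redundant:
            kept.append(cand)

    regions = []
    for start, end, period, frac in sorted(kept):
        cruseq = _consensus_unit(codes, start, end, period)
        regions.append(
            TandemRepeatRegion(
                interval=Interval(chrom, start, end),
                period=period,
                copy_number=round((end - start) / period, 2),
                cruseq=cruseq,
                mean_identity=frac,
            )
        )
    return regions


def detect_tandem_repeats_genome(genome: GenomeSequences, **kwargs) -> list[TandemRepeatRegion]:
    out = []
    for chrom, seq in genome.items():
        out.extend(detect_tandem_repeats(seq, chrom=chrom, **kwargs))
    return out


def filter_tr_regions(regions: list[TandemRepeatRegion]) -> list[TandemRepeatRegion]:
    """Keep regions with copy number > 100 and unit length > 100 bp (strict)."""
    return [r for r in regions if r.copy_number > 100 and r.period > 100]


def resolve_overlaps(regions: list[TandemRepeatRegion]) -> list[TandemRepeatRegion]:
    """Where two regions overlap by more than 80% of the shorter one,
    drop the region with the longer consensus unit.

    Pairs are examined in deterministic (chrom, start, end, period) order.
    """
    ordered = sorted(
        regions,
        key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end, r.period),
    )
    alive = [True] * len(ordered)
    for i in range(len(ordered)):
        if not alive[i]:
            continue
        for j in range(i + 1, len(ordered)):
            if not alive[j]:
                continue
            a, b = ordered[i], ordered[j]
            ov = a.interval.overlap(b.interval)
            if ov == 0:
                continue
            frac = ov / min(len(a.interval), len(b.interval))
            if frac > 0.8:
                # remove the member with the longer consensus unit;
                # on a tie remove the later one in the processing order
                if len(a.cruseq) > len(b.cruseq):
                    alive[i] = False
                    break
                else:
                    alive[j] = False
    return [r for r, ok in zip(ordered, alive) if ok]


def decompose_region(
    region_sequence: str, template: str
) -> tuple[list[tuple[int, int, float, bool]], float]:
    """Tile a region with consecutive copies of a template monomer.

    Dynamic programming aligns repeated template copies against the
    region with unit costs (match 0, mismatch 1, indel 1); the template
    may wrap at each monomer boundary and end part-way through its last
    copy at the region end.  Returns ``(tiling, mean_identity)`` where
    tiling entries are ``(start, end, identity, is_partial)`` in region
    coordinates.  A trailing monomer that ends before consuming the full
    template is flagged partial and excluded from the mean.
    """
    if not template:
        raise ValueError("empty template")
    n, t = len(region_sequence), len(template)
    if n < t:
        raise ValueError("region shorter than template")
    r = encode_sequence(region_sequence.upper())
    tmpl = encode_sequence(template.upper())

    sub = (r[:, None] != tmpl[None, :]).astype(np.int64)  # n x t mismatch costs

    D = np.empty((n + 1, t + 1), dtype=np.int64)
    D[0, :] = np.arange(t + 1)
    steps = np.arange(t + 1)
    for i in range(1, n + 1):
        prev = D[i - 1]
        cand = np.empty(t + 1, dtype=np.int64)
        cand[0] = prev[0] + 1
        cand[1:] = np.minimum(prev[:-1] + sub[i - 1], prev[1:] + 1)
        # resolve left-to-right deletion chains via prefix-min trick
        row = np.minimum.accumulate(cand - steps) + steps
        # wrap: a completed monomer may start the next one at no cost
        if row[t] < row[0]:
            row = np.minimum(row, row[t] + steps)
        D[i] = row

    # end state: free template suffix; prefer a complete monomer on ties,
    # then the longest consumed prefix
    j_end = int(np.argmin(D[n][::-1]))
    j_end = t - j_end

    boundaries = [n]
    i, j = n, j_end
    while i > 0 or j > 0:
        if j == 0:
            if i > 0 and D[i, 0] == D[i, t] and t > 0 and i not in boundaries:
                boundaries.append(i)
                j = t
                continue
            if i > 0 and D[i, 0] == D[i - 1, 0] + 1:
                i -= 1
                continue
            break
        if i > 0 and D[i, j] == D[i - 1, j - 1] + sub[i - 1, j - 1]:
            i -= 1
            j -= 1
        elif i > 0 and D[i, j] == D[i - 1, j] + 1:
            i -= 1
        elif D[i, j] == D[i, j - 1] + 1:
            j -= 1
        else:  # pragma: no cover - defensive
            raise RuntimeError("traceback failed")
    boundaries.append(0)
    boundaries = sorted(set(boundaries))

    tiling = []
    identities = []
    for k in range(len(boundaries) - 1):
        a, b = boundaries[k], boundaries[k + 1]
        chunk = region_sequence[a:b].upper()
        is_last = k == len(boundaries) - 2
        partial = is_last and j_end < t
        if partial:
            res = edlib.align(chunk, template.upper(), mode="SHW", task="distance")
        else:
            res = edlib.align(chunk, template.upper(), mode="NW", task="distance")
        edits = res["editDistance"]
        ident = 1.0 - edits / max(t, len(chunk))
        tiling.append((a, b, ident, partial))
        if not partial:
            identities.append(ident)
    mean_identity = float(np.mean(identities)) if identities else 0.0
    return tiling, mean_identity


def validate_regions(
    regions: list[TandemRepeatRegion],
    genome: GenomeSequences,
    min_identity: float = 0.8,
    max_eval_bp: int = 30000,
) -> list[TandemRepeatRegion]:
    """Keep regions whose monomer tiling against their own consensus unit
    reaches a mean identity of at least ``min_identity`` (boundary kept).

    Very long regions are scored on their leading ``max_eval_bp`` window;
    tandem arrays are homogeneous enough that the window mean estimates
    the full-region mean.
    """
    out = []
    for region in regions:
        iv = region.interval
        end = iv.end
        if len(iv) > max_eval_bp:
            end = iv.start + max_eval_bp
        seq = genome[iv.chrom][iv.start : end]
        if len(seq) < len(region.cruseq):
            continue
        _, mean_identity = decompose_region(seq, region.cruseq)
        if mean_identity >= min_identity:
            out.append(replace(region, mean_identity=mean_identity))
        else:
            logger.debug(
                "region %s discarded at identity %.3f", region.region_id, mean_identity
            )
    return out


def _max_tandem_run(window: str, motif: str) -> int:
    """Longest run of motif occurrences with inter-copy gaps <= len(motif)."""
    hits = []
    start = window.find(motif)
    while start != -1:
        hits.append(start)
        start = window.find(motif, start + 1)
    if not hits:
        return 0
    best = run = 1
    for prev, cur in zip(hits, hits[1:]):
        if cur - (prev + len(motif)) <= len(motif):
            run += 1
            best = max(best, run)
        else:
            run = 1
    return best


def find_telomeres(
    genome: GenomeSequences,
    motif: str = "CCCTGAA",
    window: int = 10000,
    min_copies: int = 10,
) -> dict[tuple[str, str], bool]:
    """Flag chromosome ends carrying a tandem run of the telomere motif.

    Returns {(chrom, "start"|"end"): flag}; each end is scanned for the
    motif and its reverse complement, whichever orientation runs longer.
    """
    if not motif:
        raise ValueError("empty motif")
    from .io_core import reverse_complement

    rc = reverse_complement(motif.upper())
    flags = {}
    for chrom, seq in genome.items():
        head = seq[:window]
        tail = seq[-window:]
        for label, win in (("start", head), ("end", tail)):
            run = max(_max_tandem_run(win, motif.upper()), _max_tandem_run(win, rc))
            flags[(chrom, label)] = run >= min_copies
    return flags
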