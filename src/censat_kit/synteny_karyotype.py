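"""Orthogroup-order synteny blocks, LCS coordinate mapping, synteny-based
cenSat assignment, and fission/fusion event bookkeeping.

Genomes are reduced to per-chromosome sequences of orthogroup IDs; a
greedy collinear-chaining pass extracts maximal blocks conserved across
genomes (same order, or fully reversed), and classic longest-common-
subsequence DP anchors each block back to gene coordinates.  Karyotype
evolution between two block genomes related only by chromosome fissions
and fusions is counted from oriented block-end adjacencies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .io_core import GeneRecord, Interval


@dataclass
class OrthoSeq:
    """Per-chromosome ordered (orthogroup_id, gene_id, interval) lists."""

    chromosomes: dict[str, list[tuple[str, str, Interval]]]

    def og_sequence(self, chrom: str) -> list[str]:
        return [og for og, _, _ in self.chromosomes[chrom]]


@dataclass
class BlockOccurrence:
    chrom: str
    start_gene: str
    end_gene: str
    orientation: str  # "+" or "-"
    interval: Interval


@dataclass
class SyntenyBlock:
    block_id: int
    og_sequence: list[str]
    occurrences: dict[str, list[BlockOccurrence]] = field(default_factory=dict)

    def copy_number(self, genome: str) -> int:
        return len(self.occurrences.get(genome, []))


@dataclass
class BlockGenome:
    """A genome as ordered signed block IDs per chromosome."""

    chromosomes: dict[str, list[int]]
    centromere_blocks: dict[str, int] = field(default_factory=dict)

    def block_multiset(self) -> Counter:
        return Counter(abs(b) for blocks in self.chromosomes.values() for b in blocks)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)


@dataclass
class EventSummary:
    n_fissions: int
    n_fusions: int
    chromosomes_before: int
    chromosomes_after: int

    def __post_init__(self):
        assert (
            self.chromosomes_after
            == self.chromosomes_before + self.n_fissions - self.n_fusions
        ), "chromosome count inconsistent with fission/fusion counts"


class UnsupportedRearrangementError(ValueError):
    """Adjacency changes not explainable by fissions and fusions alone."""


def build_orthoseq(
    gene_tables: dict[str, list[GeneRecord]], caps: dict[str, int]
) -> dict[str, OrthoSeq]:
    """Orthogroup-ID sequences per genome with copy-number filtering.

    An orthogroup whose gene count exceeds its target copy number (cap)
    in ANY genome is removed from every genome (e.g., cap 2 for a WGD
    genome, 1 otherwise).  Remaining genes are ordered by start coordinate.
    """
    for genome in gene_tables:
        if genome not in caps or caps[genome] < 1:
            raise ValueError(f"missing or invalid copy-number cap for {genome!r}")
    og_counts: dict[str, dict[str, int]] = {}
    for genome, records in gene_tables.items():
        counts: dict[str, int] = {}
        for rec in records:
            if not rec.orthogroup_id:
                raise ValueError(f"gene {rec.gene_id!r} lacks an orthogroup")
            counts[rec.orthogroup_id] = counts.get(rec.orthogroup_id, 0) + 1
        og_counts[genome] = counts

    banned = set()
    for genome, counts in og_counts.items():
        cap = caps[genome]
        banned.update(og for og, n in counts.items() if n > cap)

    out = {}
    for genome, records in gene_tables.items():
        by_chrom: dict[str, list[tuple[str, str, Interval]]] = {}
        for rec in records:
            if rec.orthogroup_id in banned:
                continue
            by_chrom.setdefault(rec.interval.chrom, []).append(
                (rec.orthogroup_id, rec.gene_id, rec.interval)
            )
        for chrom in by_chrom:
            by_chrom[chrom].sort(key=lambda t: t[2].start)
        out[genome] = OrthoSeq(chromosomes=dict(sorted(by_chrom.items())))
    return out


def _positions(orthoseq: OrthoSeq) -> dict[str, list[tuple[str, int]]]:
    """orthogroup -> [(chrom, index), ...] in deterministic order."""
    pos: dict[str, list[tuple[str, int]]] = {}
    for chrom in sorted(orthoseq.chromosomes):
        for i, (og, _, _) in enumerate(orthoseq.chromosomes[chrom]):
            pos.setdefault(og, []).append((chrom, i))
    return pos


def _chain_from(
    ref_name: str,
    ref_chrom: str,
    start_idx: int,
    orthoseqs: dict[str, OrthoSeq],
    positions: dict[str, dict[str, list[tuple[str, int]]]],
    assigned: dict[str, set[tuple[str, int]]],
    max_gap: int,
) -> list[tuple[str, dict[str, tuple[str, int]]]] | None:
    """Greedy collinear chain in the reference starting at ``start_idx``.

    Returns [(og, {genome: (chrom, idx)})] for chained genes, tracking a
    consistent direction per non-reference genome, or None if the start
    gene has no occurrence in some genome.
    """
    ref_seq = orthoseqs[ref_name].og_sequence(ref_chrom)
    others = [g for g in sorted(orthoseqs) if g != ref_name]

    og0 = ref_seq[start_idx]
    state: dict[str, tuple[str, int, int]] = {}  # genome -> (chrom, idx, dir 0=unset)
    first_links: dict[str, tuple[str, int]] = {ref_name: (ref_chrom, start_idx)}
    for g in others:
        occs = [
            p
            for p in positions[g].get(og0, [])
            if p not in assigned[g]
        ]
        if not occs:
            return None
        chrom, idx = occs[0]
        state[g] = (chrom, idx, 0)
        first_links[g] = (chrom, idx)

    chain = [(og0, first_links)]
    used_ogs = {og0}
    gap_run = 0
    i = start_idx + 1
    while i < len(ref_seq) and gap_run <= max_gap:
        if (ref_chrom, i) in assigned[ref_name]:
            gap_run += 1
            i += 1
            continue
        og = ref_seq[i]
        if og in used_ogs:
            gap_run += 1
            i += 1
            continue
        links: dict[str, tuple[str, int]] = {ref_name: (ref_chrom, i)}
        new_state = {}
        ok = True
        for g in others:
            chrom, idx, direction = state[g]
            candidates = []
            for (c, j) in positions[g].get(og, []):
                if c != chrom or (c, j) in assigned[g]:
                    continue
                step = j - idx
                if step == 0:
                    continue
                if direction and (step > 0) != (direction > 0):
                    continue
                if abs(step) > max_gap + 1:
                    continue
                candidates.append((abs(step), j))
            if not candidates:
                ok = False
                break
            _, j = min(candidates)
            new_dir = direction or (1 if j > idx else -1)
            new_state[g] = (chrom, j, new_dir)
            links[g] = (chrom, j)
        if not ok:
            gap_run += 1
            i += 1
            continue
        state.update(new_state)
        chain.append((og, links))
        used_ogs.add(og)
        gap_run = 0
        i += 1
    return chain


def detect_synteny_blocks(
    orthoseqs: dict[str, OrthoSeq],
    min_block_len: int = 5,
    max_gap: int = 20,
) -> list[SyntenyBlock]:
    """Greedy longest-chain-first collinear block detection.

    Repeatedly extracts the longest chain of orthogroup IDs conserved in
    order (or fully reversed) across all genomes, tolerating up to
    ``max_gap`` intervening unassignable genes; every gene joins at most
    one block.  Occurrences in each genome are then re-scanned so copy
    numbers above one per genome are recorded.
    """
    if len(orthoseqs) < 2:
        raise ValueError("need at least two genomes")
    genomes = sorted(orthoseqs)
    ref_name = genomes[0]
    positions = {g: _positions(orthoseqs[g]) for g in genomes}
    assigned: dict[str, set[tuple[str, int]]] = {g: set() for g in genomes}

    blocks: list[SyntenyBlock] = []
    block_id = 1
    while True:
        best_chain = None
        ref_os = orthoseqs[ref_name]
        for chrom in sorted(ref_os.chromosomes):
            n = len(ref_os.chromosomes[chrom])
            i = 0
            while i < n:
                if (chrom, i) in assigned[ref_name]:
                    i += 1
                    continue
                chain = _chain_from(
                    ref_name, chrom, i, orthoseqs, positions, assigned, max_gap
                )
                if chain and (best_chain is None or len(chain) > len(best_chain)):
                    best_chain = chain
                # jump past this chain's reference span to keep the scan linear
                i += max(1, len(chain) if chain else 1)
        if best_chain is None or len(best_chain) < min_block_len:
            break
        ogs = [og for og, _ in best_chain]
        for _, links in best_chain:
            for g, pos in links.items():
                assigned[g].add(pos)
        blocks.append(SyntenyBlock(block_id=block_id, og_sequence=ogs))
        block_id += 1

    for block in blocks:
        for g in genomes:
            block.occurrences[g] = find_block_occurrences(
                block.og_sequence, orthoseqs[g], max_gap=max_gap
            )
    return blocks


def find_block_occurrences(
    block_ogs: list[str],
    orthoseq: OrthoSeq,
    max_gap: int = 20,
    min_frac: float = 0.5,
) -> list[BlockOccurrence]:
    """Scan a genome for runs matching a block's orthogroup order.

    A run extends while consecutive members advance monotonically in the
    block (forward or reversed) with gaps <= ``max_gap`` in both the
    chromosome and the block; runs covering at least ``min_frac`` of the
    block count as occurrences.
    """
    want = {og: i for i, og in enumerate(block_ogs)}
    min_len = max(2, int(min_frac * len(block_ogs)))
    occs = []
    for chrom in sorted(orthoseq.chromosomes):
        entries = orthoseq.chromosomes[chrom]
        run: list[tuple[int, int]] = []  # (chrom idx, block idx)
        direction = 0

        def close():
            nonlocal run, direction
            if len(run) >= min_len:
                idxs = [ci for ci, _ in run]
                a, b = min(idxs), max(idxs)
                orientation = "-" if direction < 0 else "+"
                iv = Interval(chrom, entries[a][2].start, entries[b][2].end)
                occs.append(
                    BlockOccurrence(
                        chrom=chrom,
                        start_gene=entries[a][1],
                        end_gene=entries[b][1],
                        orientation=orientation,
                        interval=iv,
                    )
                )
            run = []
            direction = 0

        for ci, (og, _, _) in enumerate(entries):
            if og not in want:
                if run and ci - run[-1][0] > max_gap:
                    close()
                continue
            bi = want[og]
            if not run:
                run = [(ci, bi)]
                continue
            step = bi - run[-1][1]
            chrom_gap = ci - run[-1][0]
            dir_ok = (
                step != 0
                and abs(step) <= max_gap + 1
                and (direction == 0 or (step > 0) == (direction > 0))
            )
            if chrom_gap <= max_gap and dir_ok:
                if direction == 0:
                    direction = 1 if step > 0 else -1
                run.append((ci, bi))
            else:
                close()
                run = [(ci, bi)]
        close()
    return occs


def lcs_map_block(
    block_ogs: list[str], chrom_entries: list[tuple[str, str, Interval]]
) -> tuple[str, str, Interval]:
    """Anchor a block to gene coordinates via longest common subsequence.

    Classic LCS DP between the block's orthogroup-ID sequence and the
    chromosome's; the first and last matched genes give the block span.
    Among equal-length LCSs the leftmost-start, leftmost-end match on
    the chromosome is chosen.  Raises when the LCS is empty.
    """
    a = block_ogs
    b = [og for og, _, _ in chrom_entries]
    n, m = len(a), len(b)
    L = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        row, nxt = L[i], L[i + 1]
        ai = a[i]
        for j in range(m - 1, -1, -1):
            if ai == b[j]:
                row[j] = nxt[j + 1] + 1
            else:
                row[j] = max(nxt[j], row[j + 1])
    if L[0][0] == 0:
        raise ValueError("block has no occurrence on this chromosome (empty LCS)")

    matches = []
    i = j = 0
    while i < n and j < m:
        if a[i] == b[j] and L[i][j] == L[i + 1][j + 1] + 1:
            matches.append(j)
            i += 1
            j += 1
        elif L[i + 1][j] >= L[i][j + 1]:
            i += 1
        else:
            j += 1
    first, last = matches[0], matches[-1]
    start_gene = chrom_entries[first][1]
    end_gene = chrom_entries[last][1]
    chrom = chrom_entries[first][2].chrom
    iv = Interval(chrom, chrom_entries[first][2].start, chrom_entries[last][2].end)
    return start_gene, end_gene, iv


def lcs_length(a: list, b: list) -> int:
    """Length of the longest common subsequence of two sequences."""
    n, m = len(a), len(b)
    prev = [0] * (m + 1)
    for i in range(n):
        cur = [0] * (m + 1)
        ai = a[i]
        for j in range(m):
            cur[j + 1] = prev[j] + 1 if ai == b[j] else max(prev[j + 1], cur[j])
        prev = cur
    return prev[m]


def filter_blocks_by_copy(
    blocks: list[SyntenyBlock], targets: dict[str, int]
) -> list[SyntenyBlock]:
    """Keep blocks whose occurrence count equals the target copy number
    in every genome."""
    return [
        b
        for b in blocks
        if all(b.copy_number(g) == t for g, t in targets.items())
    ]


def _block_ends(signed_id: int) -> tuple[tuple[int, str], tuple[int, str]]:
    """(left end, right end) of a signed block in chromosome orientation."""
    if signed_id > 0:
        return (signed_id, "L"), (signed_id, "R")
    return (-signed_id, "R"), (-signed_id, "L")


def adjacencies(genome: BlockGenome) -> set[frozenset]:
    """Unordered pairs of oriented block ends adjacent on a chromosome;
    telomeric ends are not represented."""
    adj = set()
    for blocks in genome.chromosomes.values():
        for a, b in zip(blocks, blocks[1:]):
            adj.add(frozenset({_block_ends(a)[1], _block_ends(b)[0]}))
    return adj


def count_fission_fusion(
    ancestor: BlockGenome, descendant: BlockGenome
) -> EventSummary:
    """Count fissions (ancestor adjacencies cut) and fusions (descendant
    adjacencies formed) between two genomes with identical block content.

    Requires the descendant to be derivable by fissions and fusions only:
    every cut end must be telomeric in the descendant and every joined
    end telomeric in the ancestor; anything else raises
    :class:`UnsupportedRearrangementError`.
    """
    if ancestor.block_multiset() != descendant.block_multiset():
        raise ValueError("block multisets differ between genomes")
    a_adj = adjacencies(ancestor)
    d_adj = adjacencies(descendant)
    lost = a_adj - d_adj
    gained = d_adj - a_adj
    d_ends = {end for adj in d_adj for end in adj}
    a_ends = {end for adj in a_adj for end in adj}
    for adj in lost:
        for end in adj:
            if end in d_ends:
                raise UnsupportedRearrangementError(
                    f"cut end {end} re-used in descendant adjacency {adj}"
                )
    for adj in gained:
        for end in adj:
            if end in a_ends:
                raise UnsupportedRearrangementError(
                    f"joined end {end} was not telomeric in ancestor ({adj})"
                )
    return EventSummary(
        n_fissions=len(lost),
        n_fusions=len(gained),
        chromosomes_before=ancestor.n_chromosomes,
        chromosomes_after=descendant.n_chromosomes,
    )


def breakpoints_near_centromere(
    breakpoints: list[tuple[str, int]],
    centromere_arrays: list[Interval],
    window: int = 5_000_000,
) -> tuple[int, int, float]:
    """Fraction of breakpoints within ``window`` of a centromere array
    on their own chromosome."""
    if not breakpoints:
        raise ValueError("no breakpoints: fraction undefined")
    by_chrom: dict[str, list[Interval]] = {}
    for iv in centromere_arrays:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    n_near = 0
    for chrom, pos in breakpoints:
        for iv in by_chrom.get(chrom, []):
            if iv.start - window <= pos <= iv.end + window:
                n_near += 1
                break
    return n_near, len(breakpoints), n_near / len(breakpoints)


def assign_censat_by_synteny(
    ref_censat_arrays: list[Interval],
    blocks: list[SyntenyBlock],
    ref_genome: str,
    target_genome: str,
    candidate_arrays: dict[str, list[Interval]],
    unit_lengths: dict[str, int],
    flank_window: int = 2_000_000,
) -> dict[str, str | None]:
    """Predict each target chromosome's cenSat from peri-centromeric synteny.

    For every reference centromere array the nearest flanking synteny
    blocks (one per side) are mapped to the target genome; candidate
    satellites whose arrays fall between or near the mapped flanks
    (within ``flank_window``) are collected and, per target chromosome,
    the most abundant one (greatest copy number at the locus) wins.
    """
    ref_occs: list[tuple[Interval, SyntenyBlock]] = []
    tgt_occ_by_block: dict[int, list[BlockOccurrence]] = {}
    for block in blocks:
        for occ in block.occurrences.get(ref_genome, []):
            ref_occs.append((occ.interval, block))
        tgt_occ_by_block[block.block_id] = block.occurrences.get(target_genome, [])

    votes: dict[str, dict[str, int]] = {}
    for array in ref_censat_arrays:
        left = None
        right = None
        for iv, block in ref_occs:
            if iv.chrom != array.chrom:
                continue
            if iv.start <= array.start and iv.end >= array.end:
                # block genes bracket the array (no genes lie inside it):
                # the spanning block provides both flanks
                left = right = (iv, block)
                break
            if iv.end <= array.start and (left is None or iv.end > left[0].end):
                left = (iv, block)
            if iv.start >= array.end and (right is None or iv.start < right[0].start):
                right = (iv, block)
        if left is None or right is None:
            from .io_core import logger

            logger.warning(
                "reference array %s lacks flanking blocks; skipped", array
            )
            continue
        loci: dict[str, list[int]] = {}
        for _, block in (left, right):
            for occ in tgt_occ_by_block.get(block.block_id, []):
                loci.setdefault(occ.chrom, []).extend(
                    [occ.interval.start, occ.interval.end]
                )
        for chrom, coords in loci.items():
            lo = max(0, min(coords) - flank_window)
            hi = max(coords) + flank_window
            for sat, arrays in candidate_arrays.items():
                copies = 0
                for iv in arrays:
                    if iv.chrom == chrom and iv.start < hi and iv.end > lo:
                        copies += round(len(iv) / unit_lengths[sat])
                if copies:
                    votes.setdefault(chrom, {})
                    votes[chrom][sat] = votes[chrom].get(sat, 0) + copies

    predictions: dict[str, str | None] = {}
    all_target_chroms = {
        occ.chrom for occs in tgt_occ_by_block.values() for occ in occs
    }
    for chrom in sorted(all_target_chroms):
        if chrom in votes and votes[chrom]:
            predictions[chrom] = min(
                votes[chrom], key=lambda s: (-votes[chrom][s], s)
            )
        else:
            predictions[chrom] = None
    return predictions
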