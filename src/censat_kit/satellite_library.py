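"""Per-species satellite library construction.

Pipeline: validated tandem-repeat regions -> unit-vs-genome alignment ->
TR similarity network (edge when a unit's retained hit overlaps another
region) -> Louvain communities -> representative unit per community ->
AT-ranked naming -> cenSat candidate filter (total size > 1 Mb, AT > 60%).

The unit aligner is an exact-k-mer seed-and-extend scheme with edit
distance scoring; identity is 1 - edits / max(unit length, target span).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import networkx as nx
import numpy as np

from .io_core import GenomeSequences, Interval, reverse_complement
from .tr_annotation import TandemRepeatRegion, _kmer_hashes, encode_sequence


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    interval: Interval
    identity: float
    aligned_length: int
    strand: str


@dataclass
class SatelliteFamily:
    community_id: int
    member_region_ids: list[str]
    representative_region_id: str
    unit: str
    at_content: float
    hit_set: list[AlignmentHit] = field(default_factory=list)
    total_genomic_size: int = 0
    name: str = ""
    rank: int = 0


@dataclass
class SatelliteLibrary:
    species_abbrev: str
    families: list[SatelliteFamily]


def compute_at_content(sequence: str) -> float:
    """(A+T) / (A+C+G+T); N positions are excluded entirely."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    at = seq.count("A") + seq.count("T")
    acgt = at + seq.count("C") + seq.count("G")
    if acgt == 0:
        raise ValueError("sequence contains no A/C/G/T bases")
    return at / acgt


class GenomeKmerIndex:
    """Caches per-chromosome k-mer hash arrays for repeated unit queries."""

    def __init__(self, genome: GenomeSequences, k: int = 13):
        self.genome = genome
        self.k = k
        self._hashes = {
            chrom: _kmer_hashes(encode_sequence(seq), k)
            for chrom, seq in genome.items()
        }

    def seed_positions(self, chrom: str, unit_hashes: np.ndarray) -> np.ndarray:
        h = self._hashes[chrom]
        if len(h) == 0 or len(unit_hashes) == 0:
            return np.empty(0, dtype=np.int64)
        mask = np.isin(h, unit_hashes)
        return np.nonzero(mask)[0]


def align_unit_to_genome(
    unit: str,
    genome: GenomeSequences,
    min_identity: float = 0.8,
    min_length_frac: float = 0.8,
    k: int = 13,
    query_id: str = "unit",
    index: GenomeKmerIndex | None = None,
) -> list[AlignmentHit]:
    """Find genome-wide occurrences of a satellite unit on both strands.

    Exact k-mer seeds anchor candidate loci; each locus is scored by a
    banded semi-global (infix) alignment of the unit in a window around
    the seed.  Hits failing identity >= ``min_identity`` or span >=
    ``min_length_frac`` of the unit length are dropped; overlapping hits
    of the same strand are resolved keeping the higher identity.
    """
    unit = unit.upper()
    ulen = len(unit)
    if ulen < k:
        raise ValueError(f"unit length {ulen} shorter than seed size {k}")
    if index is None:
        index = GenomeKmerIndex(genome, k)
    elif index.k != k:
        raise ValueError("index seed size mismatch")

    queries = {
        "+": unit,
        "-": reverse_complement(unit),
    }
    # hash -> smallest offset of that k-mer within the query, per strand;
    # anchors each seed to the estimated start of the unit occurrence
    offset_maps: dict[str, dict[int, int]] = {}
    hash_sets: dict[str, np.ndarray] = {}
    for strand, q in queries.items():
        qh = _kmer_hashes(encode_sequence(q), k)
        omap: dict[int, int] = {}
        for off, h in enumerate(qh):
            if h >= 0 and int(h) not in omap:
                omap[int(h)] = off
        offset_maps[strand] = omap
        hash_sets[strand] = np.unique(qh[qh >= 0])
    pad = max(8, ulen // 5)

    hits: list[AlignmentHit] = []
    for chrom, seq in genome.items():
        clen = len(seq)
        chrom_hashes = index._hashes[chrom]
        for strand, q in queries.items():
            omap = offset_maps[strand]
            positions = index.seed_positions(chrom, hash_sets[strand])
            i = 0
            last_end = -1
            while i < len(positions):
                p = int(positions[i])
                est = max(0, p - omap[int(chrom_hashes[p])])
                if est < last_end - 2:
                    i += 1
                    continue
                wstart = max(0, est - pad)
                wend = min(clen, est + ulen + pad)
                res = edlib.align(q, seq[wstart:wend], mode="HW", task="locations")
                dist = res["editDistance"]
                loc = res["locations"][0]
                hstart = wstart + loc[0]
                hend = wstart + loc[1] + 1
                span = hend - hstart
                identity = 1.0 - dist / max(ulen, span)
                if identity >= min_identity and span >= min_length_frac * ulen:
                    hits.append(
                        AlignmentHit(
                            query_id=query_id,
                            interval=Interval(chrom, hstart, hend, strand),
                            identity=identity,
                            aligned_length=span,
                            strand=strand,
                        )
                    )
                    last_end = hend
                    i = max(i + 1, int(np.searchsorted(positions, hend)))
                else:
                    # seeds are sparse outside true loci (they need an
                    # exact k-mer match), so stepping one seed is cheap
                    i += 1
    return _dedupe_hits(hits)


def _dedupe_hits(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Resolve same-strand, same-locus duplicate hits, keeping the higher
    identity.  Hits count as duplicates when they overlap by more than
    half the shorter hit; adjacent tiling hits that merely share a
    boundary base are both kept."""
    out: list[AlignmentHit] = []
    by_key: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in hits:
        by_key.setdefault((h.interval.chrom, h.strand), []).append(h)
    import bisect

    for group in by_key.values():
        group.sort(key=lambda h: (-h.identity, h.interval.start))
        starts: list[int] = []  # starts of kept, non-overlapping intervals
        kept: list[AlignmentHit] = []
        def duplicates(a: AlignmentHit, b: AlignmentHit) -> bool:
            ov = a.interval.overlap(b.interval)
            return ov > 0.5 * min(len(a.interval), len(b.interval))

        for h in group:
            i = bisect.bisect_right(starts, h.interval.start)
            clash = False
            for j in (i - 1, i):
                if 0 <= j < len(kept) and duplicates(kept[j], h):
                    clash = True
            if not clash:
                starts.insert(i, h.interval.start)
                kept.insert(i, h)
        out.extend(kept)
    out.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.strand))
    return out


def merge_hit_intervals(hits: list[AlignmentHit]) -> list[Interval]:
    """Merge hit intervals (strand-agnostic) into non-overlapping spans."""
    by_chrom: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.interval.chrom, []).append(h)
    merged = []
    for chrom in sorted(by_chrom):
        ivs = sorted((h.interval.start, h.interval.end) for h in by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append(Interval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append(Interval(chrom, cur_s, cur_e))
    return merged


def build_tr_network(
    regions: list[TandemRepeatRegion],
    genome: GenomeSequences,
    min_identity: float = 0.8,
    min_length_frac: float = 0.8,
    k: int = 13,
    return_hits: bool = False,
):
    """TR similarity network: node per region; edge {TR1, TR2} when a
    retained genome-wide hit of TR1's unit overlaps TR2's interval
    (>= 1 bp), in either direction.  Self-loops are never added.

    With ``return_hits`` the per-region genome-wide hit lists are also
    returned so later stages can reuse them.
    """
    graph = nx.Graph()
    for r in sorted(regions, key=lambda r: r.region_id):
        graph.add_node(r.region_id)

    # region lookup arrays per chromosome
    by_chrom: dict[str, list[TandemRepeatRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.interval.chrom, []).append(r)
    lookup = {}
    for chrom, rs in by_chrom.items():
        rs.sort(key=lambda r: r.interval.start)
        starts = np.array([r.interval.start for r in rs])
        ends = np.array([r.interval.end for r in rs])
        lookup[chrom] = (starts, ends, rs)

    index = GenomeKmerIndex(genome, k)
    hits_by_region: dict[str, list[AlignmentHit]] = {}
    for r in sorted(regions, key=lambda r: r.region_id):
        hits = align_unit_to_genome(
            r.cruseq,
            genome,
            min_identity=min_identity,
            min_length_frac=min_length_frac,
            k=k,
            query_id=r.region_id,
            index=index,
        )
        hits_by_region[r.region_id] = hits
        for h in hits:
            if h.interval.chrom not in lookup:
                continue
            starts, ends, rs = lookup[h.interval.chrom]
            lo = int(np.searchsorted(ends, h.interval.start, side="right"))
            hi = int(np.searchsorted(starts, h.interval.end, side="left"))
            for other in rs[lo:hi]:
                if other.region_id != r.region_id:
                    graph.add_edge(r.region_id, other.region_id)
    if return_hits:
        return graph, hits_by_region
    return graph


def detect_communities(
    graph: nx.Graph, resolution: float = 1.0, seed: int = 42
) -> list[set]:
    """Louvain modularity communities with a fixed seed and canonical
    (sorted) node order; isolated nodes become singleton communities."""
    canonical = nx.Graph()
    canonical.add_nodes_from(sorted(graph.nodes))
    canonical.add_edges_from(sorted(tuple(sorted(e)) for e in graph.edges))
    communities = nx.community.louvain_communities(
        canonical, resolution=resolution, seed=seed
    )
    return sorted((set(c) for c in communities), key=lambda c: sorted(c)[0])


def select_representative(
    community: set, graph: nx.Graph, region_lengths: dict[str, int] | None = None
) -> str:
    """Member with the maximum degree; ties broken by longer region
    length, then lexicographically smallest id."""
    if not community:
        raise ValueError("empty community")
    region_lengths = region_lengths or {}

    def key(node):
        return (-graph.degree(node), -region_lengths.get(node, 0), node)

    return min(community, key=key)


def rank_and_name(
    families: list[SatelliteFamily], species_abbrev: str
) -> SatelliteLibrary:
    """Sort families by AT content (descending; ties by total size then
    unit length) and name them ``abbrev + unit_length + "S" + rank``."""
    ordered = sorted(
        families,
        key=lambda f: (-f.at_content, -f.total_genomic_size, -len(f.unit)),
    )
    for rank, fam in enumerate(ordered, 1):
        fam.rank = rank
        fam.name = f"{species_abbrev}{len(fam.unit)}S{rank}"
    return SatelliteLibrary(species_abbrev=species_abbrev, families=ordered)


def filter_censat_candidates(
    library: SatelliteLibrary,
    min_total_size: int = 1_000_000,
    min_at: float = 0.6,
) -> SatelliteLibrary:
    """Candidate cenSats: total genomic size > 1 Mb and AT content > 60%
    (both strict); original names and ranks are retained."""
    kept = [
        f
        for f in library.families
        if f.total_genomic_size > min_total_size and f.at_content > min_at
    ]
    return SatelliteLibrary(species_abbrev=library.species_abbrev, families=kept)


def build_library(
    regions: list[TandemRepeatRegion],
    genome: GenomeSequences,
    species_abbrev: str,
    resolution: float = 1.0,
    seed: int = 42,
    k: int = 13,
) -> SatelliteLibrary:
    """Assemble the satellite library from validated TR regions."""
    graph, hits_by_region = build_tr_network(regions, genome, k=k, return_hits=True)
    communities = detect_communities(graph, resolution=resolution, seed=seed)
    region_by_id = {r.region_id: r for r in regions}
    region_lengths = {r.region_id: len(r.interval) for r in regions}

    families = []
    for cid, community in enumerate(communities):
        rep_id = select_representative(community, graph, region_lengths)
        unit = region_by_id[rep_id].cruseq
        hits = hits_by_region[rep_id]
        merged = merge_hit_intervals(hits)
        families.append(
            SatelliteFamily(
                community_id=cid,
                member_region_ids=sorted(community),
                representative_region_id=rep_id,
                unit=unit,
                at_content=compute_at_content(unit),
                hit_set=hits,
                total_genomic_size=sum(len(iv) for iv in merged),
            )
        )
    return rank_and_name(families, species_abbrev)


def canonical_unit(unit: str) -> str:
    """Lexicographically minimal rotation over both strands.

    Tandem units have arbitrary phase and strand; this canonical form is
    used when scoring recovery of planted monomers, never for naming.
    """
    unit = unit.upper()
    best = None
    for s in (unit, reverse_complement(unit)):
        for i in range(len(s)):
            rot = s[i:] + s[:i]
            if best is None or rot < best:
                best = rot
    return best


def unit_identity(a: str, b: str) -> float:
    """Best identity between two units over all rotations and strands."""
    a, b = a.upper(), b.upper()
    if len(a) > len(b):
        a, b = b, a
    best = 0.0
    for s in (b, reverse_complement(b)):
        doubled = s + s
        res = edlib.align(a, doubled, mode="HW", task="distance")
        ident = 1.0 - res["editDistance"] / len(a)
        best = max(best, ident)
    return min(1.0, best)
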