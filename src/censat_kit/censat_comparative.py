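"""Cross-species centromere-satellite comparison and evolution trajectories.

Satellite units are queried genome-wide in every species; co-located hit
regions link satellites into a cross-species similarity network whose
Louvain communities group homologous families.  Copy-number bookkeeping
classifies each satellite per species/subgenome as absent, seeded (trace
copies), or amplified, and a Sankoff parsimony pass over the species or
subgenome tree reconstructs where amplification events occurred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from .io_core import GenomeSequences, Interval
from .satellite_library import (
    AlignmentHit,
    GenomeKmerIndex,
    align_unit_to_genome,
    detect_communities,
    merge_hit_intervals,
)

STATES = ("absent", "seeded", "amplified")

#: unit transition costs: direct absent<->amplified costs 2 (via seeding)
DEFAULT_COSTS = {
    (a, b): 0 if a == b else (2 if {a, b} == {"absent", "amplified"} else 1)
    for a in STATES
    for b in STATES
}


@dataclass
class SatelliteHitSet:
    """Genome-wide filtered hit regions of one satellite (its Sat_R set)."""

    satellite_id: str
    hits: dict[str, list[AlignmentHit]] = field(default_factory=dict)
    arrays: dict[str, list[Interval]] = field(default_factory=dict)


@dataclass
class CenSatCommunity:
    community_id: int
    members: list[str]
    representative: str
    is_representative_censat: bool = False


@dataclass
class TrajectoryState:
    states: dict[str, str]
    events: list[tuple[str, str, str]]  # (parent node, child node, event)
    total_cost: float


def genome_wide_hits(
    unit: str,
    genomes: dict[str, GenomeSequences],
    min_identity: float = 0.8,
    min_length_frac: float = 0.8,
    satellite_id: str = "sat",
    indexes: dict[str, GenomeKmerIndex] | None = None,
) -> SatelliteHitSet:
    """Query a satellite unit in every genome, merging hits per chromosome."""
    hit_set = SatelliteHitSet(satellite_id=satellite_id)
    for species in sorted(genomes):
        hits = align_unit_to_genome(
            unit,
            genomes[species],
            min_identity=min_identity,
            min_length_frac=min_length_frac,
            query_id=satellite_id,
            index=indexes.get(species) if indexes else None,
        )
        hit_set.hits[species] = hits
        hit_set.arrays[species] = merge_hit_intervals(hits) if hits else []
    return hit_set


def merge_adjacent_hits(
    intervals: list[Interval], max_gap: int = 5000, min_merged_len: int = 5000
) -> list[Interval]:
    """Merge same-chromosome intervals closer than ``max_gap`` and drop
    merged arrays shorter than ``min_merged_len``."""
    by_chrom: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = []
    for chrom in sorted(by_chrom):
        ivs = sorted((iv.start, iv.end) for iv in by_chrom[chrom])
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s - merged[-1][1] < max_gap:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            if e - s >= min_merged_len:
                out.append(Interval(chrom, s, e))
    return out


def count_copies(
    unit_length: int, arrays: list[Interval]
) -> tuple[dict[str, int], int]:
    """Per-chromosome and total copy numbers: round(array length / unit)."""
    if unit_length <= 0:
        raise ValueError("unit length must be positive")
    per_chrom: dict[str, int] = {}
    for iv in arrays:
        per_chrom[iv.chrom] = per_chrom.get(iv.chrom, 0) + round(len(iv) / unit_length)
    return per_chrom, sum(per_chrom.values())


def build_cross_species_network(
    hit_sets: dict[str, SatelliteHitSet], min_reciprocal_overlap: float = 0.8
) -> nx.Graph:
    """Edge {Sat_i, Sat_j} when some region of Sat_Ri and some region of
    Sat_Rj on the same genome and chromosome reciprocally overlap by at
    least ``min_reciprocal_overlap`` of the shorter region.  Hit regions
    are assumed already identity-filtered at generation time.
    """
    graph = nx.Graph()
    ids = sorted(hit_sets)
    graph.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if _hit_sets_colocate(hit_sets[a], hit_sets[b], min_reciprocal_overlap):
                graph.add_edge(a, b)
    return graph


def _hit_sets_colocate(
    a: SatelliteHitSet, b: SatelliteHitSet, frac: float
) -> bool:
    for species in set(a.arrays) & set(b.arrays):
        for iva in a.arrays[species]:
            for ivb in b.arrays[species]:
                ov = iva.overlap(ivb)
                if ov and ov >= frac * min(len(iva), len(ivb)):
                    return True
    return False


def designate_representative_censats(
    communities: list[set],
    copy_counts: dict[str, dict[tuple[str, str], int]],
    min_copies: int = 1000,
) -> list[CenSatCommunity]:
    """Flag communities substantively detected (copy number > ``min_copies``)
    on >= 2 chromosomes or in >= 2 species.

    ``copy_counts`` maps satellite id -> {(species, chrom): copies}.
    """
    out = []
    for cid, community in enumerate(sorted(communities, key=lambda c: sorted(c)[0])):
        chrom_hits: set[tuple[str, str]] = set()
        species_totals: dict[str, int] = {}
        for sat in community:
            for (species, chrom), copies in copy_counts.get(sat, {}).items():
                if copies > min_copies:
                    chrom_hits.add((species, chrom))
                species_totals[species] = species_totals.get(species, 0) + copies
        n_species = sum(1 for tot in species_totals.values() if tot > min_copies)
        flagged = len(chrom_hits) >= 2 or n_species >= 2
        members = sorted(community)
        out.append(
            CenSatCommunity(
                community_id=cid,
                members=members,
                representative=members[0],
                is_representative_censat=flagged,
            )
        )
    return out


def classify_amplification(
    per_chrom_copies: dict[str, int],
    chromosome_set: list[str],
    per_chrom_threshold: int = 1000,
    majority: float = 0.5,
) -> tuple[str, bool]:
    """Classify one satellite over a species' (or subgenome's) chromosomes.

    Per chromosome: amplified when copies > threshold; seeded when
    1 <= copies <= threshold; absent otherwise.  The satellite is
    amplified (and flagged potential-functional) when amplified on more
    than ``majority`` of the chromosome set, seeded when present
    anywhere, absent otherwise.
    """
    if not chromosome_set:
        raise ValueError("empty chromosome set")
    n_amp = 0
    n_present = 0
    for chrom in chromosome_set:
        copies = per_chrom_copies.get(chrom, 0)
        if copies > per_chrom_threshold:
            n_amp += 1
            n_present += 1
        elif copies >= 1:
            n_present += 1
    if n_amp > majority * len(chromosome_set):
        return "amplified", True
    if n_present > 0:
        return "seeded", False
    return "absent", False


def _clade_ids(tree):
    """Name internal clades deterministically; return (children, leaves)."""
    counter = [0]
    children: dict[str, list[str]] = {}
    names: dict[int, str] = {}

    def visit(clade):
        if clade.is_terminal():
            names[id(clade)] = clade.name
            return clade.name
        kids = [visit(c) for c in clade.clades]
        name = clade.name or f"node{counter[0]}"
        counter[0] += 1
        names[id(clade)] = name
        children[name] = kids
        return name

    root = visit(tree.root)
    return root, children


_EVENT_NAMES = {
    ("absent", "seeded"): "seeding",
    ("seeded", "amplified"): "amplification",
    ("amplified", "seeded"): "deamplification",
    ("seeded", "absent"): "loss",
    ("absent", "amplified"): "seeding+amplification",
    ("amplified", "absent"): "loss",
}


def infer_trajectory(
    tree,
    leaf_states: dict[str, str],
    costs: dict[tuple[str, str], float] | None = None,
) -> TrajectoryState:
    """Sankoff parsimony over {absent, seeded, amplified} for one satellite.

    Ties in ancestral assignment are resolved toward the parent's state,
    then toward "seeded", then alphabetically; branch events are emitted
    wherever parent and child states differ.  Total cost is the minimum
    over all ancestral assignments.
    """
    costs = costs or DEFAULT_COSTS
    root, children = _clade_ids(tree)
    leaves = {name for name in _iter_nodes(root, children) if name not in children}
    missing = leaves - set(leaf_states)
    if missing:
        raise ValueError(f"leaf states missing for {sorted(missing)}")
    bad = {s for s in leaf_states.values() if s not in STATES}
    if bad:
        raise ValueError(f"unknown states {sorted(bad)}")

    inf = math.inf
    score: dict[str, dict[str, float]] = {}

    def up(node: str) -> None:
        if node not in children:
            score[node] = {
                s: 0.0 if s == leaf_states[node] else inf for s in STATES
            }
            return
        for child in children[node]:
            up(child)
        score[node] = {
            s: sum(
                min(costs[(s, t)] + score[c][t] for t in STATES)
                for c in children[node]
            )
            for s in STATES
        }

    up(root)

    def prefer(options: list[str], parent: str | None) -> str:
        def key(s):
            return (s != parent, s != "seeded", s)

        return min(options, key=key)

    states: dict[str, str] = {}
    best = min(score[root].values())
    states[root] = prefer([s for s in STATES if score[root][s] == best], None)

    events: list[tuple[str, str, str]] = []

    def down(node: str) -> None:
        if node not in children:
            return
        p = states[node]
        for child in children[node]:
            vals = {t: costs[(p, t)] + score[child][t] for t in STATES}
            m = min(vals.values())
            states[child] = prefer([t for t in STATES if vals[t] == m], p)
            if states[child] != p:
                events.append((node, child, _EVENT_NAMES[(p, states[child])]))
            down(child)

    down(root)
    return TrajectoryState(states=states, events=events, total_cost=best)


def _iter_nodes(root: str, children: dict[str, list[str]]):
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(children.get(node, []))
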