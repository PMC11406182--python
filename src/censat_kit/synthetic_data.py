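"""Synthetic multi-species genomes with known ground truth.

The generator emulates the statistical structure the analysis assumes:
AT-rich satellite arrays built from monomer templates with point
mutations, multiple species sharing diverged copies of the same
ancestral families, i.i.d. background sequence at a chosen GC, telomere
motif runs at chromosome ends, orthogroup gene orders related by
fission/fusion/translocation events, Poisson ChIP/input coverage with
planted enrichment over arrays, and error-free uniform reads.

Determinism: a single global seed; per-component seeds derived by stable
hashing of (seed, component name).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .io_core import GeneRecord, GenomeSequences, Interval, reverse_complement
from .quant_utils import CoverageTrack
from .synteny_karyotype import BlockGenome

TELOMERE_MOTIF = "CCCTGAA"
BASES = np.array(list("ACGT"))


def derive_seed(seed: int, component: str) -> int:
    """Stable per-component sub-seed (< 2**31) from the global seed."""
    digest = hashlib.sha256(f"{seed}:{component}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class SatelliteSpec:
    """Template parameters for one satellite family."""

    family_id: str
    monomer_length: int = 168
    at_content: float = 0.65
    mutation_rate: float = 0.05
    copies_per_array: int = 500

    def __post_init__(self):
        if self.monomer_length < 20:
            raise ValueError("monomer_length must be >= 20")
        if not 0.0 <= self.mutation_rate <= 0.3:
            raise ValueError("mutation_rate must be in [0, 0.3]")
        if not 0.0 <= self.at_content <= 1.0:
            raise ValueError("at_content must be in [0, 1]")


@dataclass
class BackgroundElement:
    length: int
    at_content: float = 0.5
    orthogroups: list[str] = field(default_factory=list)
    gene_length: int = 300
    kind: str = "background"


@dataclass
class ArrayElement:
    family_id: str
    copies: int
    layer: int = 0
    kind: str = "array"


@dataclass
class TelomereElement:
    copies: int = 20
    motif: str = TELOMERE_MOTIF
    kind: str = "telomere"


@dataclass
class ChromosomeSpec:
    name: str
    elements: list


@dataclass
class SimTruth:
    """Ground truth sufficient to score every downstream stage."""

    species: str
    arrays: list[tuple[Interval, str]] = field(default_factory=list)
    monomers: list[tuple[Interval, str]] = field(default_factory=list)
    gene_orders: dict[str, list[str]] = field(default_factory=dict)
    telomeres: list[tuple[str, str]] = field(default_factory=list)
    genome_size: int = 0
    enrichment: float = 1.0
    event_log: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        def enc(obj):
            if isinstance(obj, Interval):
                return [obj.chrom, obj.start, obj.end, obj.strand]
            raise TypeError(type(obj))

        return json.dumps(asdict(self), default=enc, indent=1)


def make_monomer(length: int, at_content: float, seed: int) -> str:
    """Random monomer with the requested AT fraction (in expectation)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= at_content <= 1.0:
        raise ValueError("at_content must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [at_content / 2, (1 - at_content) / 2, (1 - at_content) / 2, at_content / 2]
    return "".join(rng.choice(BASES, size=length, p=p))


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each position independently with probability ``rate``."""
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    n = int(hit.sum())
    if n:
        # draw a base different from the current one at each hit
        current = arr[hit]
        repl = BASES[rng.integers(0, 3, size=n)]
        same = repl == current
        while same.any():
            repl[same] = BASES[rng.integers(0, 3, size=int(same.sum()))]
            same = repl == current
        arr[hit] = repl
    return "".join(arr)


def diverge_monomer(template: str, n_subs: int, rng: np.random.Generator) -> str:
    """Apply exactly ``n_subs`` substitutions at distinct positions."""
    if n_subs == 0:
        return template
    arr = np.array(list(template))
    pos = rng.choice(len(arr), size=min(n_subs, len(arr)), replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_array(
    spec: SatelliteSpec,
    copies: int,
    seed: int,
    template: str | None = None,
) -> tuple[str, list[tuple[int, int]]]:
    """Concatenate independently mutated monomer copies.

    Returns the array sequence and monomer truth intervals relative to
    the array start.
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    rng = np.random.default_rng(seed)
    if template is None:
        template = make_monomer(
            spec.monomer_length, spec.at_content, derive_seed(seed, spec.family_id)
        )
    pieces = []
    intervals = []
    offset = 0
    for _ in range(copies):
        copy = mutate_sequence(template, spec.mutation_rate, rng)
        pieces.append(copy)
        intervals.append((offset, offset + len(copy)))
        offset += len(copy)
    return "".join(pieces), intervals


def random_background(length: int, at_content: float, rng: np.random.Generator) -> str:
    p = [at_content / 2, (1 - at_content) / 2, (1 - at_content) / 2, at_content / 2]
    return "".join(rng.choice(BASES, size=length, p=p))


def simulate_species(
    chrom_specs: list[ChromosomeSpec],
    seed: int,
    family_monomers: dict[str, str] | None = None,
    family_specs: dict[str, SatelliteSpec] | None = None,
    species: str = "sp",
) -> tuple[GenomeSequences, list[GeneRecord], SimTruth]:
    """Build a genome from chromosome specs with full ground truth.

    ``family_monomers`` supplies per-family monomer templates (e.g.
    species-diverged copies of ancestral monomers); missing templates
    are drawn from the family spec.
    """
    family_specs = family_specs or {}
    family_monomers = dict(family_monomers or {})
    genome = GenomeSequences()
    genes: list[GeneRecord] = []
    truth = SimTruth(species=species)
    gene_counter = 0

    for cs in chrom_specs:
        rng = np.random.default_rng(derive_seed(seed, f"{species}:{cs.name}"))
        pieces = []
        offset = 0
        order: list[str] = []
        for el in cs.elements:
            if isinstance(el, BackgroundElement):
                seq = random_background(el.length, el.at_content, rng)
                if el.orthogroups:
                    n = len(el.orthogroups)
                    gap = el.length // (n + 1)
                    if gap <= el.gene_length:
                        raise ValueError(
                            f"{cs.name}: background too short for {n} genes"
                        )
                    for gi, og in enumerate(el.orthogroups):
                        gstart = offset + (gi + 1) * gap
                        gene_id = f"{species}_g{gene_counter:05d}"
                        gene_counter += 1
                        genes.append(
                            GeneRecord(
                                gene_id,
                                Interval(cs.name, gstart, gstart + el.gene_length),
                                og,
                            )
                        )
                        order.append(gene_id)
                pieces.append(seq)
                offset += el.length
            elif isinstance(el, ArrayElement):
                spec = family_specs.get(el.family_id) or SatelliteSpec(el.family_id)
                template = family_monomers.get(el.family_id)
                aseed = derive_seed(seed, f"{species}:{cs.name}:{el.family_id}:{offset}")
                seq, monomers = simulate_array(spec, el.copies, aseed, template)
                iv = Interval(cs.name, offset, offset + len(seq))
                truth.arrays.append((iv, el.family_id))
                for ms, me in monomers:
                    truth.monomers.append(
                        (Interval(cs.name, offset + ms, offset + me), el.family_id)
                    )
                pieces.append(seq)
                offset += len(seq)
            elif isinstance(el, TelomereElement):
                seq = el.motif * el.copies
                end_label = "start" if offset == 0 else "end"
                truth.telomeres.append((cs.name, end_label))
                pieces.append(seq)
                offset += len(seq)
            else:
                raise ValueError(f"unknown chromosome element {el!r}")
        genome.add(cs.name, "".join(pieces))
        truth.gene_orders[cs.name] = order
    truth.genome_size = genome.total_size
    return genome, genes, truth


def evolve_family_monomers(
    tree, template: str, per_branch_subs: int, seed: int
) -> dict[str, str]:
    """Evolve one ancestral monomer along a tree; returns leaf monomers.

    Each branch applies ``per_branch_subs`` substitutions (scaled by
    branch length when present), giving cross-species satellite networks
    a planted community structure.
    """
    out: dict[str, str] = {}

    def visit(clade, current: str, path: str):
        for i, child in enumerate(clade.clades):
            scale = child.branch_length if child.branch_length else 1.0
            rng = np.random.default_rng(derive_seed(seed, f"{path}/{i}"))
            evolved = diverge_monomer(
                current, max(1, round(per_branch_subs * scale)), rng
            )
            if child.is_terminal():
                out[child.name] = evolved
            else:
                visit(child, evolved, f"{path}/{i}")

    visit(tree.root, template, "root")
    if not out:  # single-leaf tree
        for leaf in tree.get_terminals():
            out[leaf.name] = template
    return out


# ---------------------------------------------------------------------------
# karyotype rearrangements


@dataclass
class Fission:
    chrom: str
    after_index: int  # cut between blocks[after_index] and blocks[after_index+1]
    kind: str = "fission"


@dataclass
class Fusion:
    chrom_a: str
    end_a: str  # "start" | "end"
    chrom_b: str
    end_b: str
    kind: str = "fusion"


@dataclass
class Translocation:
    """Reciprocal exchange of chromosome arms at two breakpoints."""

    chrom_a: str
    index_a: int
    chrom_b: str
    index_b: int
    kind: str = "translocation"


def apply_rearrangements(
    block_genome: BlockGenome, events: list
) -> tuple[BlockGenome, list[dict]]:
    """Apply fission/fusion/translocation events to a block genome.

    Chromosome count changes by +1 per fission, -1 per fusion, 0 per
    translocation; the block multiset is conserved.  Returns the new
    genome and an event log with breakpoints.
    """
    chroms = {name: list(blocks) for name, blocks in block_genome.chromosomes.items()}
    log = []
    fission_n = 0
    for ev in events:
        if isinstance(ev, Fission):
            if ev.chrom not in chroms:
                raise ValueError(f"fission references unknown chromosome {ev.chrom!r}")
            blocks = chroms.pop(ev.chrom)
            if not 0 <= ev.after_index < len(blocks) - 1:
                raise ValueError(
                    f"fission breakpoint {ev.after_index} invalid for {ev.chrom!r}"
                )
            fission_n += 1
            left, right = blocks[: ev.after_index + 1], blocks[ev.after_index + 1 :]
            na, nb = f"{ev.chrom}.1", f"{ev.chrom}.2"
            chroms[na], chroms[nb] = left, right
            log.append(
                {
                    "type": "fission",
                    "chrom": ev.chrom,
                    "breakpoint": (left[-1], right[0]),
                    "products": [na, nb],
                }
            )
        elif isinstance(ev, Fusion):
            for c in (ev.chrom_a, ev.chrom_b):
                if c not in chroms:
                    raise ValueError(f"fusion references unknown chromosome {c!r}")
            if ev.chrom_a == ev.chrom_b:
                raise ValueError("cannot fuse a chromosome with itself")
            a = chroms.pop(ev.chrom_a)
            b = chroms.pop(ev.chrom_b)
            if ev.end_a == "start":
                a = [-x for x in reversed(a)]
            if ev.end_b == "end":
                b = [-x for x in reversed(b)]
            name = f"{ev.chrom_a}+{ev.chrom_b}"
            chroms[name] = a + b
            log.append(
                {
                    "type": "fusion",
                    "chroms": [ev.chrom_a, ev.chrom_b],
                    "joint": (a[-1], b[0]),
                    "product": name,
                }
            )
        elif isinstance(ev, Translocation):
            for c, idx in ((ev.chrom_a, ev.index_a), (ev.chrom_b, ev.index_b)):
                if c not in chroms:
                    raise ValueError(f"translocation references unknown {c!r}")
                if not 0 < idx < len(chroms[c]):
                    raise ValueError(f"translocation breakpoint {idx} invalid for {c!r}")
            a, b = chroms[ev.chrom_a], chroms[ev.chrom_b]
            chroms[ev.chrom_a] = a[: ev.index_a] + b[ev.index_b :]
            chroms[ev.chrom_b] = b[: ev.index_b] + a[ev.index_a :]
            log.append(
                {
                    "type": "translocation",
                    "chroms": [ev.chrom_a, ev.chrom_b],
                    "breakpoints": [ev.index_a, ev.index_b],
                }
            )
        else:
            raise ValueError(f"unknown event {ev!r}")
    return BlockGenome(chromosomes=dict(sorted(chroms.items()))), log


def random_fission_fusion_log(
    block_genome: BlockGenome,
    n_fissions: int,
    n_fusions: int,
    seed: int,
) -> tuple[BlockGenome, list]:
    """Random fission/fusion event list without breakpoint reuse.

    Fissions cut only ancestral adjacencies; fusions join only ends that
    were already telomeric in the ancestor, so planted counts are exactly
    recoverable from adjacency differences.
    """
    rng = np.random.default_rng(seed)
    genome = BlockGenome(
        chromosomes={k: list(v) for k, v in block_genome.chromosomes.items()}
    )
    # ends telomeric in the ancestor, usable for fusion
    fusable: dict[str, set[str]] = {c: {"start", "end"} for c in genome.chromosomes}
    events: list = []

    for _ in range(n_fissions):
        candidates = [
            c for c, blocks in genome.chromosomes.items()
            if len(blocks) >= 2 and "." not in c
        ]
        if not candidates:
            break
        chrom = candidates[rng.integers(len(candidates))]
        idx = int(rng.integers(0, len(genome.chromosomes[chrom]) - 1))
        ev = Fission(chrom, idx)
        genome, _ = apply_rearrangements(genome, [ev])
        events.append(ev)
        # fission products: outer ends keep ancestral-telomere status
        na, nb = f"{chrom}.1", f"{chrom}.2"
        old = fusable.pop(chrom, set())
        fusable[na] = {"start"} if "start" in old else set()
        fusable[nb] = {"end"} if "end" in old else set()

    for _ in range(n_fusions):
        ends = [
            (c, e) for c, es in fusable.items() for e in es if c in genome.chromosomes
        ]
        if len(ends) < 2:
            break
        i = int(rng.integers(len(ends)))
        ca, ea = ends[i]
        partners = [(c, e) for c, e in ends if c != ca]
        if not partners:
            break
        cb, eb = partners[int(rng.integers(len(partners)))]
        ev = Fusion(ca, ea, cb, eb)
        genome, _ = apply_rearrangements(genome, [ev])
        events.append(ev)
        name = f"{ca}+{cb}"
        sa = fusable.pop(ca, set())
        sb = fusable.pop(cb, set())
        # after fusion, the outward-facing ends remain ancestral telomeres
        new = set()
        if ("end" if ea == "start" else "start") in sa:
            new.add("start")
        if ("start" if eb == "end" else "end") in sb:
            new.add("end")
        fusable[name] = new
    return genome, events


# ---------------------------------------------------------------------------
# coverage tracks and reads


def simulate_chip_tracks(
    array_intervals: list[Interval],
    chrom_lengths: dict[str, int],
    enrichment: float,
    depth: float = 100.0,
    bin_width: int = 20000,
    seed: int = 0,
) -> tuple[CoverageTrack, CoverageTrack]:
    """Poisson ChIP and input tracks with planted enrichment over arrays.

    Input bins are Poisson(depth) everywhere; ChIP bins are
    Poisson(depth * enrichment) in bins at least half-covered by a truth
    array and Poisson(depth) elsewhere.
    """
    if enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    rng = np.random.default_rng(seed)
    chip = CoverageTrack(bin_width=bin_width)
    inp = CoverageTrack(bin_width=bin_width)
    by_chrom: dict[str, list[Interval]] = {}
    for iv in array_intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(chrom_lengths):
        n_bins = max(1, chrom_lengths[chrom] // bin_width)
        lam = np.full(n_bins, depth)
        for iv in by_chrom.get(chrom, []):
            for b in range(n_bins):
                lo, hi = b * bin_width, (b + 1) * bin_width
                ov = max(0, min(hi, iv.end) - max(lo, iv.start))
                if ov * 2 >= bin_width:
                    lam[b] = depth * enrichment
        chip.values[chrom] = rng.poisson(lam).astype(float)
        inp.values[chrom] = rng.poisson(np.full(n_bins, depth)).astype(float)
    return chip, inp


def simulate_reads(
    genome: GenomeSequences,
    depth: float,
    read_length: int,
    seed: int,
) -> dict[str, str]:
    """Error-free reads at uniform positions totalling depth x genome size."""
    shortest = min(len(s) for s in genome.values())
    if read_length > shortest:
        raise ValueError("read_length exceeds shortest chromosome")
    rng = np.random.default_rng(seed)
    gsize = genome.total_size
    n_reads = round(depth * gsize / read_length)
    chroms = sorted(genome)
    weights = np.array([len(genome[c]) - read_length + 1 for c in chroms], dtype=float)
    weights /= weights.sum()
    picks = rng.choice(len(chroms), size=n_reads, p=weights)
    reads: dict[str, str] = {}
    for i in range(n_reads):
        chrom = chroms[picks[i]]
        start = int(rng.integers(0, len(genome[chrom]) - read_length + 1))
        seq = genome[chrom][start : start + read_length]
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        reads[f"read{i:07d}"] = seq
    return reads
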