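"""Readers/writers and shared domain containers.

All coordinates are 0-based half-open internally.  Formats that use
1-based inclusive coordinates (TRF ``.dat``, the gene table convention
of some exporters) are converted at parse time so nothing downstream
ever sees a 1-based number.
"""

from __future__ import annotations

import io
import logging
import sys
from dataclasses import dataclass, field
from typing import Iterable

from Bio import Phylo

logger = logging.getLogger("censat_kit")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC ambiguity codes other than N are collapsed to N on input.
_IUPAC_AMBIG = set("RYSWKMBDHV")


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class Interval:
    """Genomic interval, 0-based half-open, stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    interval: Interval
    orthogroup_id: str


class GenomeSequences(dict):
    """Ordered map of sequence name -> uppercase nucleotide string.

    Alphabet restricted to {A, C, G, T, N}; sequence slices on the
    minus strand are reverse complements of the reference slice.
    """

    def add(self, name: str, seq: str) -> None:
        if name in self:
            raise FormatError(f"duplicate sequence name {name!r}")
        seq = seq.upper()
        cleaned = []
        n_ambig = 0
        for c in seq:
            if c in "ACGTN":
                cleaned.append(c)
            elif c in _IUPAC_AMBIG:
                cleaned.append("N")
                n_ambig += 1
            else:
                raise FormatError(f"invalid character {c!r} in sequence {name!r}")
        if n_ambig:
            logger.warning(
                "sequence %s: %d IUPAC ambiguity codes mapped to N", name, n_ambig
            )
        if not cleaned:
            raise FormatError(f"empty sequence {name!r}")
        self[name] = "".join(cleaned)

    def fetch(self, interval: Interval) -> str:
        seq = self[interval.chrom][interval.start : interval.end]
        if interval.strand == "-":
            seq = reverse_complement(seq)
        return seq

    @property
    def total_size(self) -> int:
        return sum(len(s) for s in self.values())

    def validate_interval(self, interval: Interval) -> None:
        if interval.chrom not in self:
            raise ValueError(f"unknown chromosome {interval.chrom!r}")
        if interval.end > len(self[interval.chrom]):
            raise ValueError(
                f"interval {interval} exceeds chromosome length "
                f"{len(self[interval.chrom])}"
            )


def read_fasta(path) -> GenomeSequences:
    """Load a FASTA file; case-folds to uppercase, maps ambiguity codes to N."""
    genome = GenomeSequences()
    name = None
    chunks: list[str] = []
    n_records = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    genome.add(name, "".join(chunks))
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"{path}: empty FASTA header")
                name = header.split()[0]
                chunks = []
                n_records += 1
            else:
                if name is None:
                    raise FormatError(f"{path}: sequence data before first header")
                chunks.append(line.strip())
    if name is not None:
        genome.add(name, "".join(chunks))
    if n_records == 0:
        raise FormatError(f"{path}: no FASTA records")
    return genome


def write_fasta(genome: GenomeSequences | dict, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def parse_trf_dat(path) -> list:
    """Parse tandem-repeat regions from a TRF v4.09 ``.dat`` file.

    Data rows carry 15 whitespace-separated fields:
    start end period copies consensus-size pct-match pct-indel score
    A C G T entropy consensus-unit region-seq.  TRF coordinates are
    1-based inclusive and are converted to 0-based half-open here.
    """
    from .tr_annotation import TandemRepeatRegion

    regions = []
    chrom = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("Sequence:"):
                chrom = line.split(None, 1)[1].split()[0]
                continue
            if line.startswith(("Tandem", "Gary", "Program", "Version",
                                "Parameters:", "Boston")):
                continue
            fields = line.split()
            if not fields[0].lstrip("-").isdigit():
                continue  # header noise
            if chrom is None:
                raise FormatError(f"{path}:{lineno}: data row before Sequence header")
            if len(fields) < 15:
                raise FormatError(
                    f"{path}:{lineno}: expected >=15 fields, got {len(fields)}"
                )
            start_1b, end_1b = int(fields[0]), int(fields[1])
            period = int(fields[2])
            copies = float(fields[3])
            pct_match = float(fields[5])
            cruseq = fields[13]
            regions.append(
                TandemRepeatRegion(
                    interval=Interval(chrom, start_1b - 1, end_1b),
                    period=period,
                    copy_number=copies,
                    cruseq=cruseq,
                    mean_identity=pct_match / 100.0,
                )
            )
    return regions


def write_bed(intervals: Iterable[Interval], path, names: Iterable[str] | None = None) -> None:
    """Write intervals as BED (0-based half-open), sorted by (chrom, start, end)."""
    rows = []
    names = list(names) if names is not None else None
    for i, iv in enumerate(intervals):
        name = names[i] if names else "."
        rows.append((iv.chrom, iv.start, iv.end, name, iv.strand))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for chrom, start, end, name, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")


def read_bed(path) -> list[Interval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >=3 columns")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "+"
            out.append(Interval(fields[0], int(fields[1]), int(fields[2]), strand))
    return out


def read_gene_table(path) -> list[GeneRecord]:
    """Tab-delimited gene/orthogroup table.

    Columns (header required): gene_id, chrom, start, end, strand,
    orthogroup_id.  Coordinates are 0-based half-open.
    """
    records = []
    seen = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["gene_id", "chrom", "start", "end", "strand", "orthogroup_id"]
        if header[: len(required)] != required:
            raise FormatError(
                f"{path}: expected header {required}, got {header}"
            )
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns")
            gene_id, chrom, start, end, strand, og = f[:6]
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            if not og:
                raise FormatError(f"{path}:{lineno}: gene {gene_id!r} lacks orthogroup")
            records.append(
                GeneRecord(gene_id, Interval(chrom, int(start), int(end), strand), og)
            )
    return records


def write_gene_table(records: Iterable[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\torthogroup_id\n")
        for r in records:
            iv = r.interval
            fh.write(
                f"{r.gene_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{r.orthogroup_id}\n"
            )


def parse_newick(text: str):
    """Parse a Newick string into a rooted Bio.Phylo tree with named leaves."""
    if text.count("(") != text.count(")"):
        raise FormatError("unbalanced parentheses in Newick string")
    try:
        tree = Phylo.read(io.StringIO(text), "newick")
    except Exception as exc:  # bubbled from Bio.Phylo's parser
        raise FormatError(f"invalid Newick: {exc}") from exc
    leaves = [t.name for t in tree.get_terminals()]
    if any(name is None for name in leaves):
        raise FormatError("Newick tree has unnamed leaves")
    if len(set(leaves)) != len(leaves):
        raise FormatError("duplicate leaf labels in Newick tree")
    return tree


def serialize_newick(tree) -> str:
    out = io.StringIO()
    Phylo.write(tree, out, "newick", plain=True)
    return out.getvalue().strip()


def read_bedgraph(path) -> list[tuple[str, int, int, float]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise FormatError(f"{path}:{lineno}: bedGraph needs 4 columns")
            rows.append((f[0], int(f[1]), int(f[2]), float(f[3])))
    return rows


def write_bedgraph(rows: Iterable[tuple[str, int, int, float]], path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_config(path) -> dict[str, str]:
    """Flat key=value config file; '#' comments and blank lines ignored."""
    cfg = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected key=value")
            key, value = line.split("=", 1)
            cfg[key.strip()] = value.strip()
    return cfg


def setup_logging(level: str = "info") -> None:
    levels = {"quiet": logging.WARNING, "info": logging.INFO, "debug": logging.DEBUG}
    logging.basicConfig(
        stream=sys.stderr,
        level=levels.get(level, logging.INFO),
        format="[%(levelname)s] %(name)s: %(message)s",
    )
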