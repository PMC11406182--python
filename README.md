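# censat-kit

Toolkit for discovering centromere satellites (cenSats) in assembled plant
genomes and tracing their evolution across related species and subgenomes.

Plant centromeres are built from megabase-scale arrays of tandemly repeated
satellite DNA. Given one or more assemblies, censat-kit:

- builds a per-species **satellite library**: tandem-repeat regions are
  filtered (copy number > 100, unit > 100 bp), validated by monomer tiling
  against their consensus unit (CRUseq, mean identity ≥ 80%), linked into a
  similarity network by genome-wide unit alignment, clustered with Louvain
  modularity, and ranked by AT content with names like `Prh168S1`
  (abbreviation + unit length + "S" + rank); candidate cenSats are families
  with > 1 Mb total genomic size and > 60% AT;
- compares cenSat arrays **across species**: per-genome hit sets (identity
  ≥ 80%, alignment ≥ 80% of the unit), 5 kb array consolidation, copy
  counting, a co-location network whose Louvain communities group
  homologous families, and flagging of representative cenSats
  (> 1,000 copies on ≥ 2 chromosomes or in ≥ 2 species);
- reconstructs **amplification trajectories** by Sankoff parsimony over
  {absent, seeded, amplified} on a species/subgenome tree (direct
  absent↔amplified transitions cost double — amplification passes through
  seeding);
- handles **synteny and karyotype bookkeeping**: orthogroup-ID sequences,
  greedy collinear block detection, LCS anchoring of blocks to gene
  coordinates, synteny-based cenSat assignment (the most abundant satellite
  at the peri-centromeric syntenic locus wins), and fission/fusion counting
  from oriented block-end adjacencies with the invariant
  `after = before + fissions − fusions`;
- quantifies **ChIP enrichment** (fold change of mean ChIP/input inside
  satellite arrays versus the rest of the genome) and estimates **genome
  size** by the Lander–Waterman identity `G = Knum / Kdepth` from a k-mer
  spectrum (k = 17);
- ships a **synthetic-data generator** that plants all of the above
  (satellite families, diverged species homologs, telomere runs,
  rearrangement logs, ChIP enrichment, reads) with full ground truth.

## Worked example

Two satellite families planted on a two-chromosome, 2.8 Mb synthetic genome
are recovered end-to-end:

```python
from censat_kit import synthetic_data as sd, tr_annotation as tra
from censat_kit import satellite_library as sl

specs = {"famA": sd.SatelliteSpec("famA", monomer_length=168, at_content=0.72),
         "famB": sd.SatelliteSpec("famB", monomer_length=338, at_content=0.65)}
mons = {f: sd.make_monomer(s.monomer_length, s.at_content, sd.derive_seed(11, f))
        for f, s in specs.items()}
chrom_specs = [sd.ChromosomeSpec(f"chr{c+1}", [
    sd.BackgroundElement(100_000),
    sd.ArrayElement("famA", 3334), sd.BackgroundElement(100_000),
    sd.ArrayElement("famB", 1657), sd.BackgroundElement(100_000)])
    for c in range(2)]
genome, genes, truth = sd.simulate_species(
    chrom_specs, 11, family_monomers=mons, family_specs=specs)

regions = tra.validate_regions(
    tra.resolve_overlaps(tra.filter_tr_regions(
        tra.detect_tandem_repeats_genome(genome))), genome)
library = sl.build_library(regions, genome, "Syn")
for fam in sl.filter_censat_candidates(library).families:
    print(fam.name, len(fam.unit), round(fam.at_content, 3),
          fam.total_genomic_size, len(fam.member_region_ids))
```

prints

```
Syn168S1 168 0.72 1119739 2
Syn338S2 338 0.636 1119833 2
```

— exactly two candidate families survive the 1 Mb / 60% AT filter, one per
planted monomer, with unit lengths, AT contents and total array sizes
matching the planted truth (2 × 3334 × 168 bp ≈ 1.12 Mb for the 168 bp
family). The genome-size worked example

```python
from censat_kit.quant_utils import estimate_genome_size
estimate_genome_size(89_085_253_385, 35)   # -> 2545292953
```

returns 2,545,292,953 bp: 89.1 billion 17-mers at modal depth 35.

A thin CLI wraps the common entry points:

```sh
censat-kit simulate --seed 3 --outdir sim/
censat-kit tr-annotate --fasta sim/genome.fa --out-bed tr.bed --out-table tr.tsv
censat-kit build-library --fasta sim/genome.fa --abbrev Syn --out lib/
censat-kit genome-size --reads reads.fa --k 17
censat-kit chip-enrich --chip chip.bedGraph --input input.bedGraph --arrays arrays.bed
censat-kit karyotype-events --ancestor anc.tsv --descendant desc.tsv
```

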