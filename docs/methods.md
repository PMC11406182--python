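# Methods

This note documents the models and conventions behind censat-kit: what each
stage computes, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the numerical choices made where the design was
genuinely open.

## Problem setting

Centromeres of most plants are occupied by megabase-scale arrays of tandemly
repeated satellite DNA (cenSats). Identifying the satellite family that
occupies the centromeres of a genome, tracking homologous families across
related species and subgenomes, and reconstructing when each family amplified
are the core computations this package automates. The pipeline operates on
assembled genomes (FASTA), tandem-repeat annotations, orthogroup-labelled gene
tables, a species/subgenome tree (Newick), ChIP/input coverage tracks
(bedGraph), and read sets.

## Satellite library construction

1. **Tandem-repeat regions.** Regions come either from a TRF v4.09 `.dat`
   file (the fidelity path for real assemblies) or from the built-in
   detector. The detector finds candidate periods from the spacing of exact
   k-mer recurrences (k = 12, clamped to the minimum period), verifies each
   candidate region by the lag-p self-match fraction (threshold 0.8 over at
   least 3 periods), extends boundaries period-wise, prefers the smallest
   period that satisfies the threshold (divisor scan), and reports a
   per-column majority consensus unit (CRUseq). It is a periodicity scan, not
   TRF's wraparound alignment; at desk scale it recovers planted arrays with
   period within ±2 bp, but it is not intended to reproduce TRF output on
   real genomes.
2. **Filtering.** Regions are kept when copy number > 100 and unit length
   > 100 bp (both strict). When two regions overlap by more than 80% of the
   shorter one, the region with the longer consensus unit is removed; pairs
   are processed in (chrom, start, end, period) order, which makes the
   operation deterministic and idempotent.
3. **Validation.** Each region is tiled with its own consensus unit by a
   wraparound dynamic program (unit costs; the template may restart at each
   monomer boundary and stop part-way at the region end). Per-monomer
   identity is 1 − edits / max(unit length, instance length); the trailing
   partial monomer is reported but excluded from the mean so array ends are
   not penalized. Regions with mean identity below 0.8 are discarded
   (boundary kept). Regions longer than 30 kb are scored on their leading
   30 kb window — tandem arrays are homogeneous enough that the window mean
   estimates the full-region mean, and this bounds validation cost.
4. **Similarity network.** Each region's unit is queried genome-wide with a
   seed-and-extend aligner (exact 13-mer seeds on both strands; seeds are
   anchored to the estimated unit start via the seed's offset within the
   unit; each candidate window is scored by an infix edlib alignment). Hits
   with identity < 0.8 or span < 80% of the unit length are dropped.
   Same-locus duplicate hits (overlap > 50% of the shorter hit) are resolved
   by identity; adjacent per-monomer hits are all kept so arrays are tiled.
   An undirected edge joins two regions when any retained hit of one unit
   overlaps the other region's interval by at least 1 bp.
5. **Communities, representatives, names.** Louvain modularity communities
   (resolution 1.0, seed 42, canonical sorted node order — determinism is
   required for reproducible libraries; isolated nodes become singletons).
   The representative of a community is its maximum-degree region (ties:
   larger region, then lexicographic id); the community's unit is that
   region's consensus. Families are ranked by unit AT content descending
   (ties: larger total genomic size, then unit length) and named
   `abbrev + unit_length + "S" + rank` (e.g. Prh168S1). Candidate cenSats
   are families with total merged hit size > 1 Mb and AT content > 60%
   (both strict).

Unit comparisons for scoring recovery (never for naming) use a canonical
form: the lexicographically minimal rotation over both strands, since tandem
units have arbitrary phase and strand.

## Cross-species comparison and trajectories

Each satellite unit is queried in every genome with the same aligner and
filters; per-chromosome hits are merged, and adjacent arrays closer than
5 kb are consolidated while merged arrays shorter than 5 kb are dropped.
Copy number per chromosome is the rounded array-length / unit-length sum.

Two satellites are linked in the cross-species network when a merged region
of one and a merged region of the other, on the same genome and chromosome,
reciprocally overlap by at least 80% of the shorter region (hit regions are
identity-filtered at generation time, so the network edge tests co-location).
Louvain communities of this network group homologous families; a community is
flagged a representative cenSat when its members exceed 1,000 copies on at
least two chromosomes or in at least two species.

Per species or subgenome, a satellite is **amplified** on a chromosome at
> 1,000 copies, **seeded** at 1–1,000 copies, **absent** otherwise; a
satellite amplified on more than half of the chromosome set is a potential
functional satellite. The 1,000-copy and 50% conventions are configurable;
they quantify the qualitative "substantively detected" and "most
chromosomes" usage they encode.

Amplification trajectories are reconstructed per satellite by Sankoff
parsimony over the three states with unit step costs and cost 2 for the
direct absent↔amplified transition (which must pass through seeding).
Ancestral ties are resolved toward the parent's state, then toward "seeded",
then alphabetically; branch events are emitted from state changes. On a
subgenome tree where a satellite is amplified only in two hybridizing
subgenomes, the minimal solution keeps all ancestors seeded and places both
amplification events on the terminal branches — amplification after
hybridization — rather than postulating ancestral amplification plus loss.

## Synteny blocks and karyotype events

Genomes are reduced to orthogroup-ID sequences per chromosome, after
removing every orthogroup whose copy number exceeds its target (e.g. 2 for a
WGD genome, 1 otherwise) in any genome. Blocks are maximal collinear chains
(same order or fully reversed) across all genomes, extracted greedily
longest-first with up to 20 intervening unassignable genes (`max_gap`),
minimum 5 genes; every gene joins at most one block. This is a deterministic
collinear-chaining stand-in for A-Bruijn-based synteny tools; the cycle-length
parameter of those tools maps onto `max_gap`. Block occurrences per genome
are re-scanned afterwards so copy numbers above one are recorded, and blocks
whose occurrence count differs from the target in any genome can be filtered.
Classic longest-common-subsequence DP (leftmost tie-break) anchors a block
back to its start/end genes and bp coordinates on a chromosome.

Centromere assignment by synteny: for each reference centromere array the
nearest flanking block occurrences (one per side; a single block spanning
the array serves as both flanks, since no genes lie inside the array) are
mapped to the target genome; candidate satellites whose arrays fall within
the mapped locus ± 2 Mb are collected and the most copy-abundant one wins.
The 2 Mb peri-centromeric window is a convention (the notion is not
quantified in the field) and is configurable.

Fission/fusion bookkeeping represents a genome as ordered signed block IDs
per chromosome. An adjacency is an unordered pair of oriented block ends;
telomeres are not represented. Between an ancestor and a descendant with
identical block content, fissions are ancestor adjacencies missing from the
descendant and fusions are descendant adjacencies missing from the ancestor;
`after = before + fissions − fusions` is asserted on every accepted input.
Inputs whose adjacency changes cannot arise from fissions and fusions alone
(e.g. translocations, breakpoint reuse) are rejected with the offending
adjacency named. Breakpoint–centromere proximity uses a 5 Mb window by
default, also configurable.

## Quantification

**Genome size.** G = Knum / Kdepth (floored), with Knum the total number of
k-mer instances in the reads (canonical counting, k = 17, exact hash-map
counting — desk-scale genomes need no sketching) and Kdepth the modal depth
of the k-mer spectrum after the error valley. Because read starts are
discrete, neighbouring spectrum bins co-fluctuate: a read boundary moves
~L−k+1 k-mers together, so the raw modal bin is unstable at small genome
sizes even without sequencing error. Kdepth is therefore the (integer) mode
of a 5-bin moving average of the spectrum, with near-ties resolved by raw
count; the valley rule and the published worked example are unaffected. At
1 Mb and 30× with 192 bp reads the expected k-mer depth is
30·(192−16)/192 = 27.5, so either neighbouring integer mode keeps the
estimate within 2% of truth; the read length in the recovery experiments is
chosen for exactly this half-integer property.

**ChIP enrichment.** Per-bin ratio (ChIP + 1)/(input + 1) (pseudocount 1
avoids division by zero and vanishes at realistic depth; bin width 20 kb by
default), then fold change = mean ratio over bins at least half-covered by
satellite arrays divided by mean ratio over all other bins. The estimator is
invariant to global rescaling of both tracks up to pseudocount effects.

**Telomeres.** A chromosome end is flagged when its terminal 10 kb window
carries a run of ≥ 10 copies of the telomere motif (CCCTGAA) or its reverse
complement with inter-copy gaps of at most one motif length, orientation
chosen per end.

## Synthetic data

The generator plants every structure the pipeline is meant to recover:
monomer templates at a target AT fraction; arrays of independently mutated
copies (substitutions only by default — indels are a separate parameter
defaulting to 0 so identity arithmetic stays exact); species-specific family
monomers produced by evolving one ancestral monomer along the input tree
with per-branch substitution counts (planting the cross-species community
structure); i.i.d. background at a chosen GC; telomere motif runs; gene
placements carrying orthogroup IDs; fission/fusion/translocation event logs
on block genomes; Poisson ChIP/input tracks with planted enrichment over
arrays; and error-free uniformly placed reads. A single global seed drives
everything; per-component seeds are derived by stable hashing of
(seed, component name), so identical specs and seeds give byte-identical
outputs while components stay independent.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: transposable-element families and segmental
duplications (background is i.i.d., so the detector's false-positive rate on
real repeat landscapes will be higher), sequencing error and coverage bias,
higher-order repeat structure within arrays, indel-driven array turnover,
and assembly artifacts. The TRF ingestion path plus the downstream filters
are the intended route for real assemblies.

## Default problem sizes

Recovery experiments run at desk scale: 2–4 families of 168/238/338/127 bp
monomers at ~0.56 Mb of array per family per chromosome on two chromosomes
(3–6 Mb genomes), 5% monomer divergence within arrays, ≤ 10% divergence
between species homologs, 10,000 coverage bins at depth 100 for ChIP, and a
1 Mb genome at 30× for genome-size estimation. These sizes were chosen so
each planted family clears the 1 Mb library filter with margin while the
whole pipeline remains interactive on a single CPU.

## Known limitations

- The internal TR detector requires arrays long and clean enough for exact
  k-mer recurrence (it will miss arrays whose every monomer pair differs in
  all k-mers); TRF ingestion is the path for divergent real satellites.
- `resolve_overlaps` is quadratic per chromosome and intended for the
  post-filter region counts (hundreds, not millions).
- Synteny chaining assumes mostly single-copy orthogroups after the cap
  filter; heavily duplicated gene content will fragment blocks.
- Trajectory states are per-satellite; a replacement is reported as one
  satellite's loss and another's gain on the same branch, not as a joint
  event.
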