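import itertools

import edlib
import numpy as np
import pytest

from censat_kit import synthetic_data as sd
from censat_kit import tr_annotation as tra
from censat_kit.io_core import GenomeSequences, Interval
from censat_kit.tr_annotation import TandemRepeatRegion

from conftest import planted_genome, random_genome


def region(chrom, start, end, period, copies, cruseq=None):
    return TandemRepeatRegion(
        interval=Interval(chrom, start, end),
        period=period,
        copy_number=copies,
        cruseq=cruseq or "A" * period,
    )


class TestDetect:
    def test_exact_short_repeat(self):
        regions = tra.detect_tandem_repeats("ACGTACGTACGTACGT", min_period=4,
                                            max_period=8, min_span_copies=3)
        assert len(regions) == 1
        r = regions[0]
        assert r.period == 4
        assert r.cruseq == "ACGT"
        assert r.copy_number == pytest.approx(4, abs=0.5)

    def test_no_false_calls_on_random_sequence(self):
        """Empirical null: i.i.d. sequence yields no periodic calls."""
        for seed in range(20):
            g = random_genome(100_000, seed)
            assert tra.detect_tandem_repeats(g["chr1"]) == []

    def test_planted_array_recovered(self):
        spec = sd.SatelliteSpec("f", monomer_length=168, mutation_rate=0.05)
        arr, _ = sd.simulate_array(spec, 500, seed=3)
        bg = sd.random_background(30000, 0.5, np.random.default_rng(8))
        regions = tra.detect_tandem_repeats(bg + arr + bg)
        big = max(regions, key=lambda r: len(r.interval))
        assert 166 <= big.period <= 170
        truth = Interval("seq", 30000, 30000 + len(arr))
        assert big.interval.overlap(truth) >= 0.95 * len(truth)

    def test_recall_on_simulated_arrays(self):
        """>= 95% of planted arrays recovered at 5% monomer mutation."""
        hits = 0
        total = 0
        for seed in range(1, 21):
            genome, truth, _ = planted_genome(
                {"f": (168, 0.65, 300)}, seed=seed, background=20000
            )
            regions = tra.detect_tandem_repeats_genome(genome)
            for iv, _ in truth.arrays:
                total += 1
                if any(r.interval.overlap(iv) >= 0.5 * len(iv) for r in regions):
                    hits += 1
        assert hits / total >= 0.95

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            tra.detect_tandem_repeats("ACGT", min_period=10, max_period=5)


class TestFilter:
    def test_thresholds_are_strict(self):
        kept = region("c", 0, 25200, 168, 150)
        boundary_copies = region("c", 30000, 46800, 168, 100)
        boundary_period = region("c", 50000, 65000, 100, 150)
        out = tra.filter_tr_regions([kept, boundary_copies, boundary_period])
        assert out == [kept]

    def test_empty_and_idempotent(self):
        assert tra.filter_tr_regions([]) == []
        regions = [region("c", 0, 25200, 168, 150)]
        once = tra.filter_tr_regions(regions)
        assert tra.filter_tr_regions(once) == once


class TestResolveOverlaps:
    def test_nested_regions_drop_longer_unit(self):
        short_unit = region("c", 0, 20000, 168, 119)
        long_unit = region("c", 1000, 19000, 338, 53)
        out = tra.resolve_overlaps([short_unit, long_unit])
        assert out == [short_unit]

    def test_disjoint_kept(self):
        a = region("c", 0, 10000, 168, 59)
        b = region("c", 20000, 30000, 238, 42)
        assert sorted(r.interval.start for r in tra.resolve_overlaps([a, b])) == [0, 20000]

    def test_matches_pairwise_brute_force(self):
        """Triple-overlap outcomes equal brute-force pair processing."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            regs = []
            for i in range(3):
                start = int(rng.integers(0, 5000))
                length = int(rng.integers(5000, 20000))
                period = int(rng.integers(101, 400))
                regs.append(region("c", start, start + length, period,
                                   length / period))
            result = {r.region_id for r in tra.resolve_overlaps(regs)}

            ordered = sorted(
                regs, key=lambda r: (r.interval.chrom, r.interval.start,
                                     r.interval.end, r.period)
            )
            alive = {r.region_id for r in ordered}
            for a, b in itertools.combinations(ordered, 2):
                if a.region_id not in alive or b.region_id not in alive:
                    continue
                ov = a.interval.overlap(b.interval)
                if ov > 0.8 * min(len(a.interval), len(b.interval)):
                    loser = a if len(a.cruseq) > len(b.cruseq) else b
                    alive.discard(loser.region_id)
            assert result == alive

    def test_idempotent(self):
        a = region("c", 0, 20000, 168, 119)
        b = region("c", 1000, 19000, 338, 53)
        once = tra.resolve_overlaps([a, b])
        assert tra.resolve_overlaps(once) == once


def _oracle_decompose(region_seq: str, template: str, max_monomers: int = 6):
    """Exhaustive tiling oracle: minimize summed per-chunk edit distance.

    Every cut vector with up to ``max_monomers`` chunks is covered by a
    layered DP whose chunk scores come from independent edlib global
    alignments; the final chunk may instead stop at a template prefix
    (semi-global) and is then excluded from the identity mean.  Returns
    (min cost, set of mean identities over all optimal tilings).
    """
    n, t = len(region_seq), len(template)
    inf = float("inf")
    nw = {}
    shw = {}
    for j in range(n):
        for i in range(j + 1, n + 1):
            nw[(j, i)] = edlib.align(region_seq[j:i], template, mode="NW",
                                     task="distance")["editDistance"]
        shw[j] = edlib.align(region_seq[j:n], template, mode="SHW",
                             task="distance")["editDistance"]

    dp = [[inf] * (n + 1) for _ in range(max_monomers + 1)]
    dp[0][0] = 0
    for m in range(1, max_monomers + 1):
        for i in range(1, n + 1):
            dp[m][i] = min(
                (dp[m - 1][j] + nw[(j, i)] for j in range(i) if dp[m - 1][j] < inf),
                default=inf,
            )

    cost_complete = min(dp[m][n] for m in range(1, max_monomers + 1))
    cost_partial = min(
        (
            dp[m][j] + shw[j]
            for m in range(max_monomers)
            for j in range(n)
            if dp[m][j] < inf
        ),
        default=inf,
    )
    best = min(cost_complete, cost_partial)

    means = set()
    paths_budget = [2000]

    def chunk_ident(j, i):
        return 1 - nw[(j, i)] / max(t, i - j)

    def walk(m, i, idents):
        if paths_budget[0] <= 0:
            return
        if m == 0:
            if i == 0:
                mean = float(np.mean(idents)) if idents else 0.0
                means.add(round(mean, 9))
                paths_budget[0] -= 1
            return
        for j in range(i):
            if dp[m - 1][j] + nw[(j, i)] == dp[m][i]:
                walk(m - 1, j, [chunk_ident(j, i)] + idents)

    if cost_complete == best:
        for m in range(1, max_monomers + 1):
            if dp[m][n] == best:
                walk(m, n, [])
    if cost_partial == best:
        for m in range(max_monomers):
            for j in range(n):
                if dp[m][j] < inf and dp[m][j] + shw[j] == best:
                    walk(m, j, [])
    return best, means


class TestDecompose:
    def test_exact_repetition(self):
        t = "ACGTTGCA" * 3  # 24 bp template
        tiling, mean = tra.decompose_region(t * 3, t)
        assert mean == 1.0
        assert [(a, b) for a, b, _, _ in tiling] == [(0, 24), (24, 48), (48, 72)]

    def test_single_substitution_arithmetic(self):
        t = sd.make_monomer(60, 0.5, 1)
        s = list(t * 3)
        s[10] = "A" if s[10] != "A" else "C"
        tiling, mean = tra.decompose_region("".join(s), t)
        idents = sorted(i for _, _, i, _ in tiling)
        assert idents == pytest.approx([1 - 1 / 60, 1.0, 1.0])
        assert mean == pytest.approx(1 - 1 / 180)

    def test_trailing_partial_excluded(self):
        t = sd.make_monomer(40, 0.5, 2)
        tiling, mean = tra.decompose_region(t * 3 + t[:15], t)
        assert mean == 1.0
        assert tiling[-1][3] is True  # partial flag

    def test_matches_exhaustive_oracle(self):
        """Tiling DP equals the exhaustive-tiling oracle on random cases."""
        rng = np.random.default_rng(7)
        for case in range(50):
            t_len = int(rng.integers(12, 26))
            template = sd.make_monomer(t_len, 0.5, int(rng.integers(2**31)))
            kind = case % 3
            if kind == 0:  # mutated tandem copies
                copies = int(rng.integers(2, 5))
                seq = "".join(
                    sd.mutate_sequence(template, 0.1, rng) for _ in range(copies)
                )
            elif kind == 1:  # copies plus a partial tail
                seq = template * 2 + template[: int(rng.integers(3, t_len - 1))]
            else:  # unrelated random sequence
                seq = sd.random_background(
                    int(rng.integers(t_len, 3 * t_len)), 0.5, rng
                )
            max_m = len(seq) // t_len + 3
            oracle_cost, oracle_means = _oracle_decompose(seq, template, max_m)
            tiling, mean = tra.decompose_region(seq, template)
            impl_cost = 0
            for a, b, _, partial in tiling:
                mode = "SHW" if partial else "NW"
                impl_cost += edlib.align(seq[a:b], template, mode=mode,
                                         task="distance")["editDistance"]
            assert impl_cost == oracle_cost
            assert min(abs(mean - m) for m in oracle_means) < 1e-9

    def test_identity_bounds(self):
        t = sd.make_monomer(30, 0.5, 3)
        rng = np.random.default_rng(4)
        for _ in range(10):
            seq = sd.random_background(90, 0.5, rng)
            _, mean = tra.decompose_region(seq, t)
            assert 0.0 <= mean < 1.0


class TestValidate:
    def test_exact_region_kept_with_identity_one(self):
        t = sd.make_monomer(120, 0.6, 1)
        g = GenomeSequences()
        g.add("c", t * 10)
        regs = [region("c", 0, 1200, 120, 10, cruseq=t)]
        out = tra.validate_regions(regs, g)
        assert len(out) == 1
        assert out[0].mean_identity == 1.0

    def test_randomized_region_removed(self):
        rng = np.random.default_rng(5)
        for i in range(20):
            t = sd.make_monomer(168, 0.5, i)
            g = GenomeSequences()
            g.add("c", sd.random_background(1680, 0.5, rng))
            regs = [region("c", 0, 1680, 168, 10, cruseq=t)]
            assert tra.validate_regions(regs, g) == []

    def test_boundary_identity_kept(self):
        """A region at exactly the 0.8 identity boundary is kept."""
        t = "A" * 100
        # 3 copies with exactly 20 substitutions each -> identity 0.8
        copy = "C" * 20 + "A" * 80
        g = GenomeSequences()
        g.add("c", copy * 3)
        regs = [region("c", 0, 300, 100, 3, cruseq=t)]
        out = tra.validate_regions(regs, g)
        assert len(out) == 1
        assert out[0].mean_identity == pytest.approx(0.8)


class TestTelomeres:
    def test_motif_run_at_start_flagged(self):
        g = GenomeSequences()
        g.add("c", sd.TELOMERE_MOTIF * 20 + "ACGT" * 5000)
        flags = tra.find_telomeres(g)
        assert flags[("c", "start")] is True
        assert flags[("c", "end")] is False

    def test_random_chromosome_unflagged(self):
        for seed in range(20):
            g = random_genome(30000, seed)
            flags = tra.find_telomeres(g)
            assert not any(flags.values())

    def test_reverse_complement_orientation(self):
        from censat_kit.io_core import reverse_complement

        g = GenomeSequences()
        g.add("c", "ACGT" * 5000 + reverse_complement(sd.TELOMERE_MOTIF) * 15)
        assert tra.find_telomeres(g)[("c", "end")] is True

    def test_simulated_73_of_94_ends(self):
        """Mixed simulated karyotype: exactly the planted ends flagged."""
        rng = np.random.default_rng(12)
        chrom_specs = []
        planted = set()
        ends = [(f"chr{i + 1}", side) for i in range(47) for side in ("start", "end")]
        chosen = set(
            tuple(ends[i]) for i in rng.choice(len(ends), size=73, replace=False)
        )
        for i in range(47):
            name = f"chr{i + 1}"
            elements = []
            if (name, "start") in chosen:
                elements.append(sd.TelomereElement(copies=15))
                planted.add((name, "start"))
            elements.append(sd.BackgroundElement(25000))
            if (name, "end") in chosen:
                elements.append(sd.TelomereElement(copies=15))
                planted.add((name, "end"))
            chrom_specs.append(sd.ChromosomeSpec(name, elements))
        genome, _, _ = sd.simulate_species(chrom_specs, seed=13)
        flags = tra.find_telomeres(genome)
        assert len(planted) == 73
        assert {k for k, v in flags.items() if v} == planted
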