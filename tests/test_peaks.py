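"""Consensus merging, functional-region priority and TSS profiles."""

import numpy as np
import pytest

from moltseq.annotation import GeneModel, promoter_of, tts_of
from moltseq.peaks import (REGION_CATEGORIES, GenomeRegions, PeakRecord,
                           categorize_peak, merge_sample_peaks, read_narrowpeak,
                           region_distribution, tss_profile)


def _peak(chrom, start, end, fe=None, summit=None, pid="p"):
    return PeakRecord(pid, chrom, start, end, summit=summit,
                      fold_enrich=fe or {})


class TestMerge:
    def test_overlapping_peaks_union_with_per_sample_max_fe(self):
        merged = merge_sample_peaks({
            "s1": [_peak("chr1", 100, 200, {"s1": 5.0}, summit=150)],
            "s2": [_peak("chr1", 150, 250, {"s2": 7.0}, summit=180)],
        })
        (rec,) = merged
        assert (rec.start, rec.end) == (100, 250)
        assert rec.fold_enrich == {"s1": 5.0, "s2": 7.0}
        assert rec.summit == 180  # from the higher-FE constituent

    def test_non_overlapping_peaks_stay_separate(self):
        merged = merge_sample_peaks({
            "s1": [_peak("chr1", 100, 200, {"s1": 1.0})],
            "s2": [_peak("chr1", 200, 300, {"s2": 1.0})],  # touching, no overlap
        })
        assert len(merged) == 2

    def test_merge_is_idempotent(self):
        rng = np.random.default_rng(5)
        per_sample = {
            s: [_peak("chr1", int(p), int(p) + int(rng.integers(50, 300)),
                      {s: float(rng.uniform(1, 10))}, pid=f"{s}_{i}")
                for i, p in enumerate(rng.integers(0, 20_000, 60))]
            for s in ("s1", "s2", "s3")
        }
        once = merge_sample_peaks(per_sample)
        twice = merge_sample_peaks({"merged": once})
        assert [(p.chrom, p.start, p.end, p.fold_enrich) for p in once] == [
            (p.chrom, p.start, p.end, p.fold_enrich) for p in twice]

    @pytest.mark.parametrize("seed", range(25))
    def test_consensus_count_matches_overlap_graph_components(self, seed):
        """Brute-force oracle: single-linkage merging must produce one
        record per connected component of the pairwise-overlap graph."""
        rng = np.random.default_rng(seed)
        peaks = []
        for i in range(int(rng.integers(5, 200))):
            s = int(rng.integers(0, 5000))
            sample = f"s{int(rng.integers(1, 4))}"
            peaks.append(_peak("chr1", s, s + int(rng.integers(1, 400)),
                               {sample: float(rng.uniform(1, 5))}, pid=f"p{i}"))
        per_sample = {"s1": [], "s2": [], "s3": []}
        for p in peaks:
            per_sample[next(iter(p.fold_enrich))].append(p)

        n = len(peaks)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if peaks[i].start < peaks[j].end and peaks[j].start < peaks[i].end:
                    parent[find(i)] = find(j)
        n_components = len({find(i) for i in range(n)})
        assert len(merge_sample_peaks(per_sample)) == n_components

    def test_unknown_chromosome_warns_but_retains(self):
        with pytest.warns(UserWarning, match="unknown chromosome"):
            merged = merge_sample_peaks(
                {"s1": [_peak("chrUn", 0, 10, {"s1": 1.0})]},
                known_chroms={"chr1"})
        assert len(merged) == 1


def _brute_force_category(peak, genes, promoter_flank=2000, downstream_extent=3000):
    """Independent region assignment: build every region list explicitly
    and apply the priority order."""
    def overlaps(iv):
        return peak.start < iv[1] and iv[0] < peak.end

    regions = {c: [] for c in REGION_CATEGORIES}
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        prom = promoter_of(g, promoter_flank)
        regions["promoter_tss"].append((prom.start, prom.end))
        regions["utr5"].extend(g.utr5)
        regions["utr3"].extend(g.utr3)
        regions["exon"].extend(g.exons)
        prev = g.start
        for s, e in g.exons:
            if s > prev:
                regions["intron"].append((prev, s))
            prev = max(prev, e)
        if g.end > prev:
            regions["intron"].append((prev, g.end))
        tts = tts_of(g)
        if g.strand == "+":
            regions["downstream"].append((tts + 1, tts + 1 + downstream_extent))
        else:
            regions["downstream"].append((max(0, tts - downstream_extent), tts))
    for cat in REGION_CATEGORIES[:-1]:
        if any(overlaps(iv) for iv in regions[cat]):
            return cat
    return "distal_intergenic"


class TestCategorize:
    def _genes(self):
        return [
            GeneModel("gA", "chr1", "+", 10_000, 20_000,
                      exons=[(10_000, 12_000), (15_000, 20_000)]),
            GeneModel("gB", "chr1", "+", 14_000, 30_000,
                      exons=[(14_000, 14_500), (29_000, 30_000)]),
        ]

    def test_exon_of_one_gene_beats_intron_of_another(self):
        # [16_500, 16_800) is exonic in gA but intronic in gB, and outside
        # both promoters ([8000, 12001) and [12000, 16001)): the exon wins.
        regions = GenomeRegions(self._genes())
        assert categorize_peak(_peak("chr1", 16_500, 16_800), regions) == "exon"

    def test_promoter_beats_exon(self):
        regions = GenomeRegions(self._genes())
        assert categorize_peak(_peak("chr1", 10_100, 10_300), regions) == "promoter_tss"

    def test_no_overlap_is_distal_intergenic(self):
        regions = GenomeRegions(self._genes())
        assert categorize_peak(_peak("chr1", 500_000, 500_100), regions) == \
            "distal_intergenic"

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        genes = []
        cursor = 0
        for i in range(int(rng.integers(3, 40))):
            cursor += int(rng.integers(500, 8000))
            length = int(rng.integers(300, 6000))
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(1, 4))
            exons = []
            if n_ex == 1 or length < 10:
                exons = [(cursor, cursor + length)]
            else:
                cuts = np.sort(rng.choice(np.arange(1, length),
                                          2 * (n_ex - 1), replace=False))
                b = [0, *cuts.tolist(), length]
                exons = [(cursor + b[2 * k], cursor + b[2 * k + 1])
                         for k in range(n_ex)]
            genes.append(GeneModel(f"g{i}", "chr1", strand, cursor,
                                   cursor + length, exons))
            cursor += length
        regions = GenomeRegions(genes)
        for _ in range(40):
            s = int(rng.integers(0, cursor + 10_000))
            peak = _peak("chr1", s, s + int(rng.integers(1, 2000)))
            assert categorize_peak(peak, regions) == \
                _brute_force_category(peak, genes)

    def test_adding_promoter_never_demotes(self):
        """Priority monotonicity: an extra overlapping promoter can only
        move a peak to the top category."""
        genes = self._genes()
        regions = GenomeRegions(genes)
        peak = _peak("chr1", 15_500, 15_800)
        before = categorize_peak(peak, regions)
        genes_plus = genes + [GeneModel("gNew", "chr1", "+", 15_600, 25_000)]
        after = categorize_peak(peak, GenomeRegions(genes_plus))
        order = list(REGION_CATEGORIES)
        assert order.index(after) <= order.index(before)


class TestRegionDistribution:
    def test_fractions_sum_to_one_and_match_counts(self):
        genes = [GeneModel("g", "chr1", "+", 10_000, 20_000)]
        regions = GenomeRegions(genes)
        peaks = [_peak("chr1", 9_000, 9_100, pid=f"a{i}") for i in range(4)]
        peaks += [_peak("chr1", 500_000 + i * 1000, 500_100 + i * 1000,
                        pid=f"b{i}") for i in range(6)]
        dist = region_distribution(peaks, regions)
        assert dist["fraction"].sum() == pytest.approx(1.0, abs=1e-12)
        assert dist.loc["promoter_tss", "fraction"] == pytest.approx(0.4)
        assert dist.loc["distal_intergenic", "fraction"] == pytest.approx(0.6)
        recomputed = {c: sum(1 for p in peaks if categorize_peak(p, regions) == c)
                      for c in REGION_CATEGORIES}
        assert dist["count"].to_dict() == recomputed

    def test_empty_peak_list_is_an_error(self):
        regions = GenomeRegions([GeneModel("g", "chr1", "+", 0, 100)])
        with pytest.raises(ValueError):
            region_distribution([], regions)


class TestTssProfile:
    def test_point_at_tss_lands_in_central_bin_for_both_strands(self):
        fwd = GeneModel("f", "chr1", "+", 100_000, 110_000)
        rev = GeneModel("r", "chr1", "-", 100_000, 110_001)  # tss = 110_000
        signal = {"chr1": np.array([100_000])}
        mat, _, _ = tss_profile(signal, [fwd], flank=3000, bin_size=50)
        assert mat[0, 3000 // 50] == 1
        signal_rev = {"chr1": np.array([110_000])}
        mat_r, _, _ = tss_profile(signal_rev, [rev], flank=3000, bin_size=50)
        assert mat_r[0].sum() == 1
        # after orientation flip the hit is in the first downstream bin,
        # mirroring the forward-strand case
        assert np.argmax(mat_r[0]) == 3000 // 50

    def test_uniform_signal_gives_flat_mean_profile(self):
        rng = np.random.default_rng(12)
        genes = [GeneModel(f"g{i}", "chr1", "+" if i % 2 else "-",
                           50_000 + i * 20_000, 60_000 + i * 20_000)
                 for i in range(30)]
        signal = {"chr1": rng.integers(0, 700_000, size=200_000)}
        _, mean, _ = tss_profile(signal, genes, flank=3000, bin_size=50)
        lam = mean.mean()
        se = np.sqrt(lam / len(genes))
        assert np.all(np.abs(mean - lam) < 3.5 * se)

    def test_left_truncated_window_flagged(self):
        g = GeneModel("g", "chr1", "+", 1000, 5000)
        mat, _, truncated = tss_profile({"chr1": np.array([])}, [g],
                                        flank=3000, bin_size=50)
        assert truncated[0]
        assert mat[0].sum() == 0

    def test_flank_must_divide_by_bin_size(self):
        g = GeneModel("g", "chr1", "+", 10_000, 20_000)
        with pytest.raises(ValueError):
            tss_profile({}, [g], flank=3000, bin_size=70)


def test_narrowpeak_reader(tmp_path):
    p = tmp_path / "s1.narrowPeak"
    p.write_text("chr1\t100\t200\tpk1\t0\t.\t5.5\t-1\t-1\t40\n"
                 "chr2\t0\t50\tpk2\t0\t.\t2.0\t-1\t-1\t-1\n")
    peaks = read_narrowpeak(p, "s1")
    assert peaks[0].summit == 140
    assert peaks[0].fold_enrich == {"s1": 5.5}
    assert peaks[1].summit is None
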