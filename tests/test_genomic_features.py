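"""Reference selection, contig filters, mapping summaries, RPKM/coverage."""

import numpy as np
import pytest

from metafuse.genomic_features import (
    ContigRecord,
    MappingSummary,
    build_genomic_matrix,
    coverage,
    filter_contigs_by_length,
    rpkm,
    select_reference_samples,
    select_representative_contigs,
    summarize_mapping,
)
from metafuse.io_formats import AlignmentRecord


def _aln(read_id, contig, spans, primary=True, unmapped=False):
    rl = sum(e - s for s, e in spans) or 10
    return AlignmentRecord(
        read_id=read_id,
        contig_id=None if unmapped else contig,
        ref_start=spans[0][0] if spans else -1,
        aligned_ref_span=spans,
        read_length=rl,
        mismatch_count=0,
        softclip_length=0,
        is_unmapped=unmapped,
        is_primary=primary,
    )


class TestReferenceSelection:
    def test_full_draw_returns_everything(self):
        ids = [f"s{i}" for i in range(5)]
        assert sorted(select_reference_samples(ids, 5, seed=1)) == ids

    def test_same_seed_same_subset(self):
        ids = [f"s{i}" for i in range(10)]
        assert select_reference_samples(ids, 3, 42) == select_reference_samples(ids, 3, 42)

    def test_too_many_refs_error(self):
        with pytest.raises(ValueError):
            select_reference_samples(["a", "b"], 3, 0)

    def test_uniform_inclusion_frequency(self):
        """Monte Carlo: drawing 2 of 10, every sample included ~20% of the time."""
        ids = [f"s{i}" for i in range(10)]
        counts = {s: 0 for s in ids}
        n_draws = 10_000
        for seed in range(n_draws):
            for s in select_reference_samples(ids, 2, seed):
                counts[s] += 1
        freqs = np.array([counts[s] / n_draws for s in ids])
        assert np.all(np.abs(freqs - 0.2) < 0.02)


class TestContigFilters:
    def test_strict_length_boundary(self):
        contigs = [ContigRecord("a", 5001), ContigRecord("b", 5000), ContigRecord("c", 4999)]
        kept = filter_contigs_by_length(contigs)
        assert [c.contig_id for c in kept] == ["a"]

    def test_empty_input(self):
        assert filter_contigs_by_length([]) == []

    def test_longest_per_bin(self):
        contigs = [
            ContigRecord("c1", 8000, "b1"),
            ContigRecord("c2", 6000, "b1"),
            ContigRecord("solo", 7000, "b3"),
        ]
        reps = select_representative_contigs(contigs)
        assert [c.contig_id for c in reps] == ["c1", "solo"]

    def test_tie_breaks_to_smallest_id(self):
        contigs = [ContigRecord("cB", 7000, "b2"), ContigRecord("cA", 7000, "b2")]
        (rep,) = select_representative_contigs(contigs)
        assert rep.contig_id == "cA"

    def test_unbinned_excluded_and_output_size_is_bin_count(self):
        rng = np.random.default_rng(5)
        contigs = []
        for i in range(50):
            bin_id = f"b{rng.integers(0, 8)}" if rng.random() > 0.2 else None
            contigs.append(ContigRecord(f"c{i}", int(rng.integers(5001, 9000)), bin_id))
        reps = select_representative_contigs(contigs)
        bins_with_contigs = {c.bin_id for c in contigs if c.bin_id is not None}
        assert len(reps) == len(bins_with_contigs)


class TestSummarizeMapping:
    def test_overlapping_reads_union_coverage(self):
        alns = [_aln("r1", "c1", [(0, 50)]), _aln("r2", "c1", [(25, 75)])]
        (s,) = summarize_mapping(alns, {"c1": 100}, "sampleA", 1000)
        assert s.covered_bases == 75
        assert s.mapped_read_count == 2

    def test_no_alignments_zero_summary(self):
        (s,) = summarize_mapping([], {"c1": 100}, "sampleA", 1000)
        assert s.covered_bases == 0 and s.mapped_read_count == 0

    def test_secondary_alignments_not_counted(self):
        alns = [
            _aln("r1", "c1", [(0, 50)]),
            _aln("r1", "c1", [(50, 100)], primary=False),
        ]
        (s,) = summarize_mapping(alns, {"c1": 100}, "sampleA", 1000)
        assert s.mapped_read_count == 1
        assert s.covered_bases == 50

    def test_unknown_contig_error(self):
        with pytest.raises(ValueError, match="unknown contig"):
            summarize_mapping([_aln("r1", "ghost", [(0, 10)])], {"c1": 100}, "s", 10)


class TestRPKMAndCoverage:
    def test_rpkm_printed_formula(self):
        s = MappingSummary("s", "c", 4, 100, 1000, 2000)
        assert rpkm(s) == pytest.approx(2000.0)

    def test_rpkm_zero_count(self):
        assert rpkm(MappingSummary("s", "c", 0, 0, 1000, 2000)) == 0.0

    def test_rpkm_large_values(self):
        s = MappingSummary("s", "c", 10**6, 10**3, 10**6, 10**3)
        assert rpkm(s) == pytest.approx(1e6)

    def test_coverage_values(self):
        assert coverage(MappingSummary("s", "c", 1, 700, 10, 1000)) == pytest.approx(0.70)
        assert coverage(MappingSummary("s", "c", 1, 1000, 10, 1000)) == 1.0
        assert coverage(MappingSummary("s", "c", 0, 0, 10, 1000)) == 0.0

    def test_zero_denominators_error(self):
        with pytest.raises(ValueError):
            rpkm(MappingSummary("s", "c", 0, 0, 0, 100))

    def test_scale_invariance(self):
        """Doubling both read count and library size leaves RPKM unchanged."""
        a = MappingSummary("s", "c", 7, 50, 1000, 3000)
        b = MappingSummary("s", "c", 14, 50, 2000, 3000)
        assert rpkm(a) == pytest.approx(rpkm(b))


def _random_alignment_set(rng, contig_len, n_reads):
    alns = []
    for r in range(n_reads):
        start = int(rng.integers(0, max(1, contig_len - 30)))
        length = int(rng.integers(10, 30))
        end = min(start + length, contig_len)
        alns.append(_aln(f"r{r}", "c", [(start, end)]))
    return alns


def test_interval_union_matches_bitmap_oracle(rng):
    """Coverage via interval union equals a per-base bitmap on random data."""
    for _ in range(200):
        contig_len = int(rng.integers(50, 500))
        n_reads = int(rng.integers(0, 40))
        alns = _random_alignment_set(rng, contig_len, n_reads)
        (s,) = summarize_mapping(alns, {"c": contig_len}, "s", max(n_reads, 1))
        bitmap = np.zeros(contig_len, dtype=bool)
        for a in alns:
            for st_, en in a.aligned_ref_span:
                bitmap[st_:en] = True
        assert s.covered_bases == int(bitmap.sum())
        assert s.mapped_read_count == len({a.read_id for a in alns})


class TestGenomicMatrix:
    def _summaries(self, cov_frac):
        # 2 samples x 1 contig grid; contig length 1000
        covered = int(cov_frac * 1000)
        return [
            MappingSummary("s1", "c1", 40, covered, 1000, 1000),
            MappingSummary("s2", "c1", 10, 1000, 1000, 1000),
        ]

    def test_boundary_coverage_kept(self):
        m = build_genomic_matrix(self._summaries(0.70), log=False)
        assert m.values[0, 0] == pytest.approx(40 * 1e9 / (1000 * 1000))

    def test_below_boundary_zeroed(self):
        m = build_genomic_matrix(self._summaries(0.699), log=False)
        assert m.values[0, 0] == 0.0
        assert m.values[1, 0] > 0

    def test_filter_inactive_equals_log_rpkm_grid(self):
        summaries = self._summaries(0.9)
        raw = build_genomic_matrix(summaries, log=False)
        logm = build_genomic_matrix(summaries)
        assert logm.transform == "log"
        assert np.allclose(logm.values, np.log10(raw.values + 1e-6))

    def test_missing_grid_cell_error(self):
        summaries = [MappingSummary("s1", "c1", 1, 900, 10, 1000),
                     MappingSummary("s2", "c2", 1, 900, 10, 1000)]
        with pytest.raises(ValueError, match="missing mapping summary"):
            build_genomic_matrix(summaries)


def test_class_absent_contig_column_separates_classes(seq_data):
    """A contig with zero abundance in one class is (near-)zero there only."""
    from metafuse.synthetic_data import truth_genomic_matrix

    m = truth_genomic_matrix(seq_data)
    labels = seq_data.labels
    case_rows = [i for i, s in enumerate(m.sample_ids) if labels[s] == "case"]
    ctrl_rows = [i for i, s in enumerate(m.sample_ids) if labels[s] == "control"]
    # class-specific contigs: absent in one class -> log10(pseudocount) = -6
    specific_cols = [
        j
        for j in range(m.n_features)
        if (np.all(m.values[case_rows, j] == -6.0) and np.any(m.values[ctrl_rows, j] > -6.0))
        or (np.all(m.values[ctrl_rows, j] == -6.0) and np.any(m.values[case_rows, j] > -6.0))
    ]
    assert len(specific_cols) >= 2
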