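"""Genome-level abundance features from representative contigs.

The genomic modality captures strain-level signal that clade profiles miss:
a random subset of training samples ("reference samples") supplies assembled
contigs; contigs longer than 5 kb are binned, and the longest contig per bin
stands for its bin as a non-redundant representative.  Every sample's reads
are then mapped against the representatives, and each (sample, contig) cell
is the contig's RPKM

    RPKM(i, j) = mapped_reads(i, j) * 1e3 * 1e6 / (total_reads(i) * length(j))

zeroed out when breadth of coverage (covered bases / contig length) falls
below 70% — a fragment so sparsely covered is likely absent from the sample.
The resulting matrix is log10-transformed like the other modalities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .io_formats import AlignmentRecord, FeatureMatrix
from .taxonomic_features import log_transform

logger = logging.getLogger(__name__)

MIN_CONTIG_LENGTH = 5000
COVERAGE_THRESHOLD = 0.70


@dataclass
class ContigRecord:
    contig_id: str
    length: int
    bin_id: str | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"contig {self.contig_id!r}: length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"contig {self.contig_id!r}: length {self.length} != |sequence| {len(self.sequence)}"
            )


@dataclass
class MappingSummary:
    """Per-(sample, contig) mapping statistics feeding RPKM and coverage."""

    sample_id: str
    contig_id: str
    mapped_read_count: int
    covered_bases: int
    total_sample_reads: int
    contig_length: int

    def __post_init__(self) -> None:
        if self.covered_bases > self.contig_length:
            raise ValueError("covered_bases exceeds contig length")
        if self.mapped_read_count > self.total_sample_reads:
            raise ValueError("mapped_read_count exceeds total sample reads")


def select_reference_samples(sample_ids: Sequence[str], n_refs: int, seed: int) -> list[str]:
    """Uniform random subset of training samples, deterministic per seed.

    The returned subset keeps the input order.
    """
    if not 1 <= n_refs <= len(sample_ids):
        raise ValueError(f"n_refs={n_refs} out of range [1, {len(sample_ids)}]")
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(sample_ids), size=n_refs, replace=False).tolist())
    return [sample_ids[i] for i in idx]


def filter_contigs_by_length(
    contigs: Iterable[ContigRecord], min_len: int = MIN_CONTIG_LENGTH
) -> list[ContigRecord]:
    """Keep contigs strictly longer than ``min_len`` bp."""
    return [c for c in contigs if c.length > min_len]


def select_representative_contigs(contigs: Iterable[ContigRecord]) -> list[ContigRecord]:
    """One contig per bin: the longest, ties to the lexicographically smallest id.

    Unbinned contigs are excluded (logged).  Output sorted by bin id.
    """
    best: dict[str, ContigRecord] = {}
    n_unbinned = 0
    for c in contigs:
        if c.bin_id is None:
            n_unbinned += 1
            continue
        cur = best.get(c.bin_id)
        if cur is None or (c.length, _neg_id_key(c.contig_id)) > (cur.length, _neg_id_key(cur.contig_id)):
            best[c.bin_id] = c
    if n_unbinned:
        logger.info("excluded %d unbinned contigs from representative selection", n_unbinned)
    return [best[b] for b in sorted(best)]


class _neg_id_key(str):
    """Orders strings reversed so (length, key) max picks the smallest id on ties."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other) -> bool:  # type: ignore[override]
        return str.__lt__(self, other)


def _union_length(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    total = 0
    cur_s, cur_e = None, None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    total += cur_e - cur_s
    return total


def summarize_mapping(
    alignments: Iterable[AlignmentRecord],
    contigs: Sequence[ContigRecord] | Mapping[str, int],
    sample_id: str,
    total_sample_reads: int,
) -> list[MappingSummary]:
    """Collapse one sample's alignments into per-contig mapping summaries.

    Counts distinct mapped reads (primary alignments only) and the breadth of
    coverage as the union of aligned reference intervals.  Every contig gets
    a summary, zero-filled when nothing mapped.
    """
    if isinstance(contigs, Mapping):
        lengths = dict(contigs)
    else:
        lengths = {c.contig_id: c.length for c in contigs}
    reads_per_contig: dict[str, set[str]] = {cid: set() for cid in lengths}
    spans_per_contig: dict[str, list[tuple[int, int]]] = {cid: [] for cid in lengths}
    for a in alignments:
        if a.is_unmapped or not a.is_primary:
            continue
        if a.contig_id not in lengths:
            raise ValueError(f"alignment of {a.read_id!r} to unknown contig {a.contig_id!r}")
        reads_per_contig[a.contig_id].add(a.read_id)
        spans_per_contig[a.contig_id].extend(a.aligned_ref_span)
    return [
        MappingSummary(
            sample_id=sample_id,
            contig_id=cid,
            mapped_read_count=len(reads_per_contig[cid]),
            covered_bases=_union_length(spans_per_contig[cid]),
            total_sample_reads=total_sample_reads,
            contig_length=lengths[cid],
        )
        for cid in sorted(lengths)
    ]


def rpkm(s: MappingSummary) -> float:
    """Reads per kilobase of contig per million sample reads."""
    if s.total_sample_reads <= 0:
        raise ValueError("total_sample_reads must be > 0")
    if s.contig_length <= 0:
        raise ValueError("contig_length must be > 0")
    return s.mapped_read_count * 1e3 * 1e6 / (s.total_sample_reads * s.contig_length)


def coverage(s: MappingSummary) -> float:
    """Breadth of coverage: fraction of contig bases touched by >= 1 read."""
    if s.contig_length <= 0:
        raise ValueError("contig_length must be > 0")
    return s.covered_bases / s.contig_length


def build_genomic_matrix(
    summaries: Iterable[MappingSummary],
    coverage_threshold: float = COVERAGE_THRESHOLD,
    log: bool = True,
    pseudocount: float = 1e-6,
) -> FeatureMatrix:
    """RPKM grid over all (sample, contig) pairs with the coverage filter.

    A cell keeps its RPKM when coverage >= ``coverage_threshold`` and becomes
    0 otherwise (a sparsely covered fragment is treated as absent, and the
    downstream network needs dense input).  Log10 transform applied unless
    ``log=False``.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no mapping summaries given")
    sample_ids = sorted({s.sample_id for s in summaries})
    contig_ids = sorted({s.contig_id for s in summaries})
    grid: dict[tuple[str, str], MappingSummary] = {}
    for s in summaries:
        key = (s.sample_id, s.contig_id)
        if key in grid:
            raise ValueError(f"duplicate summary for {key}")
        grid[key] = s
    values = np.zeros((len(sample_ids), len(contig_ids)))
    for i, sid in enumerate(sample_ids):
        for j, cid in enumerate(contig_ids):
            s = grid.get((sid, cid))
            if s is None:
                raise ValueError(f"missing mapping summary for sample {sid!r}, contig {cid!r}")
            values[i, j] = rpkm(s) if coverage(s) >= coverage_threshold else 0.0
    m = FeatureMatrix(tuple(sample_ids), tuple(contig_ids), values, "genomic", "raw")
    return log_transform(m, pseudocount) if log else m


# ---------------------------------------------------------------------------
# File-level helpers


def read_contigs(fasta_path: str | Path, bins_path: str | Path | None = None) -> list[ContigRecord]:
    """Load contigs from FASTA, optionally attaching bin ids from a 2-col TSV."""
    bins: dict[str, str] = {}
    if bins_path is not None:
        with open(bins_path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                cid, bid = line.split("\t")[:2]
                bins[cid] = bid
    contigs = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        contigs.append(ContigRecord(rec.id, len(seq), bins.get(rec.id), seq))
    return contigs


def genomic_matrix_from_files(
    contig_fasta: str | Path,
    bins_tsv: str | Path,
    sam_paths: Mapping[str, str | Path],
    total_reads: Mapping[str, int],
    min_len: int = MIN_CONTIG_LENGTH,
    coverage_threshold: float = COVERAGE_THRESHOLD,
    log: bool = True,
) -> FeatureMatrix:
    """Full file-level genomic pipeline: contigs -> representatives -> RPKM matrix."""
    from .io_formats import read_sam

    contigs = read_contigs(contig_fasta, bins_tsv)
    reps = select_representative_contigs(filter_contigs_by_length(contigs, min_len))
    lengths = {c.contig_id: c.length for c in reps}
    summaries: list[MappingSummary] = []
    for sid, sam_path in sam_paths.items():
        alignments = read_sam(sam_path, contig_lengths=lengths)
        summaries.extend(summarize_mapping(alignments, reps, sid, total_reads[sid]))
    return build_genomic_matrix(summaries, coverage_threshold, log=log)


def read_manifest(path: str | Path) -> dict[str, int]:
    """Sample read-count manifest: TSV of sample_id, total_reads."""
    counts: dict[str, int] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            sid, n = line.split("\t")[:2]
            counts[sid] = int(n)
    return counts
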