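"""KEGG-ortholog functional abundance features.

Reads are searched against KO protein clusters; hits are kept at >= 50%
identity, >= 50% query coverage and e-value <= 1e-10, each read is assigned
its single best surviving hit (highest bit score), and per-(sample, KO) read
counts are converted to RPKM normalized by the KO's gene length.  Only KOs
matched by at least one read anywhere in the dataset become features.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .io_formats import FeatureMatrix, KOHit
from .taxonomic_features import log_transform

MIN_IDENTITY = 50.0
MIN_QUERY_COVERAGE = 50.0
MAX_EVALUE = 1.0e-10


def filter_hits(
    hits: Iterable[KOHit],
    min_identity: float = MIN_IDENTITY,
    min_qcov: float = MIN_QUERY_COVERAGE,
    max_evalue: float = MAX_EVALUE,
) -> list[KOHit]:
    """Apply the identity / query-coverage / e-value cutoffs (all inclusive)."""
    return [
        h
        for h in hits
        if h.percent_identity >= min_identity
        and h.query_coverage >= min_qcov
        and h.e_value <= max_evalue
    ]


def assign_best_hit(hits_per_read: list[KOHit]) -> KOHit | None:
    """Pick one KO per read: highest bit score, then lowest e-value, then KO id."""
    if not hits_per_read:
        return None
    read_ids = {h.read_id for h in hits_per_read}
    if len(read_ids) > 1:
        raise ValueError(f"hits from multiple reads: {sorted(read_ids)}")
    return min(hits_per_read, key=lambda h: (-h.bit_score, h.e_value, h.ko_id))


def assign_hits(hits: Iterable[KOHit]) -> dict[str, KOHit]:
    """Group filtered hits by read and assign each read its best KO."""
    by_read: dict[str, list[KOHit]] = defaultdict(list)
    for h in hits:
        by_read[h.read_id].append(h)
    return {rid: assign_best_hit(hs) for rid, hs in by_read.items()}


def ko_counts(assigned: Mapping[str, KOHit]) -> Counter:
    """Reads per KO after best-hit assignment."""
    return Counter(h.ko_id for h in assigned.values())


def build_functional_matrix(
    sample_counts: Mapping[str, Mapping[str, int]],
    gene_table: Mapping[str, int],
    total_reads: Mapping[str, int],
    log: bool = True,
    pseudocount: float = 1e-6,
) -> FeatureMatrix:
    """Per-sample KO RPKM matrix from assigned-hit read counts.

    ``sample_counts`` maps sample id -> {ko_id: read count}.  Columns are the
    KOs with at least one matched read in any sample.  A cell is
    count * 1e3 * 1e6 / (total_reads * gene_length); gene lengths come from
    ``gene_table`` (units as declared in its source file).
    """
    sample_ids = sorted(sample_counts)
    kos = sorted({ko for counts in sample_counts.values() for ko, n in counts.items() if n > 0})
    missing = [ko for ko in kos if ko not in gene_table]
    if missing:
        raise KeyError(f"KOs missing from gene-length table: {missing}")
    for sid in sample_ids:
        if sid not in total_reads:
            raise KeyError(f"sample {sid!r} missing from total-read table")
    values = np.zeros((len(sample_ids), len(kos)))
    for i, sid in enumerate(sample_ids):
        total = total_reads[sid]
        if total <= 0:
            raise ValueError(f"sample {sid!r}: total_reads must be > 0")
        counts = sample_counts[sid]
        for j, ko in enumerate(kos):
            n = counts.get(ko, 0)
            values[i, j] = n * 1e3 * 1e6 / (total * gene_table[ko])
    m = FeatureMatrix(tuple(sample_ids), tuple(kos), values, "functional", "raw")
    return log_transform(m, pseudocount) if log else m


def read_ko_gene_lengths(path: str | Path) -> dict[str, int]:
    """Two-column TSV: KO id, gene length (units declared in a '#' header)."""
    table: dict[str, int] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            ko, length = line.split("\t")[:2]
            length = int(length)
            if length < 1:
                raise ValueError(f"KO {ko!r}: gene length must be >= 1")
            table[ko] = length
    return table


def functional_matrix_from_hits(
    per_sample_hits: Mapping[str, Iterable[KOHit]],
    gene_table: Mapping[str, int],
    total_reads: Mapping[str, int],
    log: bool = True,
    **filter_kwargs,
) -> FeatureMatrix:
    """Convenience: filter -> best-hit assign -> count -> RPKM matrix."""
    sample_counts = {
        sid: ko_counts(assign_hits(filter_hits(hits, **filter_kwargs)))
        for sid, hits in per_sample_hits.items()
    }
    return build_functional_matrix(sample_counts, gene_table, total_reads, log=log)
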