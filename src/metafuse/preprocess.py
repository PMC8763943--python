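"""Read quality control and host-read decontamination.

Reads are windowed-quality trimmed at a Phred-20 threshold, reads containing
any ambiguous base (N) are dropped, and reads that align well to the host
genome are classified as contamination: a mapped read is called host when its
mismatch count is under 10% and its soft-clipped length under 30% of the read
length (both strict).  For paired data a pair is kept only when both mates
survive every filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Literal

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .io_formats import AlignmentRecord

logger = logging.getLogger(__name__)

_ALPHABET = set("ACGTN")


@dataclass
class ReadRecord:
    read_id: str
    sequence: str
    qualities: list[int]
    mate: Literal["R1", "R2", "unpaired"] = "unpaired"

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        bad = set(self.sequence.upper()) - _ALPHABET
        if bad:
            raise ValueError(f"read {self.read_id!r}: invalid bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


def quality_filter(
    read: ReadRecord, q_threshold: float = 20.0, window: int = 10
) -> ReadRecord | None:
    """Sliding-window quality trim from both ends; None when rejected.

    The trim points are located by scanning for the outermost windows whose
    mean quality reaches ``q_threshold`` and then stepping to the first base
    within them at or above the threshold, so a low-quality flank is removed
    entirely.  Reads shorter than one window after trimming are rejected.
    """
    n = len(read)
    if n == 0:
        logger.debug("read %s rejected: empty", read.read_id)
        return None
    if n < window:
        return None
    q = np.asarray(read.qualities, dtype=np.float64)
    # mean quality of every window of length `window`
    csum = np.concatenate([[0.0], np.cumsum(q)])
    means = (csum[window:] - csum[:-window]) / window
    passing = np.flatnonzero(means >= q_threshold)
    if passing.size == 0:
        return None
    left_w, right_w = int(passing[0]), int(passing[-1])
    left = left_w
    while left < left_w + window and q[left] < q_threshold:
        left += 1
    right = right_w + window  # exclusive
    while right > right_w and q[right - 1] < q_threshold:
        right -= 1
    if right - left < window:
        return None
    if left == 0 and right == n:
        return read
    return ReadRecord(
        read.read_id, read.sequence[left:right], list(read.qualities[left:right]), read.mate
    )


def drop_n_reads(read: ReadRecord) -> ReadRecord | None:
    """Reject any read whose sequence contains an N."""
    if "N" in read.sequence.upper():
        return None
    return read


def classify_host_read(a: AlignmentRecord) -> Literal["host", "non_host"]:
    """Call a read host contamination from its alignment to the host genome.

    Host iff mapped with mismatch_count < 10% and softclip_length < 30% of
    the read length (strict inequalities: a read exactly at a boundary is
    kept as non-host).  Unmapped reads cannot be contamination.
    """
    if a.is_unmapped or a.contig_id is None:
        return "non_host"
    if a.read_length == 0:
        return "non_host"
    if (
        a.mismatch_count < 0.10 * a.read_length
        and a.softclip_length < 0.30 * a.read_length
    ):
        return "host"
    return "non_host"


def preprocess_read(
    read: ReadRecord,
    host_alignment: AlignmentRecord | None = None,
    q_threshold: float = 20.0,
    window: int = 10,
) -> ReadRecord | None:
    """Full single-read pipeline: quality trim, N filter, host filter."""
    out = quality_filter(read, q_threshold=q_threshold, window=window)
    if out is None:
        return None
    out = drop_n_reads(out)
    if out is None:
        return None
    if host_alignment is not None and classify_host_read(host_alignment) == "host":
        return None
    return out


def preprocess_pairs(
    pairs: Iterable[tuple[ReadRecord, ReadRecord]],
    host_alignments: dict[str, AlignmentRecord] | None = None,
    q_threshold: float = 20.0,
    window: int = 10,
) -> Iterator[tuple[ReadRecord, ReadRecord]]:
    """Apply all filters pairwise: a pair survives only if both mates do."""
    host_alignments = host_alignments or {}
    for r1, r2 in pairs:
        out1 = preprocess_read(
            r1, host_alignments.get(r1.read_id), q_threshold=q_threshold, window=window
        )
        if out1 is None:
            continue
        out2 = preprocess_read(
            r2, host_alignments.get(r2.read_id), q_threshold=q_threshold, window=window
        )
        if out2 is None:
            continue
        yield out1, out2


# ---------------------------------------------------------------------------
# FASTQ I/O (Phred+33)


def read_fastq(path: str | Path, mate: Literal["R1", "R2", "unpaired"] = "unpaired") -> Iterator[ReadRecord]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield ReadRecord(
            rec.id, str(rec.seq).upper(), list(rec.letter_annotations["phred_quality"]), mate
        )


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for read in reads:
            rec = SeqRecord(Seq(read.sequence), id=read.read_id, description="")
            rec.letter_annotations["phred_quality"] = list(read.qualities)
            SeqIO.write(rec, fh, "fastq")
            n += 1
    return n
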