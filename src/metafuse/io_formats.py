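"""Readers, writers and the in-memory containers shared by every pipeline stage.

The pipeline exchanges four kinds of data: per-sample clade-abundance
profiles (MetaPhlAn-style TSV), read-vs-contig alignments (SAM), protein
search hits against KEGG orthologs (12-column BLAST tabular), and dense
samples x features abundance matrices (annotated TSV).  All coordinates are
0-based half-open internally; SAM's 1-based inclusive convention is converted
on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

RANKS = ("phylum", "class", "order", "family", "genus", "species")

#: MetaPhlAn clade-string prefixes, kingdom included for parsing only.
_PREFIX_TO_RANK = {
    "k__": "kingdom",
    "p__": "phylum",
    "c__": "class",
    "o__": "order",
    "f__": "family",
    "g__": "genus",
    "s__": "species",
    "t__": "strain",
}

MODALITIES = ("taxonomic", "genomic", "functional", "embedding", "fused")
TRANSFORMS = ("raw", "log")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class TaxonProfile:
    """Per-sample hierarchical clade -> proportion map (percent, 0-100)."""

    sample_id: str
    entries: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (rank, clade), value in self.entries.items():
            if rank not in RANKS:
                raise ValueError(f"unknown rank {rank!r}")
            if not clade:
                raise ValueError("empty clade name")
            if value < 0:
                raise ValueError(f"negative proportion for {clade!r}: {value}")

    def at_rank(self, rank: str) -> dict[str, float]:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return {clade: v for (r, clade), v in self.entries.items() if r == rank}


@dataclass
class AlignmentRecord:
    """One SAM alignment reduced to the fields the pipeline needs.

    ``aligned_ref_span`` holds half-open reference intervals covered by the
    alignment (CIGAR M/=/X/D ops; N splits the span).  ``read_length``
    includes soft-clipped bases.
    """

    read_id: str
    contig_id: str | None
    ref_start: int
    aligned_ref_span: list[tuple[int, int]]
    read_length: int
    mismatch_count: int
    softclip_length: int
    is_unmapped: bool = False
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.mismatch_count > self.read_length:
            raise ValueError("mismatch_count exceeds read length")
        if self.softclip_length > self.read_length:
            raise ValueError("softclip_length exceeds read length")
        for start, end in self.aligned_ref_span:
            if start < 0 or end < start:
                raise ValueError(f"bad reference interval ({start}, {end})")


@dataclass
class KOHit:
    """One filtered-searchable protein hit of a read against a KEGG ortholog."""

    read_id: str
    ko_id: str
    percent_identity: float
    query_coverage: float
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"percent_identity out of [0,100]: {self.percent_identity}")
        if not 0.0 <= self.query_coverage <= 100.0:
            raise ValueError(f"query_coverage out of [0,100]: {self.query_coverage}")
        if self.e_value < 0:
            raise ValueError(f"negative e-value: {self.e_value}")


@dataclass
class FeatureMatrix:
    """Dense samples x features abundance table, the currency between stages."""

    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    values: np.ndarray
    modality: str
    transform: str = "raw"

    def __post_init__(self) -> None:
        self.sample_ids = tuple(self.sample_ids)
        self.feature_ids = tuple(self.feature_ids)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.transform == "raw":
            if self.values.size and np.nanmin(self.values) < 0:
                raise ValueError("raw abundance values must be >= 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix values must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.feature_ids)
        )

    def equals(self, other: "FeatureMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.feature_ids == other.feature_ids
            and self.modality == other.modality
            and self.transform == other.transform
            and np.array_equal(self.values, other.values)
        )

    def select_samples(self, idx: Sequence[int]) -> "FeatureMatrix":
        idx = list(idx)
        return FeatureMatrix(
            tuple(self.sample_ids[i] for i in idx),
            self.feature_ids,
            self.values[idx, :],
            self.modality,
            self.transform,
        )

    def project(self, feature_ids: Sequence[str]) -> "FeatureMatrix":
        """Reindex onto ``feature_ids``: missing features become 0, extras drop.

        Used to put a held-out sample onto the feature space determined by the
        training fold.
        """
        pos = {f: j for j, f in enumerate(self.feature_ids)}
        out = np.zeros((self.n_samples, len(feature_ids)))
        for j, f in enumerate(feature_ids):
            if f in pos:
                out[:, j] = self.values[:, pos[f]]
        return FeatureMatrix(self.sample_ids, tuple(feature_ids), out, self.modality, self.transform)


# ---------------------------------------------------------------------------
# MetaPhlAn-style clade profiles


def read_metaphlan_profile(path: str | Path, sample_id: str | None = None) -> TaxonProfile:
    """Parse a two-column MetaPhlAn clade TSV into a :class:`TaxonProfile`.

    One entry is emitted per line for the line's *terminal* clade; kingdom and
    strain lines carry no entry.  Non-bacterial kingdoms are dropped, matching
    a profiler run with archaea/eukaryotes/viruses ignored.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    entries: dict[tuple[str, str], float] = {}
    n_data_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            clade_str, value_str = parts[0], parts[1]
            try:
                value = float(value_str)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric proportion {value_str!r}") from None
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative proportion {value}")
            n_data_lines += 1
            clades = clade_str.split("|")
            lineage = []
            for clade in clades:
                prefix, name = clade[:3], clade[3:]
                if prefix not in _PREFIX_TO_RANK:
                    raise FormatError(
                        f"{path}:{lineno}: malformed clade string {clade!r} "
                        f"(unknown rank prefix {prefix!r})"
                    )
                lineage.append((_PREFIX_TO_RANK[prefix], name))
            kingdom = next((n for r, n in lineage if r == "kingdom"), None)
            if kingdom is not None and kingdom != "Bacteria":
                continue
            rank, name = lineage[-1]
            if rank in ("kingdom", "strain"):
                continue
            if not name:
                raise FormatError(f"{path}:{lineno}: empty clade name in {clade_str!r}")
            key = (rank, name)
            if key in entries:
                raise FormatError(f"{path}:{lineno}: duplicate clade {name!r} at rank {rank}")
            entries[key] = value
    if n_data_lines == 0:
        logger.warning("empty clade profile: %s", path)
    return TaxonProfile(sample_id=sample_id, entries=entries)


# ---------------------------------------------------------------------------
# SAM alignments

# CIGAR operation codes (pysam): M=0 I=1 D=2 N=3 S=4 H=5 P=6 ==7 X=8
_REF_CONSUMING = {0, 2, 7, 8}
_QUERY_CONSUMING = {0, 1, 4, 7, 8}


def _spans_from_cigar(ref_start: int, cigartuples: list[tuple[int, int]]) -> list[tuple[int, int]]:
    spans: list[tuple[int, int]] = []
    pos = ref_start
    cur = ref_start
    for op, length in cigartuples:
        if op in _REF_CONSUMING:
            pos += length
        elif op == 3:  # N: reference skip splits the span
            if pos > cur:
                spans.append((cur, pos))
            pos += length
            cur = pos
    if pos > cur:
        spans.append((cur, pos))
    return spans


def _mismatches_from_md(md: str) -> int:
    """Count substitution positions in an MD tag (deletion runs excluded)."""
    n = 0
    i = 0
    while i < len(md):
        c = md[i]
        if c.isdigit():
            i += 1
        elif c == "^":  # deletion: skip the deleted reference bases
            i += 1
            while i < len(md) and md[i].isalpha():
                i += 1
        else:
            n += 1
            i += 1
    return n


def read_sam(
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
    require_mismatches: bool = True,
) -> list[AlignmentRecord]:
    """Read a SAM file into :class:`AlignmentRecord` objects.

    Mismatch counts come from the NM tag (minus indel lengths) when present,
    else from the MD tag; if neither is present on a mapped read and
    ``require_mismatches`` is set, that is an error.  Reference coordinates
    are converted to 0-based half-open.
    """
    path = Path(path)
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        if contig_lengths is not None:
            for name, length in zip(sam.references, sam.lengths):
                if name in contig_lengths and contig_lengths[name] != length:
                    raise FormatError(
                        f"{path}: @SQ length for {name} is {length}, "
                        f"expected {contig_lengths[name]}"
                    )
        for aln in sam:
            read_length = aln.infer_read_length() or (
                len(aln.query_sequence) if aln.query_sequence else 0
            )
            if aln.is_unmapped:
                records.append(
                    AlignmentRecord(
                        read_id=aln.query_name,
                        contig_id=None,
                        ref_start=-1,
                        aligned_ref_span=[],
                        read_length=read_length,
                        mismatch_count=0,
                        softclip_length=0,
                        is_unmapped=True,
                    )
                )
                continue
            cig = aln.cigartuples or []
            if aln.query_sequence:
                q_consumed = sum(l for op, l in cig if op in _QUERY_CONSUMING)
                if q_consumed != len(aln.query_sequence):
                    raise FormatError(
                        f"{path}: read {aln.query_name}: CIGAR consumes {q_consumed} "
                        f"query bases but sequence has {len(aln.query_sequence)}"
                    )
            softclip = sum(l for op, l in cig if op == 4)
            indel = sum(l for op, l in cig if op in (1, 2))
            if aln.has_tag("NM"):
                mism = int(aln.get_tag("NM")) - indel
                mism = max(mism, 0)
            elif aln.has_tag("MD"):
                mism = _mismatches_from_md(str(aln.get_tag("MD")))
            elif require_mismatches:
                raise FormatError(
                    f"{path}: read {aln.query_name} has neither NM nor MD tag; "
                    "cannot determine mismatch count"
                )
            else:
                mism = 0
            spans = _spans_from_cigar(aln.reference_start, cig)
            contig = aln.reference_name
            if contig_lengths is not None and contig not in contig_lengths:
                raise FormatError(f"{path}: alignment to unknown contig {contig!r}")
            if contig_lengths is not None:
                clen = contig_lengths[contig]
                for s, e in spans:
                    if e > clen:
                        raise FormatError(
                            f"{path}: read {aln.query_name} spans [{s},{e}) beyond "
                            f"contig {contig} length {clen}"
                        )
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    contig_id=contig,
                    ref_start=aln.reference_start,
                    aligned_ref_span=spans,
                    read_length=read_length,
                    mismatch_count=mism,
                    softclip_length=softclip,
                    is_unmapped=False,
                    is_primary=not (aln.is_secondary or aln.is_supplementary),
                )
            )
    return records


# ---------------------------------------------------------------------------
# DIAMOND 12-column tabular

_DIAMOND_COLS = 12


def read_diamond_hits(path: str | Path, query_lengths: Mapping[str, int]) -> list[KOHit]:
    """Read a 12-column BLAST-tabular hit file into :class:`KOHit` objects.

    The standard 12-column dialect lacks a query-coverage column, so coverage
    is computed from qstart/qend against ``query_lengths``:
    ``|qend - qstart| + 1) / query_length * 100``.
    """
    path = Path(path)
    hits: list[KOHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < _DIAMOND_COLS:
                raise FormatError(f"{path}:{lineno}: expected {_DIAMOND_COLS} columns, got {len(parts)}")
            qseqid, sseqid = parts[0], parts[1]
            try:
                pident = float(parts[2])
                qstart = int(parts[6])
                qend = int(parts[7])
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if qseqid not in query_lengths:
                raise FormatError(f"{path}:{lineno}: query {qseqid!r} missing from length table")
            qlen = query_lengths[qseqid]
            qcov = (abs(qend - qstart) + 1) / qlen * 100.0
            hits.append(
                KOHit(
                    read_id=qseqid,
                    ko_id=sseqid,
                    percent_identity=pident,
                    query_coverage=min(qcov, 100.0),
                    e_value=evalue,
                    bit_score=bitscore,
                )
            )
    return hits


def read_query_lengths(path: str | Path) -> dict[str, int]:
    """Two-column TSV: query id, length."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            qid, slen = line.split("\t")[:2]
            lengths[qid] = int(slen)
    return lengths


# ---------------------------------------------------------------------------
# FeatureMatrix TSV round-trip


def write_feature_matrix(m: FeatureMatrix, path: str | Path) -> None:
    """Write a matrix as TSV: '#key=value' metadata, header row, one row per sample.

    Values are written with ``repr`` so the read/write round-trip is exact.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#modality={m.modality}\n")
        fh.write(f"#transform={m.transform}\n")
        fh.write("sample_id\t" + "\t".join(m.feature_ids) + "\n")
        for i, sid in enumerate(m.sample_ids):
            fh.write(sid + "\t" + "\t".join(repr(float(v)) for v in m.values[i]) + "\n")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    meta = {"modality": "taxonomic", "transform": "raw"}
    sample_ids: list[str] = []
    rows: list[list[float]] = []
    feature_ids: tuple[str, ...] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line[1:].partition("=")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split("\t")
            if feature_ids is None:
                if parts[0] != "sample_id":
                    raise FormatError(f"{path}:{lineno}: header must start with 'sample_id'")
                feature_ids = tuple(parts[1:])
                if len(set(feature_ids)) != len(feature_ids):
                    raise FormatError(f"{path}: duplicate feature ids in header")
                continue
            sid = parts[0]
            if sid in sample_ids:
                raise FormatError(f"{path}:{lineno}: duplicate sample id {sid!r}")
            if len(parts) - 1 != len(feature_ids):
                raise FormatError(
                    f"{path}:{lineno}: row has {len(parts) - 1} values, expected {len(feature_ids)}"
                )
            sample_ids.append(sid)
            rows.append([float(v) for v in parts[1:]])
    if feature_ids is None:
        raise FormatError(f"{path}: missing header row")
    values = np.array(rows, dtype=np.float64) if rows else np.empty((0, len(feature_ids)))
    return FeatureMatrix(
        tuple(sample_ids), feature_ids, values, meta["modality"], meta["transform"]
    )
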