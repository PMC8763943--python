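"""Rank-level taxonomic feature matrices from per-sample clade profiles.

For a chosen rank (phylum ... species) the feature space is the union of
clades observed across samples; each cell is that sample's relative-abundance
percentage for the clade, zero when absent.  Genus- and species-level tables
are pruned of clades seen in at most one sample (likely sample-specific), and
proportions are log10-transformed with a small pseudocount before entering a
neural network.
"""

from __future__ import annotations

import numpy as np

from .io_formats import RANKS, FeatureMatrix, TaxonProfile

#: Ranks at which the single-sample prevalence filter applies by default.
DEFAULT_FILTER_RANKS = ("genus", "species")


def build_rank_table(profiles: list[TaxonProfile], rank: str) -> FeatureMatrix:
    """Assemble the samples x clades abundance matrix at one rank.

    Columns are the union of clade names observed at ``rank`` over all
    profiles, in sorted order; a sample missing a clade gets 0.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; choose from {RANKS}")
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to build a rank table")
    sample_ids = [p.sample_id for p in profiles]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids among profiles")
    clades = sorted({clade for p in profiles for clade in p.at_rank(rank)})
    values = np.zeros((len(profiles), len(clades)))
    col = {c: j for j, c in enumerate(clades)}
    for i, p in enumerate(profiles):
        for clade, v in p.at_rank(rank).items():
            values[i, col[clade]] = v
    return FeatureMatrix(tuple(sample_ids), tuple(clades), values, "taxonomic", "raw")


def filter_single_sample_taxa(m: FeatureMatrix) -> FeatureMatrix:
    """Drop clades present (nonzero) in at most one sample.

    Idempotent; preserves column order of the survivors.
    """
    if m.modality != "taxonomic":
        raise ValueError("prevalence filter applies to taxonomic matrices")
    if m.transform != "raw":
        raise ValueError("prevalence filter must run before log transform")
    keep = np.count_nonzero(m.values, axis=0) > 1
    return FeatureMatrix(
        m.sample_ids,
        tuple(f for f, k in zip(m.feature_ids, keep) if k),
        m.values[:, keep],
        m.modality,
        m.transform,
    )


def log_transform(m: FeatureMatrix, pseudocount: float = 1e-6) -> FeatureMatrix:
    """log10(x + pseudocount), marking the matrix as transformed.

    The pseudocount maps exact zeros to log10(pseudocount) (-6 by default)
    rather than -inf; strictly monotone, so sample ordering within each
    feature is preserved.
    """
    if m.transform != "raw":
        raise ValueError(f"matrix already has transform={m.transform!r}")
    if m.values.size and m.values.min() < 0:
        raise ValueError("cannot log-transform negative abundances")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    with np.errstate(divide="raise"):
        values = np.log10(m.values + pseudocount)
    return FeatureMatrix(m.sample_ids, m.feature_ids, values, m.modality, "log")
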