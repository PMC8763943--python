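"""Synthetic inputs for every pipeline stage, with known ground truth.

Two generators cover the two entry points of the pipeline:

* :func:`generate_feature_dataset` draws labeled class-conditional Gaussian
  feature matrices for the three modalities — informative features get a
  between-class mean shift expressed in units of the within-class standard
  deviation, the rest are pure noise.  Values are exponentiated (base 10) so
  they behave like raw non-negative abundances and the pipeline's log10
  transform approximately recovers the Gaussians.

* :func:`generate_sequence_dataset` emits the file-level inputs: random DNA
  contigs grouped into bins, error-free reads drawn per sample from a
  class-dependent Dirichlet abundance over the representative contigs and
  written as SAM alignments, MetaPhlAn-style clade profiles, KEGG-ortholog
  hit tables with a gene-length table, and TSV manifests.  Ground-truth
  per-(sample, contig) read counts and covered bases are recorded during
  generation so downstream bookkeeping can be checked exactly.

Class signal in the sequence data comes from contigs and orthologs that are
present in one class and absent (abundance zero) in the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import FeatureMatrix

_DNA = np.array(list("ACGT"))


@dataclass
class ModalitySpec:
    n_features: int = 100
    n_informative: int = 10
    effect_size: float = 2.0  # between-class mean shift, in units of noise_sd
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative must be <= n_features")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


@dataclass
class SequenceSpec:
    n_contigs: int = 30
    contigs_per_bin: int = 1
    contig_length_range: tuple[int, int] = (5500, 9000)
    read_length: int = 100
    reads_per_sample: int = 2500
    dirichlet_concentration: float = 5.0
    n_class_specific_contigs: int = 4
    class_specific_boost: float = 3.0
    error_rate: float = 0.0
    n_species: int = 8
    n_kos: int = 40
    ko_length_range: tuple[int, int] = (300, 1500)
    ko_hit_fraction: float = 0.5
    n_class_specific_kos: int = 6
    decoy_fraction: float = 0.1


@dataclass
class SyntheticSpec:
    n_samples_per_class: int = 10
    n_classes: int = 2
    modalities: dict[str, ModalitySpec] = field(
        default_factory=lambda: {
            "taxonomic": ModalitySpec(),
            "genomic": ModalitySpec(),
            "functional": ModalitySpec(),
        }
    )
    sequence: SequenceSpec = field(default_factory=SequenceSpec)
    seed: int = 0


def _labels(spec: SyntheticSpec) -> list[str]:
    if spec.n_classes == 2:
        names = ["case", "control"]
    else:
        names = [f"class{k}" for k in range(spec.n_classes)]
    return [names[k] for k in range(spec.n_classes) for _ in range(spec.n_samples_per_class)]


def generate_feature_dataset(
    spec: SyntheticSpec,
) -> tuple[dict[str, FeatureMatrix], list[str]]:
    """Labeled Gaussian feature matrices, one per modality, raw scale.

    The first ``n_informative`` features of each modality carry the class
    signal; class k's mean for those features is ``k * effect_size *
    noise_sd`` on the log scale.  Deterministic for a given spec seed.
    """
    labels = _labels(spec)
    n = len(labels)
    sample_ids = tuple(f"S{i:03d}" for i in range(n))
    class_idx = np.repeat(np.arange(spec.n_classes), spec.n_samples_per_class)
    streams = np.random.SeedSequence(spec.seed).spawn(len(spec.modalities))
    matrices: dict[str, FeatureMatrix] = {}
    for stream, (name, mod) in zip(streams, spec.modalities.items()):
        rng = np.random.default_rng(stream)
        z = rng.normal(0.0, mod.noise_sd, size=(n, mod.n_features))
        shift = mod.effect_size * mod.noise_sd
        for k in range(spec.n_classes):
            z[class_idx == k, : mod.n_informative] += k * shift
        modality = name if name in ("taxonomic", "genomic", "functional") else "taxonomic"
        matrices[name] = FeatureMatrix(
            sample_ids,
            tuple(f"{name}_f{j:04d}" for j in range(mod.n_features)),
            np.power(10.0, z),
            modality,
            "raw",
        )
    return matrices, labels


@dataclass
class SyntheticSequenceData:
    """Paths and ground truth emitted by :func:`generate_sequence_dataset`."""

    out_dir: Path
    contig_fasta: Path
    bins_tsv: Path
    sam_paths: dict[str, Path]
    manifest_tsv: Path
    labels_tsv: Path
    profile_paths: dict[str, Path]
    ko_hit_paths: dict[str, Path]
    ko_lengths_tsv: Path
    query_length_paths: dict[str, Path]
    truth_tsv: Path
    labels: dict[str, str]
    representative_contigs: list[str]
    contig_lengths: dict[str, int]
    #: (sample, contig) -> (read count, covered bases)
    truth_counts: dict[tuple[str, str], tuple[int, int]]
    #: (sample, ko) -> read count surviving the hit filters
    ko_truth_counts: dict[tuple[str, str], int]
    ko_lengths: dict[str, int]
    reads_per_sample: int


def _union_length(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    total, cur_s, cur_e = 0, None, None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def _class_abundances(
    rng: np.random.Generator,
    n_items: int,
    n_classes: int,
    concentration: float,
    n_specific: int,
    boost: float,
) -> np.ndarray:
    """Per-class Dirichlet abundance vectors with class-exclusive items.

    The first ``n_classes * n_specific`` items are split into blocks; block k
    is present only in class k (boosted weight) and has zero abundance in
    every other class.
    """
    if n_classes * n_specific > n_items:
        raise ValueError("too many class-specific items for the item count")
    out = np.zeros((n_classes, n_items))
    for k in range(n_classes):
        alpha = np.full(n_items, concentration)
        alpha[: n_classes * n_specific] *= boost
        vec = rng.dirichlet(alpha)
        for other in range(n_classes):
            if other != k:
                vec[other * n_specific : (other + 1) * n_specific] = 0.0
        out[k] = vec / vec.sum()
    return out


def generate_sequence_dataset(spec: SyntheticSpec, out_dir: str | Path) -> SyntheticSequenceData:
    """Write the full set of file inputs plus ground truth under ``out_dir``."""
    seq = spec.sequence
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = _labels(spec)
    sample_ids = [f"S{i:03d}" for i in range(len(labels))]
    class_idx = np.repeat(np.arange(spec.n_classes), spec.n_samples_per_class)
    streams = np.random.SeedSequence(spec.seed).spawn(6)
    rng_contig = np.random.default_rng(streams[0])
    rng_abund = np.random.default_rng(streams[1])
    rng_reads = np.random.default_rng(streams[2])
    rng_taxa = np.random.default_rng(streams[3])
    rng_ko = np.random.default_rng(streams[4])

    lo, hi = seq.contig_length_range
    if seq.read_length > lo:
        raise ValueError(
            f"read_length {seq.read_length} exceeds shortest possible contig {lo}"
        )

    # ---- contigs and bins -------------------------------------------------
    n_total = seq.n_contigs * seq.contigs_per_bin
    contig_ids = [f"contig_{j:04d}" for j in range(n_total)]
    lengths = rng_contig.integers(lo, hi + 1, size=n_total)
    sequences = ["".join(rng_contig.choice(_DNA, size=L)) for L in lengths]
    seq_of = dict(zip(contig_ids, sequences))
    bin_of = {cid: f"bin_{j // seq.contigs_per_bin:03d}" for j, cid in enumerate(contig_ids)}
    contig_fasta = out / "contigs.fasta"
    with open(contig_fasta, "w") as fh:
        for cid, s in zip(contig_ids, sequences):
            fh.write(f">{cid}\n")
            for k in range(0, len(s), 80):
                fh.write(s[k : k + 80] + "\n")
    bins_tsv = out / "bins.tsv"
    with open(bins_tsv, "w") as fh:
        for cid in contig_ids:
            fh.write(f"{cid}\t{bin_of[cid]}\n")

    # representatives: longest per bin, ties to smallest id (mirrors pipeline)
    length_of = {cid: int(L) for cid, L in zip(contig_ids, lengths)}
    reps: dict[str, str] = {}
    for cid in contig_ids:
        b = bin_of[cid]
        cur = reps.get(b)
        if (
            cur is None
            or length_of[cid] > length_of[cur]
            or (length_of[cid] == length_of[cur] and cid < cur)
        ):
            reps[b] = cid
    rep_ids = sorted(reps.values())
    rep_lengths = {cid: length_of[cid] for cid in rep_ids}

    abund = _class_abundances(
        rng_abund,
        len(rep_ids),
        spec.n_classes,
        seq.dirichlet_concentration,
        seq.n_class_specific_contigs,
        seq.class_specific_boost,
    )

    # ---- reads, SAM, truth ------------------------------------------------
    sam_paths: dict[str, Path] = {}
    truth_counts: dict[tuple[str, str], tuple[int, int]] = {}
    sam_dir = out / "sam"
    sam_dir.mkdir(exist_ok=True)
    rl = seq.read_length
    for sid, k in zip(sample_ids, class_idx):
        counts = rng_reads.multinomial(seq.reads_per_sample, abund[k])
        path = sam_dir / f"{sid}.sam"
        sam_paths[sid] = path
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            for cid in rep_ids:
                fh.write(f"@SQ\tSN:{cid}\tLN:{rep_lengths[cid]}\n")
            read_no = 0
            for cid, n_reads in zip(rep_ids, counts):
                L = rep_lengths[cid]
                cseq = seq_of[cid]
                starts = rng_reads.integers(0, L - rl + 1, size=n_reads)
                intervals = [(int(s), int(s) + rl) for s in starts]
                truth_counts[(sid, cid)] = (int(n_reads), _union_length(intervals))
                for s in sorted(intervals):
                    read_seq = cseq[s[0] : s[0] + rl]
                    nm = 0
                    if seq.error_rate > 0:
                        read_arr = np.array(list(read_seq))
                        err = rng_reads.random(rl) < seq.error_rate
                        for pos in np.flatnonzero(err):
                            choices = [b for b in "ACGT" if b != read_arr[pos]]
                            read_arr[pos] = rng_reads.choice(choices)
                        nm = int(err.sum())
                        read_seq = "".join(read_arr)
                    rid = f"{sid}_r{read_no:06d}"
                    read_no += 1
                    fh.write(
                        f"{rid}\t0\t{cid}\t{s[0] + 1}\t60\t{rl}M\t*\t0\t0\t"
                        f"{read_seq}\t{'I' * rl}\tNM:i:{nm}\n"
                    )

    manifest_tsv = out / "manifest.tsv"
    with open(manifest_tsv, "w") as fh:
        fh.write("#sample_id\ttotal_reads\n")
        for sid in sample_ids:
            fh.write(f"{sid}\t{seq.reads_per_sample}\n")
    labels_tsv = out / "labels.tsv"
    with open(labels_tsv, "w") as fh:
        fh.write("#sample_id\tlabel\n")
        for sid, lab in zip(sample_ids, labels):
            fh.write(f"{sid}\t{lab}\n")
    truth_tsv = out / "truth_counts.tsv"
    with open(truth_tsv, "w") as fh:
        fh.write("#sample_id\tcontig_id\tread_count\tcovered_bases\n")
        for (sid, cid), (n_reads, cov) in sorted(truth_counts.items()):
            fh.write(f"{sid}\t{cid}\t{n_reads}\t{cov}\n")

    # ---- MetaPhlAn-style clade profiles ----------------------------------
    profile_paths = _write_profiles(
        out, rng_taxa, sample_ids, class_idx, spec.n_classes, seq
    )

    # ---- KO hit tables ----------------------------------------------------
    ko_hit_paths, query_length_paths, ko_lengths, ko_truth_counts = _write_ko_hits(
        out, rng_ko, sample_ids, class_idx, spec.n_classes, seq
    )
    ko_lengths_tsv = out / "ko_lengths.tsv"
    with open(ko_lengths_tsv, "w") as fh:
        fh.write("#ko_id\tgene_length_nt\n")
        for ko, L in sorted(ko_lengths.items()):
            fh.write(f"{ko}\t{L}\n")

    return SyntheticSequenceData(
        out_dir=out,
        contig_fasta=contig_fasta,
        bins_tsv=bins_tsv,
        sam_paths=sam_paths,
        manifest_tsv=manifest_tsv,
        labels_tsv=labels_tsv,
        profile_paths=profile_paths,
        ko_hit_paths=ko_hit_paths,
        ko_lengths_tsv=ko_lengths_tsv,
        query_length_paths=query_length_paths,
        truth_tsv=truth_tsv,
        labels=dict(zip(sample_ids, labels)),
        representative_contigs=rep_ids,
        contig_lengths={cid: int(L) for cid, L in zip(contig_ids, lengths)},
        truth_counts=truth_counts,
        ko_truth_counts=ko_truth_counts,
        ko_lengths=ko_lengths,
        reads_per_sample=seq.reads_per_sample,
    )


def _write_profiles(out, rng, sample_ids, class_idx, n_classes, seq) -> dict[str, Path]:
    """Small fake bacterial taxonomy with class-dependent species proportions."""
    n_sp = seq.n_species
    species = [f"Species_{i}" for i in range(n_sp)]
    genus = [f"Genus_{i // 2}" for i in range(n_sp)]
    family = [f"Family_{i // 4}" for i in range(n_sp)]
    order = [f"Order_{i // 4}" for i in range(n_sp)]
    clazz = [f"Class_{i // 4}" for i in range(n_sp)]
    phylum = [f"Phylum_{i // 4}" for i in range(n_sp)]
    base = rng.dirichlet(np.full(n_sp, 5.0), size=n_classes)
    # tilt: each class favors its own block of species
    for k in range(n_classes):
        tilt = np.ones(n_sp)
        block = max(1, n_sp // n_classes)
        tilt[k * block : (k + 1) * block] = 3.0
        base[k] = base[k] * tilt
        base[k] /= base[k].sum()
    prof_dir = out / "profiles"
    prof_dir.mkdir(exist_ok=True)
    paths: dict[str, Path] = {}
    for sid, k in zip(sample_ids, class_idx):
        props = rng.dirichlet(base[k] * 50.0) * 100.0
        path = prof_dir / f"{sid}.tsv"
        paths[sid] = path
        with open(path, "w") as fh:
            fh.write("#clade_name\trelative_abundance\n")
            fh.write("k__Bacteria\t100.0\n")
            for rank_names, prefix_chain in (
                (phylum, ("p__",)),
                (clazz, ("p__", "c__")),
                (order, ("p__", "c__", "o__")),
                (family, ("p__", "c__", "o__", "f__")),
                (genus, ("p__", "c__", "o__", "f__", "g__")),
                (species, ("p__", "c__", "o__", "f__", "g__", "s__")),
            ):
                agg: dict[str, float] = {}
                lineage_of: dict[str, list[str]] = {}
                for i in range(n_sp):
                    chain_names = [phylum[i], clazz[i], order[i], family[i], genus[i], species[i]]
                    key = rank_names[i]
                    agg[key] = agg.get(key, 0.0) + props[i]
                    lineage_of[key] = chain_names[: len(prefix_chain)]
                for key in sorted(agg):
                    clade = "k__Bacteria|" + "|".join(
                        p + n for p, n in zip(prefix_chain, lineage_of[key])
                    )
                    fh.write(f"{clade}\t{agg[key]:.6f}\n")
    return paths


def _write_ko_hits(out, rng, sample_ids, class_idx, n_classes, seq):
    """DIAMOND-style 12-column hit tables with class-dependent KO usage."""
    kos = [f"K{j + 1:05d}" for j in range(seq.n_kos)]
    lo, hi = seq.ko_length_range
    ko_lengths = {ko: int(rng.integers(lo, hi + 1)) for ko in kos}
    abund = _class_abundances(
        rng, seq.n_kos, n_classes, 5.0, seq.n_class_specific_kos, seq.class_specific_boost
    )
    hits_dir = out / "ko_hits"
    hits_dir.mkdir(exist_ok=True)
    hit_paths: dict[str, Path] = {}
    qlen_paths: dict[str, Path] = {}
    truth: dict[tuple[str, str], int] = {}
    rl = seq.read_length
    for sid, k in zip(sample_ids, class_idx):
        n_hit_reads = int(round(seq.ko_hit_fraction * seq.reads_per_sample))
        counts = rng.multinomial(n_hit_reads, abund[k])
        hit_path = hits_dir / f"{sid}.tsv"
        qlen_path = hits_dir / f"{sid}.lengths.tsv"
        hit_paths[sid], qlen_paths[sid] = hit_path, qlen_path
        read_no = 0
        with open(hit_path, "w") as fh, open(qlen_path, "w") as qh:
            for ko, n in zip(kos, counts):
                if n > 0:
                    truth[(sid, ko)] = int(n)
                for _ in range(n):
                    rid = f"{sid}_q{read_no:06d}"
                    read_no += 1
                    qh.write(f"{rid}\t{rl}\n")
                    pident = 60.0 + 39.0 * rng.random()
                    bits = 100.0 + 200.0 * rng.random()
                    fh.write(
                        f"{rid}\t{ko}\t{pident:.1f}\t{rl // 3}\t0\t0\t1\t{rl}\t1\t"
                        f"{rl // 3}\t1e-30\t{bits:.1f}\n"
                    )
                    if rng.random() < seq.decoy_fraction:
                        # below-threshold competing hit; must be filtered out
                        other = kos[int(rng.integers(0, seq.n_kos))]
                        fh.write(
                            f"{rid}\t{other}\t{30.0 + 10.0 * rng.random():.1f}\t{rl // 3}"
                            f"\t5\t1\t1\t{rl}\t1\t{rl // 3}\t1e-5\t{bits + 50.0:.1f}\n"
                        )
    return hit_paths, qlen_paths, ko_lengths, truth


def truth_genomic_matrix(
    data: SyntheticSequenceData, coverage_threshold: float = 0.70, pseudocount: float = 1e-6
) -> FeatureMatrix:
    """Genomic matrix computed directly from the generator's ground truth.

    Applies the RPKM and breadth-of-coverage formulas to the true read counts
    and covered bases, independently of any SAM parsing — the oracle against
    which the real pipeline's matrix is compared.
    """
    sample_ids = sorted({sid for sid, _ in data.truth_counts})
    contig_ids = sorted(data.representative_contigs)
    values = np.zeros((len(sample_ids), len(contig_ids)))
    for i, sid in enumerate(sample_ids):
        for j, cid in enumerate(contig_ids):
            n_reads, covered = data.truth_counts.get((sid, cid), (0, 0))
            length = data.contig_lengths[cid]
            if covered / length >= coverage_threshold:
                values[i, j] = n_reads * 1e3 * 1e6 / (data.reads_per_sample * length)
    values = np.log10(values + pseudocount)
    return FeatureMatrix(tuple(sample_ids), tuple(contig_ids), values, "genomic", "log")


def generate_complementary_dataset(
    n_samples_per_class: int = 30,
    n_modalities: int = 3,
    n_features: int = 100,
    n_informative: int = 10,
    effect_size: float = 5.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[dict[str, FeatureMatrix], list[str], list[int]]:
    """Dataset where each modality separates only its own disjoint sample subset.

    Samples are split (stratified by class) into ``n_modalities`` disjoint
    subsets; modality m's informative features carry the class shift only for
    subset m's samples and are pure noise for everyone else.  A classifier on
    one modality can therefore resolve at most its own subset, while the
    fused representation contains the signal for all samples.  Returns the
    matrices, labels, and each sample's subset index.
    """
    n = 2 * n_samples_per_class
    labels = ["case"] * n_samples_per_class + ["control"] * n_samples_per_class
    class_idx = np.array([0] * n_samples_per_class + [1] * n_samples_per_class)
    # stratified round-robin subset assignment
    subsets = [i % n_modalities for i in range(n_samples_per_class)] * 2
    sample_ids = tuple(f"S{i:03d}" for i in range(n))
    streams = np.random.SeedSequence(seed).spawn(n_modalities)
    names = ["taxonomic", "genomic", "functional"][:n_modalities] + [
        f"extra{m}" for m in range(3, n_modalities)
    ]
    matrices: dict[str, FeatureMatrix] = {}
    for m, (stream, name) in enumerate(zip(streams, names)):
        rng = np.random.default_rng(stream)
        z = rng.normal(0.0, noise_sd, size=(n, n_features))
        for i in range(n):
            if subsets[i] == m and class_idx[i] == 0:
                z[i, :n_informative] += effect_size * noise_sd
        modality = name if name in ("taxonomic", "genomic", "functional") else "taxonomic"
        matrices[name] = FeatureMatrix(
            sample_ids,
            tuple(f"{name}_f{j:04d}" for j in range(n_features)),
            np.power(10.0, z),
            modality,
            "raw",
        )
    return matrices, labels, subsets


SMALL_PRESET = SyntheticSpec(n_samples_per_class=10)

LARGE_PRESET = SyntheticSpec(
    n_samples_per_class=100,
    sequence=SequenceSpec(
        n_contigs=200,
        reads_per_sample=20000,
        n_kos=400,
        n_species=32,
    ),
)
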