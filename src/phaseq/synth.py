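"""Synthetic inputs with known ground truth for the whole pipeline.

Emulates the study's data regime: a small multi-replicon bacterial genome
(the organism modelled, Ralstonia eutropha H16, carries three circular
replicons), 36-bp single-end alignments with controlled per-gene expression,
multimapping multiplicity, mismatch fraction and a dominant rRNA read
fraction (72-89% of reads in the real libraries map to rrn operons despite
rRNA depletion), two technical replicates per condition, and GC-MS
mass-isotopomer spectra following a per-carbon binomial labelling model with
multiplicative measurement noise.

No aligner is invoked: alignment records are generated directly, which keeps
every downstream stage deterministic and download-free. Multi-hit reads are
emitted as repeated-QNAME records (primary + secondary), the dialect a
BWA-era consumer must handle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .quant import CDSFeature, GenomeAnnotation

READ_LENGTH = 36


class SizingError(ValueError):
    """Requested features do not fit on the requested replicons."""


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic experiment.

    Defaults mirror the study conditions: four sampling phases
    (growth F16, PHA production F26, stationary F36, octanoate O26), two
    technical replicates each, 36-bp single-end reads, five rrn regions and
    an 80% rRNA read fraction (mid observed range).
    """

    n_replicons: int = 3
    n_genes: int = 60
    gene_length_range: tuple[int, int] = (300, 1500)
    n_rrn_regions: int = 5
    conditions: tuple[str, ...] = ("F16", "F26", "F36", "O26")
    replicates_per_condition: int = 2
    reads_per_sample: int = 20_000
    rrna_read_fraction: float = 0.80
    multimap_fraction: float = 0.05
    max_loci_per_read: int = 3
    mismatch_fraction: float = 0.05
    read_length: int = READ_LENGTH
    rrn_region_length: int = 5000
    replicon_length: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rrna_read_fraction", "multimap_fraction", "mismatch_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.rrna_read_fraction + self.mismatch_fraction > 1.0:
            raise ValueError(
                "rrna_read_fraction + mismatch_fraction > 1: the read classes "
                "are disjoint"
            )
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        if self.gene_length_range[0] < self.read_length:
            raise ValueError("gene lengths must be >= read length")
        if self.max_loci_per_read < 2:
            raise ValueError("max_loci_per_read must be >= 2")
        if self.n_rrn_regions > 0 and self.rrn_region_length < self.read_length:
            raise ValueError("rrn_region_length must be >= read length")


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def generate_annotation(config: SynthConfig) -> GenomeAnnotation:
    """Lay out non-overlapping CDS and rrn intervals on the replicons.

    The first rrn interval is stored with reversed (high-to-low) coordinate
    order, as real exclusion lists sometimes are, to exercise downstream
    normalisation. Deterministic in ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 0xA1])
    lo, hi = config.gene_length_range
    gene_lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    gene_replicon = np.arange(config.n_genes) % config.n_replicons
    rrn_replicon = np.arange(config.n_rrn_regions) % config.n_replicons

    replicon_names = [f"replicon{i + 1}" for i in range(config.n_replicons)]
    cursors = {name: 1 for name in replicon_names}
    cds: list[CDSFeature] = []
    for i in range(config.n_genes):
        rep = replicon_names[gene_replicon[i]]
        gap = int(rng.integers(50, 301))
        start = cursors[rep] + gap
        end = start + int(gene_lengths[i]) - 1
        strand = "+" if rng.random() < 0.5 else "-"
        cds.append(CDSFeature(f"gene{i + 1:04d}", rep, start, end, strand))
        cursors[rep] = end + 1

    rrna_raw: list[tuple[str, int, int]] = []
    for j in range(config.n_rrn_regions):
        rep = replicon_names[rrn_replicon[j]]
        gap = int(rng.integers(200, 501))
        start = cursors[rep] + gap
        end = start + config.rrn_region_length - 1
        cursors[rep] = end + 1
        if j == 0:
            rrna_raw.append((rep, end, start))  # reversed on purpose
        else:
            rrna_raw.append((rep, start, end))

    replicons = []
    for name in replicon_names:
        needed = cursors[name] + 200
        if config.replicon_length is not None:
            if needed > config.replicon_length:
                raise SizingError(
                    f"{name}: features need {needed} bp but replicon_length="
                    f"{config.replicon_length}"
                )
            replicons.append((name, config.replicon_length))
        else:
            replicons.append((name, needed))
    return GenomeAnnotation(replicons, cds, rrna_raw, rrna_intervals_raw=rrna_raw)


# ---------------------------------------------------------------------------
# Expression profiles
# ---------------------------------------------------------------------------

@dataclass
class ExpressionProfile:
    """Ground-truth expression: expected reads per base, gene x condition."""

    true_level: pd.DataFrame  # genes x conditions, nonnegative
    fold_change_map: dict[tuple[str, str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.true_level.values < 0).any():
            raise ValueError("true_level must be nonnegative")

    def set_fold_change(self, gene: str, numerator: str, denominator: str,
                        fold: float) -> None:
        """Program level[gene, numerator] = fold * level[gene, denominator]."""
        base = self.true_level.loc[gene, denominator]
        if base <= 0:
            raise ValueError(f"{gene} has zero level in {denominator}")
        self.true_level.loc[gene, numerator] = fold * base
        self.fold_change_map[(gene, numerator, denominator)] = fold


def default_profile(annotation: GenomeAnnotation, config: SynthConfig) -> ExpressionProfile:
    """Lognormal expression levels with silent, weak and high genes.

    The first gene is silent (level 0 everywhere), the second weak, the
    third high, guaranteeing at least one gene per expression category;
    remaining genes draw lognormal levels independently per condition.
    """
    rng = np.random.default_rng([config.seed, 0xE7])
    genes = annotation.gene_ids()
    n = len(genes)
    levels = rng.lognormal(mean=0.0, sigma=1.0,
                           size=(n, len(config.conditions)))
    levels[0, :] = 0.0          # silent
    levels[1, :] = 0.01         # weak
    levels[2, :] = 50.0         # high
    df = pd.DataFrame(levels, index=genes, columns=list(config.conditions))
    return ExpressionProfile(df)


# ---------------------------------------------------------------------------
# Alignment simulation
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    """Ground truth for one simulated sample."""

    condition: str
    replicate: int
    per_gene_counts: pd.Series        # origin-gene counts of all genic reads
    per_gene_clean_counts: pd.Series  # excluding mismatched reads
    read_loci: dict[str, list[tuple[str, int, int]]]
    rrna_reads: set[str]
    mismatched_reads: set[str]

    @property
    def n_rrna(self) -> int:
        return len(self.rrna_reads)


def _sam_header(annotation: GenomeAnnotation) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": name, "LN": length} for name, length in annotation.replicons],
        }
    )


def simulate_alignments(
    annotation: GenomeAnnotation,
    profile: ExpressionProfile,
    config: SynthConfig,
    condition: str,
    replicate: int,
    out_sam: str | Path,
) -> TruthRecord:
    """Write a SAM file of simulated 36-bp single-end alignments.

    Reads fall into disjoint classes: rRNA-derived (placed uniformly in rrn
    intervals), mismatched genic (NM=1, to be discarded downstream) and clean
    genic. A fraction of the clean genic reads is multimapped: the same
    QNAME is emitted at k uniformly chosen gene loci (one primary record,
    k-1 secondary). Genic origins are sampled proportionally to
    true_level x placeable positions; placement within a gene is uniform.
    Deterministic in (config.seed, condition, replicate).
    """
    if condition not in profile.true_level.columns:
        raise KeyError(f"unknown condition {condition!r}")
    cond_idx = list(profile.true_level.columns).index(condition)
    rng = np.random.default_rng([config.seed, 0x5A, cond_idx, replicate])

    genes = [f for f in annotation.cds if f.length >= config.read_length]
    levels = profile.true_level.loc[[f.gene_id for f in genes], condition].to_numpy()
    placeable = np.array([f.length - config.read_length + 1 for f in genes], dtype=float)
    weights = levels * placeable
    total_w = weights.sum()
    rrn = annotation.rrna_intervals

    n = config.reads_per_sample
    u = rng.random(n)
    is_rrna = u < config.rrna_read_fraction
    if rrn == [] or not len(rrn):
        if config.rrna_read_fraction > 0:
            raise ValueError("rrna_read_fraction > 0 but annotation has no rrn regions")
        is_rrna[:] = False
    is_mismatch = (~is_rrna) & (
        u < config.rrna_read_fraction + config.mismatch_fraction
    )
    if total_w <= 0 and (~is_rrna).any():
        raise ValueError(f"no expressed gene long enough in condition {condition!r}")

    per_gene = pd.Series(0, index=annotation.gene_ids(), dtype=int)
    per_gene_clean = per_gene.copy()
    read_loci: dict[str, list[tuple[str, int, int]]] = {}
    rrna_reads: set[str] = set()
    mismatched_reads: set[str] = set()

    header = _sam_header(annotation)
    gene_probs = weights / total_w if total_w > 0 else None
    with pysam.AlignmentFile(str(out_sam), "w", header=header) as out:
        for i in range(n):
            qname = f"{condition}_r{replicate}_{i:07d}"
            if is_rrna[i]:
                rep, start, end = rrn[int(rng.integers(len(rrn)))]
                pos = int(rng.integers(start, end - config.read_length + 2))
                loci = [(rep, pos, 0)]
                rrna_reads.add(qname)
            else:
                gi = int(rng.choice(len(genes), p=gene_probs))
                origin = genes[gi]
                per_gene[origin.gene_id] += 1
                nm = 1 if is_mismatch[i] else 0
                if nm:
                    mismatched_reads.add(qname)
                else:
                    per_gene_clean[origin.gene_id] += 1
                pos = int(rng.integers(
                    origin.start, origin.end - config.read_length + 2))
                loci = [(origin.replicon, pos, nm)]
                if nm == 0 and rng.random() < config.multimap_fraction:
                    k = int(rng.integers(2, config.max_loci_per_read + 1))
                    extra = rng.choice(len(genes), size=k - 1, replace=False)
                    for gj in extra:
                        g = genes[int(gj)]
                        p2 = int(rng.integers(
                            g.start, g.end - config.read_length + 2))
                        loci.append((g.replicon, p2, 0))
            read_loci[qname] = [
                (rep, pos, pos + config.read_length - 1) for rep, pos, _ in loci
            ]
            for j, (rep, pos, nm) in enumerate(loci):
                a = pysam.AlignedSegment(header)
                a.query_name = qname
                a.query_sequence = "A" * config.read_length
                a.query_qualities = pysam.qualitystring_to_array(
                    "I" * config.read_length)
                a.flag = 0 if j == 0 else 256
                a.reference_id = header.get_tid(rep)
                a.reference_start = pos - 1  # SAM text is 1-based
                a.mapping_quality = 37 if len(loci) == 1 else 0
                a.cigarstring = f"{config.read_length}M"
                a.set_tag("NM", nm)
                out.write(a)
    return TruthRecord(condition, replicate, per_gene, per_gene_clean,
                       read_loci, rrna_reads, mismatched_reads)


def simulate_experiment(
    annotation: GenomeAnnotation,
    profile: ExpressionProfile,
    config: SynthConfig,
    out_dir: str | Path,
) -> tuple[dict[str, Path], pd.DataFrame, dict[str, TruthRecord]]:
    """All conditions x replicates -> SAM files, design table, truth records."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sams: dict[str, Path] = {}
    truths: dict[str, TruthRecord] = {}
    rows = []
    for condition in config.conditions:
        for rep in range(1, config.replicates_per_condition + 1):
            sample = f"{condition}_r{rep}"
            path = out_dir / f"{sample}.sam"
            truths[sample] = simulate_alignments(
                annotation, profile, config, condition, rep, path)
            sams[sample] = path
            rows.append({"sample_id": sample, "condition": condition,
                         "replicate": rep})
    design = pd.DataFrame(rows).set_index("sample_id")
    return sams, design, truths


# ---------------------------------------------------------------------------
# Isotopomer spectra
# ---------------------------------------------------------------------------

def binomial_mid(p13: float, n_carbons: int) -> np.ndarray:
    """Exact mass-isotopomer distribution Binom(n_carbons, p13), M0..Mn.

    Each of the fragment's carbon positions is 13C independently with
    probability ``p13``; the MID is the distribution of the number of
    labelled positions.
    """
    if not 0.0 <= p13 <= 1.0:
        raise ValueError(f"p13={p13} outside [0, 1]")
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    return stats.binom.pmf(np.arange(n_carbons + 1), n_carbons, p13)


def simulate_mid(
    p13: float,
    n_carbons: int,
    noise_cv: float = 0.0,
    n_spectra: int = 1,
    seed: int = 0,
) -> list[np.ndarray]:
    """Binomial MIDs with multiplicative lognormal measurement noise.

    Each channel of the exact binomial MID is multiplied by an independent
    unit-mean lognormal factor with coefficient of variation ``noise_cv``,
    then the spectrum is renormalised to sum 1.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    base = binomial_mid(p13, n_carbons)
    if noise_cv == 0:
        return [base.copy() for _ in range(n_spectra)]
    rng = np.random.default_rng([seed, 0x1D])
    sigma = np.sqrt(np.log1p(noise_cv**2))
    out = []
    for _ in range(n_spectra):
        factors = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=base.size)
        mid = base * factors
        out.append(mid / mid.sum())
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in annotation.replicons:
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for f in annotation.cds:
            fh.write(
                f"{f.replicon}\tphaseq\tCDS\t{f.start}\t{f.end}\t.\t{f.strand}\t0\t"
                f"ID={f.gene_id}\n"
            )


def write_rrna_tsv(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write rRNA exclusion intervals, preserving raw coordinate order."""
    pd.DataFrame(annotation.rrna_intervals_raw,
                 columns=["replicon", "start", "end"]).to_csv(
        path, sep="\t", index=False)


def write_truth_tsv(truths: dict[str, TruthRecord], path: str | Path) -> None:
    df = pd.DataFrame({s: t.per_gene_counts for s, t in truths.items()})
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def write_mid_tsv(rows: list[dict], path: str | Path) -> None:
    """Write MID table: sample_id, strain, condition, fragment_label,
    n_carbons, M0..Mn."""
    max_n = max(r["n_carbons"] for r in rows)
    records = []
    for r in rows:
        rec = {k: r[k] for k in
               ("sample_id", "strain", "condition", "fragment_label", "n_carbons")}
        for i in range(max_n + 1):
            rec[f"M{i}"] = r["abundances"][i] if i <= r["n_carbons"] else ""
        records.append(rec)
    pd.DataFrame(records).to_csv(path, sep="\t", index=False)
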