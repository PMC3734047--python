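"""Alignment filtering and fractional-count RPKM quantification.

Consumes single-end short-read alignments (SAM) produced by a BWA-style
aligner, discards alignments with mismatches or falling in rRNA (rrn operon)
regions, and counts the remainder onto CDS features. A read mapping equally
well to k loci contributes weight 1/k at each locus; a locus overlapping m
CDS features splits its weight 1/m among them. RPKM is computed per kilobase
of CDS per million counted reads, with the library size defined as the total
counted CDS weight of the sample.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree


class AnnotationError(ValueError):
    """Malformed or inconsistent genome annotation."""


class SamHeaderError(ValueError):
    """SAM input lacks required header information."""


class DegenerateSampleError(ValueError):
    """A sample has no counted reads, so RPKM is undefined."""


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CDSFeature:
    gene_id: str
    replicon: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeAnnotation:
    """Replicons, CDS features and rRNA exclusion intervals.

    Coordinates are 1-based inclusive (SAM/GFF3 convention). Intervals given
    in reversed (high-to-low) order are normalised to (min, max) at
    construction; the raw orientation of rRNA rows is preserved in
    ``rrna_intervals_raw`` so writers can round-trip it.
    """

    replicons: list[tuple[str, int]]
    cds: list[CDSFeature]
    rrna_intervals: list[tuple[str, int, int]]
    rrna_intervals_raw: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rrna_intervals_raw:
            self.rrna_intervals_raw = list(self.rrna_intervals)
        self.rrna_intervals = [
            (rep, min(a, b), max(a, b)) for rep, a, b in self.rrna_intervals
        ]
        lengths = dict(self.replicons)
        if len(lengths) != len(self.replicons):
            raise AnnotationError("duplicate replicon names")
        seen: set[str] = set()
        norm_cds = []
        for f in self.cds:
            if f.gene_id in seen:
                raise AnnotationError(f"duplicate gene_id {f.gene_id!r}")
            seen.add(f.gene_id)
            if f.replicon not in lengths:
                raise AnnotationError(
                    f"CDS {f.gene_id!r} on unknown replicon {f.replicon!r}"
                )
            start, end = min(f.start, f.end), max(f.start, f.end)
            if start < 1 or end > lengths[f.replicon]:
                raise AnnotationError(
                    f"CDS {f.gene_id!r} ({start}-{end}) outside replicon "
                    f"{f.replicon!r} bounds 1-{lengths[f.replicon]}"
                )
            norm_cds.append(CDSFeature(f.gene_id, f.replicon, start, end, f.strand))
        self.cds = norm_cds
        for rep, start, end in self.rrna_intervals:
            if rep not in lengths:
                raise AnnotationError(f"rRNA interval on unknown replicon {rep!r}")
            if start < 1 or end > lengths[rep]:
                raise AnnotationError(
                    f"rRNA interval {start}-{end} outside replicon {rep!r} bounds"
                )
        self._cds_index = _build_index(
            (f.replicon, f.start, f.end, f.gene_id) for f in self.cds
        )
        self._rrna_index = _build_index(
            (rep, s, e, None) for rep, s, e in self.rrna_intervals
        )

    # -- queries ------------------------------------------------------------

    def gene_ids(self) -> list[str]:
        return [f.gene_id for f in self.cds]

    def gene_lengths(self) -> pd.Series:
        return pd.Series(
            {f.gene_id: f.length for f in self.cds}, name="length", dtype=float
        )

    def overlapping_genes(self, replicon: str, start: int, end: int) -> list[str]:
        """Gene IDs of CDS overlapping [start, end] (1-based incl.) by >= 1 bp."""
        tree = self._cds_index.get(replicon)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.overlap(start, end + 1))

    def in_rrna(self, replicon: str, start: int, end: int) -> bool:
        tree = self._rrna_index.get(replicon)
        return bool(tree is not None and tree.overlap(start, end + 1))


def _build_index(rows: Iterable[tuple[str, int, int, object]]) -> dict[str, IntervalTree]:
    index: dict[str, IntervalTree] = {}
    for rep, start, end, data in rows:
        index.setdefault(rep, IntervalTree()).addi(start, end + 1, data)
    return index


def read_annotation(gff_path: str | Path, rrna_tsv_path: str | Path) -> GenomeAnnotation:
    """Load CDS features from GFF3 and rRNA exclusion intervals from TSV.

    Replicon lengths are taken from ``##sequence-region`` pragmas. The rRNA
    TSV has columns (replicon, start, end); rows listed high-to-low are
    normalised.
    """
    import gffutils

    gff_path = Path(gff_path)
    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    replicons: list[tuple[str, int]] = []
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            replicons.append((parts[1], int(parts[3])))
    if not replicons:
        raise AnnotationError(f"{gff_path}: no ##sequence-region pragmas")
    cds = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [None])[0]
        if gene_id is None:
            raise AnnotationError(f"{gff_path}: CDS without ID attribute at line {feat}")
        cds.append(CDSFeature(gene_id, feat.seqid, feat.start, feat.end, feat.strand))

    rrna_rows: list[tuple[str, int, int]] = []
    rrna_df = pd.read_csv(rrna_tsv_path, sep="\t", dtype={0: str})
    if len(rrna_df):
        expected = {"replicon", "start", "end"}
        if not expected.issubset(rrna_df.columns):
            raise AnnotationError(
                f"{rrna_tsv_path}: expected columns {sorted(expected)}"
            )
        for i, row in enumerate(rrna_df.itertuples(index=False), start=2):
            try:
                rrna_rows.append((str(row.replicon), int(row.start), int(row.end)))
            except (TypeError, ValueError) as exc:
                raise AnnotationError(f"{rrna_tsv_path}: line {i}: {exc}") from exc
    return GenomeAnnotation(replicons, cds, rrna_rows, rrna_intervals_raw=rrna_rows)


# ---------------------------------------------------------------------------
# Alignment groups
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Locus:
    replicon: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    mismatches: int


@dataclass
class ReadAlignmentGroup:
    """All alignment loci of a single read; the unit of filtering and 1/k."""

    read_id: str
    loci: list[Locus]


def group_alignments(sam: str | Path | pysam.AlignmentFile) -> Iterator[ReadAlignmentGroup]:
    """Collate SAM records into one group per read name.

    Unmapped records contribute no locus. The mismatch count is taken from
    the NM tag; a missing NM is treated as 0 mismatches (a warning reports
    how many records lacked the tag). Groups are yielded in sorted read-name
    order with canonically sorted loci, so the result is independent of the
    input record order.
    """
    if isinstance(sam, pysam.AlignmentFile):
        fh, owned = sam, False
    else:
        fh, owned = pysam.AlignmentFile(str(sam), "r", check_sq=False), True
    try:
        if not fh.header.get("SQ"):
            raise SamHeaderError("SAM header has no @SQ reference lines")
        groups: dict[str, list[Locus]] = {}
        missing_nm = 0
        for rec in fh:
            groups.setdefault(rec.query_name, [])
            if rec.is_unmapped:
                continue
            if rec.has_tag("NM"):
                nm = int(rec.get_tag("NM"))
            else:
                nm = 0
                missing_nm += 1
            groups[rec.query_name].append(
                Locus(rec.reference_name, rec.reference_start + 1,
                      rec.reference_end, nm)
            )
        if missing_nm:
            warnings.warn(
                f"{missing_nm} alignment record(s) lacked an NM tag; "
                "treated as 0 mismatches", stacklevel=2,
            )
    finally:
        if owned:
            fh.close()
    for read_id in sorted(groups):
        loci = sorted(groups[read_id],
                      key=lambda l: (l.replicon, l.start, l.end, l.mismatches))
        if loci:
            yield ReadAlignmentGroup(read_id, loci)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterStats:
    n_reads_input: int = 0
    n_reads_rrna: int = 0
    n_loci_dropped_mismatch: int = 0
    n_reads_retained: int = 0

    @property
    def frac_rrna(self) -> float:
        return self.n_reads_rrna / self.n_reads_input if self.n_reads_input else 0.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_reads_input": self.n_reads_input,
                "n_reads_rrna": self.n_reads_rrna,
                "n_loci_dropped_mismatch": self.n_loci_dropped_mismatch,
                "n_reads_retained": self.n_reads_retained,
                "frac_rrna": self.frac_rrna,
            },
            indent=2,
        )


def filter_alignments(
    groups: Iterable[ReadAlignmentGroup],
    annotation: GenomeAnnotation,
    *,
    drop_whole_read_on_rrna: bool = False,
) -> tuple[list[ReadAlignmentGroup], FilterStats]:
    """Discard mismatched loci and rRNA-region loci; drop emptied reads.

    Filtering is per alignment (locus): every locus with mismatches > 0 is
    removed, and every locus overlapping an rRNA interval is removed. A read
    with no surviving locus is dropped entirely. A read is tallied as an
    rRNA read when at least one of its loci hit an rRNA interval and no
    genic (CDS-overlapping) locus survived. With
    ``drop_whole_read_on_rrna=True`` a single rRNA-region locus discards the
    whole read (the stricter per-read interpretation).
    """
    stats = FilterStats()
    retained: list[ReadAlignmentGroup] = []
    for group in groups:
        stats.n_reads_input += 1
        hit_rrna = False
        survivors: list[Locus] = []
        for locus in group.loci:
            if locus.mismatches > 0:
                stats.n_loci_dropped_mismatch += 1
                continue
            if annotation.in_rrna(locus.replicon, locus.start, locus.end):
                hit_rrna = True
                continue
            survivors.append(locus)
        if hit_rrna and drop_whole_read_on_rrna:
            survivors = []
        genic_survived = any(
            annotation.overlapping_genes(l.replicon, l.start, l.end)
            for l in survivors
        )
        if hit_rrna and not genic_survived:
            stats.n_reads_rrna += 1
        if survivors:
            stats.n_reads_retained += 1
            retained.append(ReadAlignmentGroup(group.read_id, survivors))
    return retained, stats


# ---------------------------------------------------------------------------
# Counting and RPKM
# ---------------------------------------------------------------------------

def count_reads(
    groups: Iterable[ReadAlignmentGroup], annotation: GenomeAnnotation
) -> tuple[pd.Series, float]:
    """Fractional per-gene counts and the counted library size.

    Each read distributes total weight <= 1: with k surviving loci each locus
    carries 1/k, and a locus overlapping m >= 1 CDS features adds 1/(k*m) to
    each; loci overlapping no CDS contribute nothing. The library size is the
    sum of counted weights (the "reads on CDSs" convention).
    """
    counts = pd.Series(0.0, index=annotation.gene_ids(), name="count")
    for group in groups:
        k = len(group.loci)
        for locus in group.loci:
            genes = annotation.overlapping_genes(locus.replicon, locus.start, locus.end)
            if not genes:
                continue
            w = 1.0 / (k * len(genes))
            for g in genes:
                counts[g] += w
    return counts, float(counts.sum())


def compute_rpkm(
    counts: pd.DataFrame | pd.Series,
    gene_length: pd.Series,
    library_size: pd.Series | float,
) -> pd.DataFrame | pd.Series:
    """RPKM = counts / (gene length / 1e3) / (library size / 1e6)."""
    lib = library_size
    if isinstance(lib, pd.Series):
        if (lib <= 0).any():
            bad = list(lib.index[lib <= 0])
            raise DegenerateSampleError(f"zero library size for sample(s) {bad}")
    elif lib <= 0:
        raise DegenerateSampleError("zero library size")
    if (gene_length <= 0).any():
        raise AnnotationError("non-positive gene length")
    per_kb = counts.div(gene_length / 1e3, axis=0) if isinstance(counts, pd.DataFrame) \
        else counts / (gene_length / 1e3)
    return per_kb / (lib / 1e6)


@dataclass
class RPKMMatrix:
    """Gene x sample fractional counts, library sizes and RPKM values.

    ``design`` maps each sample ID to its (condition, replicate) pair.
    """

    counts: pd.DataFrame
    gene_length: pd.Series
    design: pd.DataFrame  # index: sample_id; columns: condition, replicate
    library_size: pd.Series = field(init=False)
    rpkm: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        if not set(self.counts.columns) <= set(self.design.index):
            missing = set(self.counts.columns) - set(self.design.index)
            raise ValueError(f"samples missing from design: {sorted(missing)}")
        self.design = self.design.loc[list(self.counts.columns)]
        self.gene_length = self.gene_length.loc[self.counts.index].astype(float)
        self.library_size = self.counts.sum(axis=0)
        self.library_size.name = "library_size"
        self.rpkm = compute_rpkm(self.counts, self.gene_length, self.library_size)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def condition_of(self, sample: str) -> str:
        return str(self.design.loc[sample, "condition"])

    def samples_of(self, condition: str) -> list[str]:
        sel = self.design.index[self.design["condition"] == condition]
        if len(sel) == 0:
            raise KeyError(f"unknown condition {condition!r}")
        return list(sel)

    def condition_means(self) -> pd.DataFrame:
        """Mean RPKM per gene per condition over replicates."""
        return self.rpkm.T.groupby(self.design["condition"]).mean().T


def quantify_sample(
    sam: str | Path, annotation: GenomeAnnotation, **filter_kwargs
) -> tuple[pd.Series, FilterStats]:
    """SAM file -> filtered fractional gene counts for one sample."""
    groups = group_alignments(sam)
    retained, stats = filter_alignments(groups, annotation, **filter_kwargs)
    counts, _ = count_reads(retained, annotation)
    return counts, stats


def quantify_experiment(
    sam_by_sample: dict[str, str | Path],
    annotation: GenomeAnnotation,
    design: pd.DataFrame,
    **filter_kwargs,
) -> tuple[RPKMMatrix, dict[str, FilterStats]]:
    """Quantify every sample of an experiment into one RPKM matrix."""
    counts = {}
    stats = {}
    for sample, sam in sam_by_sample.items():
        counts[sample], stats[sample] = quantify_sample(sam, annotation, **filter_kwargs)
    matrix = RPKMMatrix(pd.DataFrame(counts), annotation.gene_lengths(), design)
    return matrix, stats


def read_design(path: str | Path) -> pd.DataFrame:
    """Read a design TSV with columns sample_id, condition, replicate."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    return df.set_index("sample_id")
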