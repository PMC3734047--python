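"""Shared fixtures: tiny hand-built annotations and an independent
brute-force counting oracle used to cross-check the quantification path."""

from __future__ import annotations

import pandas as pd
import pytest

from phaseq.quant import CDSFeature, GenomeAnnotation, ReadAlignmentGroup


@pytest.fixture
def tiny_annotation() -> GenomeAnnotation:
    """Two replicons, three genes, one rRNA region (coordinates by hand)."""
    return GenomeAnnotation(
        replicons=[("chr1", 10_000), ("chr2", 8_000)],
        cds=[
            CDSFeature("geneA", "chr1", 1001, 2500),   # 1500 bp
            CDSFeature("geneB", "chr1", 3001, 3500),   # 500 bp
            CDSFeature("geneC", "chr2", 501, 1500),    # 1000 bp
        ],
        rrna_intervals=[("chr1", 5001, 6000)],
    )


def brute_force_counts(groups, annotation):
    """Independent per-read enumeration of the filter + 1/k / 1/m rules.

    Interval overlap and rRNA membership are recomputed here with plain
    loops over the annotation lists, so this shares no code with the
    indexed implementation under test.
    """
    def overlaps(a_start, a_end, b_start, b_end):
        lo, hi = min(b_start, b_end), max(b_start, b_end)
        return a_start <= hi and a_end >= lo

    counts = {f.gene_id: 0.0 for f in annotation.cds}
    n_retained = 0
    for group in groups:
        survivors = []
        for locus in group.loci:
            if locus.mismatches > 0:
                continue
            in_rrna = any(
                rep == locus.replicon and overlaps(locus.start, locus.end, s, e)
                for rep, s, e in annotation.rrna_intervals
            )
            if in_rrna:
                continue
            survivors.append(locus)
        if not survivors:
            continue
        n_retained += 1
        k = len(survivors)
        for locus in survivors:
            hit_genes = [
                f.gene_id
                for f in annotation.cds
                if f.replicon == locus.replicon
                and overlaps(locus.start, locus.end, f.start, f.end)
            ]
            if hit_genes:
                for g in hit_genes:
                    counts[g] += 1.0 / (k * len(hit_genes))
    return pd.Series(counts), n_retained


@pytest.fixture
def counting_oracle():
    return brute_force_counts
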