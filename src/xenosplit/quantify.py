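"""Gene-level quantification by exon containment, plus CPM normalization.

Counting follows a strict containment rule: a read is ascribed to a gene
only if its aligned interval lies completely inside a single merged exon of
that gene's model.  Exons of one gene coming from several annotation sources
are unioned before counting.  A fragment contained in exons of more than one
gene is counted for none and tallied as ambiguous-assignment, which avoids
double counting while keeping the audit trail.

Normalization divides counts by the library total in millions (CPM); the
library total defaults to the number of species-classified reads for the
sample rather than the assigned-count sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

__all__ = [
    "GeneModel",
    "CountMatrix",
    "load_gene_models",
    "count_contained_reads",
    "cpm_normalize",
]


@dataclass
class GeneModel:
    """One gene's merged exon intervals (internal 0-based half-open)."""

    gene_id: str
    species: str
    exons: list[tuple[str, int, int, str]]  # (contig, start, end, strand)
    source: str = ""


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals."""
    merged: list[list[int]] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(m) for m in merged]


def load_gene_models(
    gtf_paths: list[str | Path] | str | Path, species: str
) -> dict[str, GeneModel]:
    """Load gene models from one or more GTF files and merge exons per gene.

    Exons of the same gene listed in several files (e.g. two annotation
    collections) are unioned.  GTF 1-based inclusive coordinates become
    0-based half-open internally.
    """
    if isinstance(gtf_paths, (str, Path)):
        gtf_paths = [gtf_paths]
    raw: dict[str, dict[str, list[tuple[int, int]]]] = {}
    strands: dict[str, str] = {}
    for path in gtf_paths:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        for feat in db.features_of_type("exon"):
            gene_ids = feat.attributes.get("gene_id")
            if not gene_ids:
                raise ValueError(
                    f"{path}: exon at {feat.seqid}:{feat.start} lacks gene_id"
                )
            gid = gene_ids[0]
            raw.setdefault(gid, {}).setdefault(feat.seqid, []).append(
                (feat.start - 1, feat.end)
            )
            strands[gid] = feat.strand
    models: dict[str, GeneModel] = {}
    for gid, by_contig in raw.items():
        exons = []
        for contig, ivs in by_contig.items():
            exons.extend(
                (contig, s, e, strands[gid]) for s, e in _merge_intervals(ivs)
            )
        models[gid] = GeneModel(gene_id=gid, species=species, exons=exons)
    return models


@dataclass
class CountMatrix:
    """Genes x samples integer counts with per-sample library totals.

    ``library_totals`` is the divisor basis for CPM (total reads for the
    sample, not necessarily the assigned-count column sum).
    """

    counts: pd.DataFrame
    library_totals: pd.Series
    species: str = "human"

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [c for c in self.counts.columns if c not in self.library_totals]
        if missing:
            raise ValueError(f"library_totals missing samples: {missing}")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def cpm(self) -> pd.DataFrame:
        """Counts per million, per sample."""
        return self.counts / (self.library_totals[self.counts.columns] / 1e6)


def _exon_tree(models: dict[str, GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for gm in models.values():
        for contig, s, e, _strand in gm.exons:
            trees.setdefault(contig, IntervalTree()).addi(s, e, gm.gene_id)
    return trees


def _containing_genes(
    trees: dict[str, IntervalTree], contig: str, start: int, end: int
) -> set[str]:
    tree = trees.get(contig)
    if tree is None:
        return set()
    return {
        iv.data for iv in tree.overlap(start, end) if iv.begin <= start and end <= iv.end
    }


def count_contained_reads(
    sam_path: str | Path,
    models: dict[str, GeneModel],
    library_total: float | None = None,
):
    """Count fragments completely contained within single-gene exons.

    Each mate is tested separately; the fragment is ascribed to a gene only
    when all of its mates map and each lies entirely within a merged exon of
    that same gene.  Fragments contained in exons of more than one gene are tallied as
    ``ambiguous_assignment``; everything else unassignable is ``unassigned``.

    Returns ``(counts: pd.Series indexed by gene, audit: dict)`` where audit
    has keys ``assigned``, ``ambiguous_assignment``, ``unassigned``,
    ``missing_contig``.
    """
    trees = _exon_tree(models)
    counts = {gid: 0 for gid in models}
    audit = {"assigned": 0, "ambiguous_assignment": 0, "unassigned": 0,
             "missing_contig": 0}
    # gene sets per fragment, intersected over mates
    frag_genes: dict[str, set[str] | None] = {}
    seen_missing = False
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            prev = frag_genes.get(rec.query_name)
            if rec.is_unmapped:
                frag_genes.setdefault(rec.query_name, set())
                continue
            if rec.reference_name not in trees:
                seen_missing = True
                genes: set[str] = set()
            else:
                genes = _containing_genes(
                    trees, rec.reference_name, rec.reference_start, rec.reference_end
                )
            if prev is None:
                frag_genes[rec.query_name] = genes
            else:
                frag_genes[rec.query_name] = prev & genes
    for genes in frag_genes.values():
        if not genes:
            audit["unassigned"] += 1
        elif len(genes) > 1:
            audit["ambiguous_assignment"] += 1
        else:
            counts[next(iter(genes))] += 1
            audit["assigned"] += 1
    if seen_missing:
        import warnings

        warnings.warn("SAM contains contigs absent from the gene models; "
                      "affected reads counted as unassigned")
        audit["missing_contig"] = 1
    series = pd.Series(counts, name="count").astype(int)
    if library_total is None:
        library_total = len(frag_genes)
    return series, audit


def cpm_normalize(column: pd.Series | np.ndarray, library_total: float):
    """Counts per million: count / (library_total / 1e6)."""
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    return column / (library_total / 1e6)
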