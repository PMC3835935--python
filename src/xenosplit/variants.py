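"""Strand-stratified allele counting at candidate variant loci.

For a locus of interest (e.g. the APC Q861* stop-gain), every aligned read
covering the position contributes one tally: wild-type if its base matches
the reference allele, mutant if it matches the alternate, "other" if
neither.  Tallies are stratified by the read's strand (the SAM
reverse-strand flag), giving the forward/reverse x WT/mut quadruple, and the
percent wild-type / percent mutant are computed over WT+mut only, rounded
half-even to integer percent.  Overlapping mates are counted independently
(forward and reverse transcripts are tallied separately).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pysam

__all__ = [
    "VariantLocus",
    "StrandedAlleleCounts",
    "load_loci",
    "pileup_at_locus",
    "allele_fractions",
    "tally_report",
]

_VALID_BASES = set("ACGT")


@dataclass(frozen=True)
class VariantLocus:
    """A single-base variant: 1-based position, ref and alt alleles."""

    label: str
    contig: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be 1-based and >= 1")
        if self.ref_allele not in _VALID_BASES or self.alt_allele not in _VALID_BASES:
            raise ValueError("alleles must be single bases in ACGT")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


@dataclass
class StrandedAlleleCounts:
    """Forward/reverse x WT/mut read tallies at one locus."""

    fwd_wt: int = 0
    fwd_mut: int = 0
    rev_wt: int = 0
    rev_mut: int = 0
    n_other: int = 0

    @property
    def total(self) -> int:
        """WT + mut total; bases matching neither allele are excluded."""
        return self.fwd_wt + self.fwd_mut + self.rev_wt + self.rev_mut


def load_loci(path: str | Path) -> list[VariantLocus]:
    """Read loci from TSV columns label, contig, position, ref, alt."""
    df = pd.read_csv(path, sep="\t", dtype={"position": int})
    required = ["label", "contig", "position", "ref", "alt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        VariantLocus(r.label, r.contig, int(r.position), r.ref, r.alt)
        for r in df.itertuples()
    ]


def pileup_at_locus(
    sam_path: str | Path,
    locus: VariantLocus,
    min_base_quality: int = 0,
) -> StrandedAlleleCounts:
    """Tally WT/mut bases of all reads covering the locus.

    The read base at the reference position is located through the CIGAR
    alignment (insertions and soft clips shift it; deletions and reference
    skips at the position are ignored).  No filters are applied by default;
    ``min_base_quality`` optionally drops low-quality base calls.
    """
    counts = StrandedAlleleCounts()
    pos0 = locus.position - 1
    seen_contig = False
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        if sam.references and locus.contig in sam.references:
            seen_contig = True
        for rec in sam:
            if rec.is_unmapped or rec.reference_name != locus.contig:
                continue
            if not (rec.reference_start <= pos0 < rec.reference_end):
                continue
            qpos = None
            for q, r in rec.get_aligned_pairs(matches_only=True):
                if r == pos0:
                    qpos = q
                    break
            if qpos is None:  # deletion or skip at the locus
                continue
            if min_base_quality > 0 and rec.query_qualities is not None:
                if rec.query_qualities[qpos] < min_base_quality:
                    continue
            base = rec.query_sequence[qpos].upper()
            rev = rec.is_reverse
            if base == locus.ref_allele:
                if rev:
                    counts.rev_wt += 1
                else:
                    counts.fwd_wt += 1
            elif base == locus.alt_allele:
                if rev:
                    counts.rev_mut += 1
                else:
                    counts.fwd_mut += 1
            else:
                counts.n_other += 1
    if not seen_contig:
        import warnings

        warnings.warn(f"contig {locus.contig!r} absent from {sam_path}; zero counts")
    return counts


def _round_half_even_pct(x: float) -> int:
    # float->Decimal via str keeps 62.5 exactly representable for the tie rule
    from decimal import ROUND_HALF_EVEN, Decimal

    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_EVEN))


def allele_fractions(counts: StrandedAlleleCounts) -> tuple[int, int]:
    """Integer percent WT and mutant over strand-pooled WT+mut reads.

    Rounding is half-even (banker's), the convention that reproduces the
    published strand-stratified tallies; "other" bases are excluded from the
    denominator.  Raises on a zero total rather than returning undefined
    percentages.
    """
    total = counts.total
    if total == 0:
        raise ValueError("no WT or mutant reads at locus: fractions undefined")
    wt = counts.fwd_wt + counts.rev_wt
    mut = counts.fwd_mut + counts.rev_mut
    return (
        _round_half_even_pct(100.0 * wt / total),
        _round_half_even_pct(100.0 * mut / total),
    )


def tally_report(
    sam_path: str | Path, loci: list[VariantLocus]
) -> pd.DataFrame:
    """Per-locus strand-stratified tallies and percent alleles."""
    rows = []
    for locus in loci:
        c = pileup_at_locus(sam_path, locus)
        if c.total:
            pct_wt, pct_mut = allele_fractions(c)
        else:
            pct_wt = pct_mut = None
        rows.append(
            {
                "label": locus.label,
                "fwd_wt": c.fwd_wt,
                "fwd_mut": c.fwd_mut,
                "rev_wt": c.rev_wt,
                "rev_mut": c.rev_mut,
                "n_other": c.n_other,
                "pct_wt": pct_wt,
                "pct_mut": pct_mut,
            }
        )
    return pd.DataFrame(rows)
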