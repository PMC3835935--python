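"""Species-of-origin read classification for xenograft RNA-seq.

A xenograft sample mixes human tumor reads with murine stromal reads.  Each
read (fragment) is aligned to both the human and the mouse reference; the
classifier keeps whichever species the read matches with higher fidelity,
i.e. with fewer mismatching bases (the SAM NM edit distance).  Equal
mismatch counts put the read in an "ambiguous" class that downstream
analyses drop.  Reads aligned in neither genome form an explicit fourth
"unaligned" class so that the reported fractions always refer to all input
reads; when everything aligns this reduces to the three-class view.

Paired-end reads are classified at fragment level: mate NM values are
summed, and a genome counts as aligning the fragment only if both mates map
there.  The best alignment per mate is the minimum NM over all of its
records (secondary alignments included).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "SpeciesClass",
    "PartitionResult",
    "summarize_alignments",
    "classify_read",
    "partition_sample",
    "partition_report",
]


class SpeciesClass(str, enum.Enum):
    HUMAN = "human"
    MOUSE = "mouse"
    AMBIGUOUS = "ambiguous"
    UNALIGNED = "unaligned"


_MD_TOKEN = re.compile(r"(\d+)|\^[A-Z]+|([A-Z])")


def _record_mismatches(rec: pysam.AlignedSegment) -> int:
    """Mismatch count of one alignment record, from NM or (fallback) MD."""
    if rec.has_tag("NM"):
        return int(rec.get_tag("NM"))
    if rec.has_tag("MD"):
        md = rec.get_tag("MD")
        return sum(1 for m in _MD_TOKEN.finditer(md) if m.group(2))
    raise ValueError(
        f"alignment record {rec.query_name!r} has neither NM nor MD tag; "
        "cannot determine mismatch count"
    )


def _scan_sam(path: str | Path) -> dict[str, list]:
    """Per-fragment best mismatch evidence from one SAM.

    Returns qname -> [min_nm_mate1, min_nm_mate2, paired_flag]; for single-end
    records mate slot 0 is used.  ``None`` in a slot means that mate never
    aligned in this genome.
    """
    best: dict[str, list] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            slot = 1 if (rec.is_paired and rec.is_read2) else 0
            entry = best.setdefault(rec.query_name, [None, None, rec.is_paired])
            entry[2] = entry[2] or rec.is_paired
            if rec.is_unmapped:
                continue
            nm = _record_mismatches(rec)
            if entry[slot] is None or nm < entry[slot]:
                entry[slot] = nm
    return best


def _fragment_nm(entry: list) -> float:
    """Best fragment-level NM for one genome, NaN if not aligned there."""
    m1, m2, paired = entry
    if paired:
        if m1 is None or m2 is None:  # both mates must map
            return np.nan
        return float(m1 + m2)
    return np.nan if m1 is None else float(m1)


def summarize_alignments(
    sam_human: str | Path, sam_mouse: str | Path
) -> pd.DataFrame:
    """Best-alignment mismatch evidence per fragment against both genomes.

    Returns a DataFrame indexed by read id with float columns ``nm_human``
    and ``nm_mouse``; NaN marks "did not align in that genome".
    """
    h = _scan_sam(sam_human)
    m = _scan_sam(sam_mouse)
    ids = list(dict.fromkeys(list(h) + [k for k in m if k not in h]))
    return pd.DataFrame(
        {
            "nm_human": [_fragment_nm(h[k]) if k in h else np.nan for k in ids],
            "nm_mouse": [_fragment_nm(m[k]) if k in m else np.nan for k in ids],
        },
        index=pd.Index(ids, name="read_id"),
    )


def classify_read(nm_human: float | None, nm_mouse: float | None) -> SpeciesClass:
    """Classify one fragment from its best mismatch counts.

    Fewer mismatches wins; equality is ambiguous; absent on one side means
    the other species; absent on both means unaligned.
    """
    h_absent = nm_human is None or (isinstance(nm_human, float) and np.isnan(nm_human))
    m_absent = nm_mouse is None or (isinstance(nm_mouse, float) and np.isnan(nm_mouse))
    if h_absent and m_absent:
        return SpeciesClass.UNALIGNED
    if m_absent:
        return SpeciesClass.HUMAN
    if h_absent:
        return SpeciesClass.MOUSE
    if nm_human < nm_mouse:
        return SpeciesClass.HUMAN
    if nm_human > nm_mouse:
        return SpeciesClass.MOUSE
    return SpeciesClass.AMBIGUOUS


@dataclass
class PartitionResult:
    """Per-sample read composition (Table-1 style)."""

    sample_id: str
    total_reads: int
    counts: dict[SpeciesClass, int]

    def __post_init__(self) -> None:
        for cls in SpeciesClass:
            self.counts.setdefault(cls, 0)
        if sum(self.counts.values()) != self.total_reads:
            raise ValueError("class counts must sum to total_reads")

    @property
    def defined(self) -> bool:
        return self.total_reads > 0

    def fractions(self) -> dict[SpeciesClass, float]:
        """Percent of all input reads per class (NaN when total is zero)."""
        if not self.defined:
            return {cls: float("nan") for cls in SpeciesClass}
        return {
            cls: 100.0 * self.counts[cls] / self.total_reads for cls in SpeciesClass
        }

    @classmethod
    def from_counts(
        cls,
        sample_id: str,
        total_reads: int,
        human: int,
        mouse: int = 0,
        ambiguous: int = 0,
    ) -> "PartitionResult":
        """Build a result from published per-class counts.

        Any remainder between ``total_reads`` and the three stated classes is
        attributed to the unaligned class.
        """
        unaligned = total_reads - human - mouse - ambiguous
        if unaligned < 0:
            raise ValueError("class counts exceed total_reads")
        return cls(
            sample_id=sample_id,
            total_reads=total_reads,
            counts={
                SpeciesClass.HUMAN: human,
                SpeciesClass.MOUSE: mouse,
                SpeciesClass.AMBIGUOUS: ambiguous,
                SpeciesClass.UNALIGNED: unaligned,
            },
        )


def _classify_summaries(summaries: pd.DataFrame) -> pd.Series:
    nm_h = summaries["nm_human"].to_numpy()
    nm_m = summaries["nm_mouse"].to_numpy()
    out = np.empty(len(summaries), dtype=object)
    h_absent = np.isnan(nm_h)
    m_absent = np.isnan(nm_m)
    out[h_absent & m_absent] = SpeciesClass.UNALIGNED
    out[~h_absent & m_absent] = SpeciesClass.HUMAN
    out[h_absent & ~m_absent] = SpeciesClass.MOUSE
    both = ~h_absent & ~m_absent
    out[both & (nm_h < nm_m)] = SpeciesClass.HUMAN
    out[both & (nm_h > nm_m)] = SpeciesClass.MOUSE
    out[both & (nm_h == nm_m)] = SpeciesClass.AMBIGUOUS
    return pd.Series(out, index=summaries.index)


def partition_sample(
    sam_human: str | Path,
    sam_mouse: str | Path,
    sample_id: str,
    out_dir: str | Path | None = None,
) -> tuple[PartitionResult, dict[SpeciesClass, list[str]]]:
    """Classify every fragment of a sample and tally the composition.

    When ``out_dir`` is given, writes ``<sample>.human.sam`` containing
    exactly the human-class fragments' human-genome alignments (and the
    mouse analogue).

    Returns ``(PartitionResult, read ids per class)``.
    """
    summaries = summarize_alignments(sam_human, sam_mouse)
    classes = _classify_summaries(summaries)
    ids: dict[SpeciesClass, list[str]] = {cls: [] for cls in SpeciesClass}
    for rid, cls in classes.items():
        ids[cls].append(rid)
    result = PartitionResult(
        sample_id=sample_id,
        total_reads=len(summaries),
        counts={cls: len(v) for cls, v in ids.items()},
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for cls, src in ((SpeciesClass.HUMAN, sam_human), (SpeciesClass.MOUSE, sam_mouse)):
            keep = set(ids[cls])
            dest = out_dir / f"{sample_id}.{cls.value}.sam"
            with pysam.AlignmentFile(str(src), "r", check_sq=False) as sam_in:
                with pysam.AlignmentFile(str(dest), "wh", template=sam_in) as sam_out:
                    for rec in sam_in:
                        if rec.query_name in keep and not rec.is_unmapped:
                            sam_out.write(rec)
    return result, ids


def partition_report(results: list[PartitionResult]) -> pd.DataFrame:
    """Table-1-style composition report, percentages at two decimals."""
    if not results:
        raise ValueError("no partition results to report")
    rows = []
    for r in results:
        f = r.fractions()
        rows.append(
            {
                "sample_id": r.sample_id,
                "total_reads": r.total_reads,
                "human_reads": r.counts[SpeciesClass.HUMAN],
                "human_pct": round(f[SpeciesClass.HUMAN], 2),
                "mouse_pct": round(f[SpeciesClass.MOUSE], 2),
                "ambiguous_pct": round(f[SpeciesClass.AMBIGUOUS], 2),
                "unaligned_pct": round(f[SpeciesClass.UNALIGNED], 2),
            }
        )
    return pd.DataFrame(rows)


def write_partition_report(results: list[PartitionResult], path: str | Path) -> None:
    df = partition_report(results)
    df.to_csv(path, sep="\t", index=False, float_format="%.2f")
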