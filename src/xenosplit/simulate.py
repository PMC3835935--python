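"""Synthetic data for testing xenograft RNA-seq deconvolution end to end.

Real xenograft experiments mix human carcinoma reads with murine stromal
reads; separating them requires aligning every read to both genomes.  This
module builds a miniature two-genome world in which the truth is known:
paired orthologous transcripts at a configurable per-base divergence,
truth-labeled reads with independent sequencing errors, SAM alignments
against both references with exact NM (edit distance) tags, negative-binomial
count matrices with planted fold changes, and noisy exponential tumor-growth
series.

Gene models are deliberately single-exon and unspliced: splicing belongs to
the upstream aligner, and unspliced transcripts make exon-containment
counting and per-base pileups exactly checkable by brute force.  There are
no indels — the downstream species classifier compares mismatch counts only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "SimulationConfig",
    "ReferenceSet",
    "SimulatedReads",
    "generate_ortholog_pair",
    "generate_reference_set",
    "simulate_reads",
    "write_fastq",
    "emit_alignments",
    "simulate_counts",
    "simulate_growth",
    "revcomp",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_IDX[_b] = _i
_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN)."""
    return _COMP[_encode(seq)][::-1].tobytes().decode("ascii")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated two-species sequencing experiment.

    ``divergence`` is the per-base substitution probability between a human
    transcript and its murine orthologue (default 0.12, the order of typical
    human-mouse exonic divergence).  ``species_mix`` gives the (human, mouse)
    fragment fractions and must sum to 1.  Defaults emulate a 50 bp
    paired-end library.
    """

    n_genes: int = 50
    gene_length_range: tuple[int, int] = (500, 3000)
    divergence: float = 0.12
    read_length: int = 50
    error_rate: float = 0.01
    species_mix: tuple[float, float] = (0.5, 0.5)
    paired: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        lo, hi = self.gene_length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"bad gene_length_range {self.gene_length_range}")
        for name in ("divergence", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.read_length < 1:
            raise ValueError("read_length must be positive")
        if abs(sum(self.species_mix) - 1.0) > 1e-9:
            raise ValueError("species_mix fractions must sum to 1")
        if min(self.species_mix) < 0:
            raise ValueError("species_mix fractions must be non-negative")


def generate_ortholog_pair(
    length: int,
    divergence: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[str, str, np.ndarray]:
    """Draw a human transcript and a diverged murine orthologue.

    Each base substitutes independently with probability ``divergence`` and a
    substitution never reproduces the original base, so the two sequences
    differ exactly at the returned positions.

    Returns ``(human_seq, mouse_seq, substituted_positions)``.
    """
    if length < 1:
        raise ValueError("length must be positive")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError(f"divergence must lie in [0, 1], got {divergence}")
    if rng is None:
        rng = np.random.default_rng(seed)
    human = _BASES[rng.integers(0, 4, size=length)]
    positions = np.flatnonzero(rng.random(length) < divergence)
    mouse = human.copy()
    if positions.size:
        shift = rng.integers(1, 4, size=positions.size)
        mouse[positions] = _BASES[(_BASE_IDX[human[positions]] + shift) % 4]
    return _decode(human), _decode(mouse), positions


@dataclass
class ReferenceSet:
    """Paired human/mouse transcript references with a 1:1 orthologue map.

    Transcripts double as contigs (one single-exon gene each), so gene i of
    the human side is the orthologue of gene i of the mouse side and shares
    its length and coordinate system.
    """

    human: dict[str, str]
    mouse: dict[str, str]
    pairs: list[tuple[str, str]]
    substituted: dict[str, np.ndarray]  # keyed by human gene id

    @property
    def n_genes(self) -> int:
        return len(self.pairs)

    def sequences(self, species: str) -> dict[str, str]:
        if species not in ("human", "mouse"):
            raise ValueError(f"unknown species {species!r}")
        return self.human if species == "human" else self.mouse

    def partner(self, gene_id: str) -> str:
        """Orthologous gene id in the other species."""
        if not hasattr(self, "_partner"):
            self._partner = {}
            for h, m in self.pairs:
                self._partner[h] = m
                self._partner[m] = h
        return self._partner[gene_id]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA x2, single-exon GTF x2 and the orthologue TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "human_fasta": outdir / "human.fa",
            "mouse_fasta": outdir / "mouse.fa",
            "human_gtf": outdir / "human.gtf",
            "mouse_gtf": outdir / "mouse.gtf",
            "orthologs": outdir / "orthologs.tsv",
        }
        for species in ("human", "mouse"):
            seqs = self.sequences(species)
            with open(paths[f"{species}_fasta"], "w") as fa:
                for gid, seq in seqs.items():
                    fa.write(f">{gid}\n")
                    for i in range(0, len(seq), 60):
                        fa.write(seq[i : i + 60] + "\n")
            with open(paths[f"{species}_gtf"], "w") as gtf:
                for gid, seq in seqs.items():
                    attrs = f'gene_id "{gid}"; transcript_id "{gid}.t1";'
                    for feat in ("gene", "exon"):
                        gtf.write(
                            f"{gid}\txenosplit_sim\t{feat}\t1\t{len(seq)}"
                            f"\t.\t+\t.\t{attrs}\n"
                        )
        with open(paths["orthologs"], "w") as tsv:
            tsv.write("human_gene\tmouse_gene\n")
            for h, m in self.pairs:
                tsv.write(f"{h}\t{m}\n")
        return paths


def generate_reference_set(config: SimulationConfig) -> ReferenceSet:
    """Generate ``config.n_genes`` orthologous transcript pairs.

    Deterministic for a fixed config (same seed gives byte-identical files
    from :meth:`ReferenceSet.write`).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    human: dict[str, str] = {}
    mouse: dict[str, str] = {}
    pairs: list[tuple[str, str]] = []
    substituted: dict[str, np.ndarray] = {}
    for i, L in enumerate(lengths):
        hid, mid = f"HG{i:06d}", f"MG{i:06d}"
        hseq, mseq, pos = generate_ortholog_pair(int(L), config.divergence, rng=rng)
        human[hid] = hseq
        mouse[mid] = mseq
        pairs.append((hid, mid))
        substituted[hid] = pos
    return ReferenceSet(human=human, mouse=mouse, pairs=pairs, substituted=substituted)


@dataclass
class SimulatedReads:
    """Truth-labeled simulated fragments.

    ``truth`` has one row per fragment (mates share one row) with columns
    ``read_id, true_species, source_gene, source_position``.  Mate sequences
    are stored in reference-forward orientation; FASTQ output reverse-
    complements mate 2 to sequencer orientation.
    """

    config: SimulationConfig
    truth: pd.DataFrame
    # parallel per-fragment arrays/lists
    gene_ids: list[str] = field(repr=False, default_factory=list)
    starts: np.ndarray = field(repr=False, default=None)
    frag_lengths: np.ndarray = field(repr=False, default=None)
    mate1: list[np.ndarray] = field(repr=False, default_factory=list)
    mate2: list[np.ndarray] | None = field(repr=False, default=None)
    n_err1: np.ndarray = field(repr=False, default=None)
    n_err2: np.ndarray | None = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return len(self.truth)


def simulate_reads(
    refs: ReferenceSet,
    config: SimulationConfig,
    n_reads: int,
    rng: np.random.Generator | None = None,
) -> SimulatedReads:
    """Draw ``n_reads`` fragments from the two references.

    Species per fragment follows ``config.species_mix``; source gene and
    start position are uniform.  Each base is flipped to a different base
    independently with probability ``config.error_rate``.  In paired mode the
    fragment length is uniform between ``read_length`` and
    ``min(6 * read_length, transcript_length)`` and both mates come from the
    same fragment (insert size >= read_length, mates may overlap).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    rl = config.read_length
    shortest = min(
        min((len(s) for s in refs.human.values()), default=0),
        min((len(s) for s in refs.mouse.values()), default=0),
    )
    if rl > shortest:
        raise ValueError(
            f"read_length {rl} exceeds shortest transcript ({shortest} bp)"
        )

    n = int(n_reads)
    species = (rng.random(n) < config.species_mix[1]).astype(np.int8)  # 1=mouse
    gene_idx = rng.integers(0, refs.n_genes, size=n)
    enc = {
        "human": {g: _encode(s) for g, s in refs.human.items()},
        "mouse": {g: _encode(s) for g, s in refs.mouse.items()},
    }
    lengths = np.array([len(refs.human[h]) for h, _ in refs.pairs])
    L = lengths[gene_idx]
    if config.paired:
        fmax = np.minimum(L, 6 * rl)
        frag = rl + np.floor(rng.random(n) * (fmax - rl + 1)).astype(np.int64)
    else:
        frag = np.full(n, rl, dtype=np.int64)
    starts = np.floor(rng.random(n) * (L - frag + 1)).astype(np.int64)

    err_mask1 = rng.random((n, rl)) < config.error_rate if n else np.zeros((0, rl), bool)
    shift1 = rng.integers(1, 4, size=(n, rl))
    if config.paired:
        err_mask2 = rng.random((n, rl)) < config.error_rate if n else np.zeros((0, rl), bool)
        shift2 = rng.integers(1, 4, size=(n, rl))

    gene_ids: list[str] = []
    mate1: list[np.ndarray] = []
    mate2: list[np.ndarray] | None = [] if config.paired else None
    true_species: list[str] = []
    for i in range(n):
        sp = "mouse" if species[i] else "human"
        gid = refs.pairs[gene_idx[i]][1 if species[i] else 0]
        ref = enc[sp][gid]
        s, f = starts[i], frag[i]
        r1 = ref[s : s + rl].copy()
        m = err_mask1[i]
        if m.any():
            r1[m] = _BASES[(_BASE_IDX[r1[m]] + shift1[i, m]) % 4]
        mate1.append(r1)
        if config.paired:
            r2 = ref[s + f - rl : s + f].copy()
            m2 = err_mask2[i]
            if m2.any():
                r2[m2] = _BASES[(_BASE_IDX[r2[m2]] + shift2[i, m2]) % 4]
            mate2.append(r2)
        gene_ids.append(gid)
        true_species.append(sp)

    truth = pd.DataFrame(
        {
            "read_id": [f"sim{i:07d}" for i in range(n)],
            "true_species": pd.Series(true_species, dtype="object"),
            "source_gene": pd.Series(gene_ids, dtype="object"),
            "source_position": starts,
        }
    )
    return SimulatedReads(
        config=config,
        truth=truth,
        gene_ids=gene_ids,
        starts=starts,
        frag_lengths=frag,
        mate1=mate1,
        mate2=mate2,
        n_err1=err_mask1.sum(axis=1) if n else np.zeros(0, int),
        n_err2=(err_mask2.sum(axis=1) if n else np.zeros(0, int)) if config.paired else None,
    )


def write_fastq(reads: SimulatedReads, path1: str | Path, path2: str | Path | None = None) -> None:
    """Write Phred+33 FASTQ with constant quality; mate names get /1, /2."""
    rl = reads.config.read_length
    qual = "I" * rl
    paired = reads.config.paired
    if paired and path2 is None:
        raise ValueError("paired reads need two FASTQ paths")
    f1 = open(path1, "w")
    f2 = open(path2, "w") if paired else None
    try:
        for i, rid in enumerate(reads.truth["read_id"]):
            f1.write(f"@{rid}/1\n{_decode(reads.mate1[i])}\n+\n{qual}\n")
            if paired:
                f2.write(f"@{rid}/2\n{revcomp(_decode(reads.mate2[i]))}\n+\n{qual}\n")
    finally:
        f1.close()
        if f2:
            f2.close()


def _sam_header(seqs: dict[str, str]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": g, "LN": len(s)} for g, s in seqs.items()],
        }
    )


def emit_alignments(
    reads: SimulatedReads,
    refs: ReferenceSet,
    sam_human: str | Path,
    sam_mouse: str | Path,
    max_mismatch: int | None = None,
) -> None:
    """Write each fragment's alignment against both genomes as SAM.

    The simulator knows every fragment's true locus and, because orthologues
    share coordinates, the corresponding locus in the other genome, so it
    writes both alignments directly with NM equal to the Hamming distance
    between the read and the reference window.  A mate whose distance exceeds
    ``max_mismatch`` (when given) is emitted as an unmapped record instead.
    """
    rl = reads.config.read_length
    paired = reads.config.paired
    enc = {
        "human": {g: _encode(s) for g, s in refs.human.items()},
        "mouse": {g: _encode(s) for g, s in refs.mouse.items()},
    }
    for species, path in (("human", sam_human), ("mouse", sam_mouse)):
        seqs = refs.sequences(species)
        header = _sam_header(seqs)
        tid = {g: i for i, g in enumerate(seqs)}
        with pysam.AlignmentFile(str(path), "wh", header=header) as out:
            for i, rid in enumerate(reads.truth["read_id"]):
                src = reads.truth["true_species"].iat[i]
                gid = reads.gene_ids[i]
                gid_here = gid if src == species else refs.partner(gid)
                ref = enc[species][gid_here]
                s = int(reads.starts[i])
                f = int(reads.frag_lengths[i])
                nm1 = int((reads.mate1[i] != ref[s : s + rl]).sum())
                un1 = max_mismatch is not None and nm1 > max_mismatch
                if paired:
                    s2 = s + f - rl
                    nm2 = int((reads.mate2[i] != ref[s2 : s2 + rl]).sum())
                    un2 = max_mismatch is not None and nm2 > max_mismatch
                    _write_pair(out, rid, tid[gid_here], s, s2, f,
                                reads.mate1[i], reads.mate2[i], nm1, nm2, un1, un2)
                else:
                    a = _segment(rid, tid[gid_here], s, reads.mate1[i], nm1, un1)
                    out.write(a)


def _segment(rid, tid, pos, seq, nm, unmapped, flag=0):
    a = pysam.AlignedSegment()
    a.query_name = rid
    a.query_sequence = _decode(seq)
    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    a.flag = flag | (0x4 if unmapped else 0)
    a.reference_id = tid
    a.reference_start = pos
    if unmapped:
        a.mapping_quality = 0
    else:
        a.mapping_quality = 50
        a.cigar = [(0, len(seq))]
        a.set_tag("NM", nm)
    return a


def _write_pair(out, rid, tid, s1, s2, frag, seq1, seq2, nm1, nm2, un1, un2):
    # mate 1 forward, mate 2 reverse; SEQ stored reference-forward per SAM
    proper = not (un1 or un2)
    f1 = 0x1 | 0x40 | (0x2 if proper else 0) | (0x20 if not un2 else 0) | (0x8 if un2 else 0)
    f2 = 0x1 | 0x80 | (0x2 if proper else 0) | (0x10 if not un2 else 0) | (0x8 if un1 else 0)
    a1 = _segment(rid, tid, s1, seq1, nm1, un1, flag=f1)
    a2 = _segment(rid, tid, s2, seq2, nm2, un2, flag=f2)
    a1.next_reference_id = tid
    a2.next_reference_id = tid
    a1.next_reference_start = s2
    a2.next_reference_start = s1
    if proper:
        a1.template_length = frag
        a2.template_length = -frag
    out.write(a1)
    out.write(a2)


def simulate_counts(
    n_genes: int,
    n_per_group: int,
    mean_range: tuple[float, float] = (20.0, 2000.0),
    dispersion: float = 0.1,
    de_fraction: float = 0.0,
    fold_change: float = 2.0,
    seed: int | None = None,
):
    """Negative-binomial count matrix with planted differential expression.

    Gene means are log-uniform over ``mean_range``; a ``de_fraction`` of
    genes get their group-B mean multiplied by ``fold_change``.  Counts are
    NB with the stated dispersion (variance = m + dispersion * m^2);
    ``dispersion=0`` is the Poisson limit.

    Returns ``(CountMatrix, is_de)`` where ``is_de`` is a boolean array of
    the planted truth.
    """
    from .quantify import CountMatrix

    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if fold_change <= 0:
        raise ValueError("fold_change must be > 0")
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lo, hi = mean_range
    means = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    n_de = int(round(de_fraction * n_genes))
    is_de = np.zeros(n_genes, dtype=bool)
    if n_de:
        is_de[rng.choice(n_genes, size=n_de, replace=False)] = True
    mean_a = means
    mean_b = np.where(is_de, means * fold_change, means)

    def draw(mean_vec, n_samples):
        m = np.tile(mean_vec[:, None], (1, n_samples))
        if dispersion == 0:
            return rng.poisson(m)
        r = 1.0 / dispersion
        p = r / (r + m)
        return rng.negative_binomial(r, p)

    counts = np.hstack([draw(mean_a, n_per_group), draw(mean_b, n_per_group)])
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"A{j + 1}" for j in range(n_per_group)] + [
        f"B{j + 1}" for j in range(n_per_group)
    ]
    df = pd.DataFrame(counts, index=genes, columns=samples)
    totals = df.sum(axis=0).astype(float)
    return CountMatrix(counts=df, library_totals=totals, species="human"), is_de


def simulate_growth(
    V0: float,
    doubling_time: float,
    timepoints,
    noise_sd: float = 0.0,
    seed: int | None = None,
    sample_id: str = "sim",
):
    """Exponential tumor volume series V0 * 2^(t/Td) with log-normal noise."""
    from .growth import GrowthSeries

    if V0 <= 0:
        raise ValueError("V0 must be positive")
    if doubling_time <= 0:
        raise ValueError("doubling_time must be positive")
    rng = np.random.default_rng(seed)
    t = np.asarray(timepoints, dtype=float)
    eps = rng.normal(0.0, noise_sd, size=t.size) if noise_sd > 0 else np.zeros(t.size)
    volumes = V0 * np.power(2.0, t / doubling_time) * np.exp(eps)
    return GrowthSeries(sample_id=sample_id, timepoints=t, volumes=volumes)
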