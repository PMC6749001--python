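"""Assembly quality operations: gap finding, gap closure, QV, contiguity.

A gap is a maximal run of >= 2 N bases (a lone N is not a gap; the minimum
run is configurable).  Gap closure extracts up to 5 kb of flanking sequence
on each side of a gap, locates each flank on the new assembly through the
unique-k-mer anchor machinery, and declares the gap closed when both flanks
map (> 2.5 kb of chained-anchor footprint each) to the same assembly
chromosome in consistent orientation and order with non-N bases between the
rightmost coordinate reached by the upstream flank (LC) and the leftmost
coordinate of the downstream flank (RC).  The bases in [LC, RC) are the
closed-gap sequence.

QV is the standard -10*log10(P) with P the per-base error probability
(homozygous variants / assembly size).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

from .io_formats import GenomeSequence, GenomicInterval
from .lineage import (
    KmerIndex,
    _junction_extension,
    chain_anchors,
    kmer_index,
    unique_anchors,
)

__all__ = [
    "GapRecord",
    "find_gaps",
    "ClosureRecord",
    "close_gaps",
    "QVResult",
    "compute_qv",
    "AssemblyStats",
    "assembly_stats",
    "n50",
]


@dataclass(frozen=True)
class GapRecord:
    interval: GenomicInterval

    @property
    def length(self) -> int:
        return len(self.interval)


def find_gaps(genome: GenomeSequence, min_run: int = 2) -> list[GapRecord]:
    """Maximal N runs of length >= ``min_run``, sorted by (chrom, start)."""
    pattern = re.compile("N{%d,}" % min_run)
    gaps = []
    for chrom in genome:
        for m in pattern.finditer(genome[chrom]):
            gaps.append(GapRecord(GenomicInterval(chrom, m.start(), m.end())))
    return gaps


# ---------------------------------------------------------------------------
# gap closure
# ---------------------------------------------------------------------------

@dataclass
class ClosureRecord:
    gap: GapRecord
    status: str                     # closed | unclosed | flank_fail
    assembly_chrom: str | None = None
    LC: int | None = None           # rightmost assembly coord reached upstream
    RC: int | None = None           # leftmost assembly coord of downstream flank
    closed_length: int | None = None
    filled_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.status == "closed":
            assert self.LC is not None and self.RC is not None and self.LC < self.RC
            assert self.closed_length == self.RC - self.LC
            assert self.filled_sequence is not None and "N" not in self.filled_sequence


def _map_flank(flank_seq: str, asm_index: KmerIndex, assembly: GenomeSequence,
               min_aligned: int, k: int):
    """Locate one flank on the assembly; returns the best chain or a failure tag.

    The flank is treated as a miniature genome; anchors are its k-mers that
    are unique both within the flank and genome-wide in the assembly.  A
    flank maps when its best chain's merged anchor footprint on the flank
    exceeds ``min_aligned``; two distinct loci with equal best footprint
    are ambiguous and fail.
    """
    if len(flank_seq) < k:
        return None
    mini = GenomeSequence("flank", {"flank": flank_seq})
    anchors = unique_anchors(kmer_index(mini, k), asm_index)
    # anchors: ref = flank, qry = assembly
    chains = chain_anchors(anchors, max_chain_gap=len(flank_seq))
    scored = []
    for c in chains:
        cov = c.anchor_coverage(frame="ref")
        scored.append((cov, c))
    scored.sort(key=lambda t: -t[0])
    if not scored or scored[0][0] <= min_aligned:
        return None
    best_cov, best = scored[0]
    if len(scored) > 1 and scored[1][0] == best_cov:
        other = scored[1][1]
        same_locus = (other.qry_chrom == best.qry_chrom
                      and abs(int(other.qry_pos[0]) - int(best.qry_pos[0])) < len(flank_seq))
        if not same_locus:
            return "ambiguous"
    return best


def close_gaps(gapped_ref: GenomeSequence, assembly: GenomeSequence,
               flank: int = 5000, min_aligned: int = 2500, k: int = 31,
               min_gap_run: int = 2) -> list[ClosureRecord]:
    """Attempt to close every gap of ``gapped_ref`` using ``assembly``."""
    asm_index = kmer_index(assembly, k)
    records: list[ClosureRecord] = []
    for gap in find_gaps(gapped_ref, min_run=min_gap_run):
        chrom = gap.interval.chrom
        seq = gapped_ref[chrom]
        up = seq[max(0, gap.interval.start - flank) : gap.interval.start]
        down = seq[gap.interval.end : gap.interval.end + flank]
        up_chain = _map_flank(up, asm_index, assembly, min_aligned, k)
        down_chain = _map_flank(down, asm_index, assembly, min_aligned, k)
        if up_chain is None or down_chain is None or "ambiguous" in (up_chain, down_chain):
            records.append(ClosureRecord(gap=gap, status="flank_fail"))
            continue
        consistent = (
            up_chain.qry_chrom == down_chain.qry_chrom
            and up_chain.orientation == "+" and down_chain.orientation == "+"
        )
        if not consistent:
            records.append(ClosureRecord(gap=gap, status="unclosed"))
            continue
        asm_seq = assembly[up_chain.qry_chrom]
        # extend exact matches from the terminal anchors to the gap junction,
        # so LC/RC land on the junction even when the last unique anchor
        # stops short of it (e.g. a repeat bordering the gap)
        ui = int(np.argmax(up_chain.ref_pos))
        fl, ap = int(up_chain.ref_pos[ui]), int(up_chain.qry_pos[ui])
        lc = ap + k + _junction_extension(up[fl + k :], asm_seq[ap + k :])
        di = int(np.argmin(down_chain.ref_pos))
        fd, ad = int(down_chain.ref_pos[di]), int(down_chain.qry_pos[di])
        rc = ad - _junction_extension(down[:fd][::-1], asm_seq[max(0, ad - fd) : ad][::-1])
        if rc <= lc:
            records.append(ClosureRecord(gap=gap, status="unclosed",
                                         assembly_chrom=up_chain.qry_chrom,
                                         LC=lc, RC=rc))
            continue
        filled = assembly[up_chain.qry_chrom][lc:rc]
        if "N" in filled:
            records.append(ClosureRecord(gap=gap, status="unclosed",
                                         assembly_chrom=up_chain.qry_chrom,
                                         LC=lc, RC=rc))
            continue
        records.append(
            ClosureRecord(gap=gap, status="closed", assembly_chrom=up_chain.qry_chrom,
                          LC=lc, RC=rc, closed_length=rc - lc, filled_sequence=filled)
        )
    return records


# ---------------------------------------------------------------------------
# QV
# ---------------------------------------------------------------------------

@dataclass
class QVResult:
    n_homozygous_variants: int
    assembly_size: int
    error_rate: float
    qv: float
    qv_rounded: int | None
    infinite: bool = False


def compute_qv(n_homozygous_variants: int, assembly_size: int) -> QVResult:
    """QV = -10*log10(P) with P = homozygous variants per assembly base."""
    if assembly_size <= 0:
        raise ValueError("assembly_size must be positive")
    if n_homozygous_variants < 0:
        raise ValueError("variant count must be >= 0")
    if n_homozygous_variants == 0:
        return QVResult(0, assembly_size, 0.0, math.inf, None, infinite=True)
    p = n_homozygous_variants / assembly_size
    qv = -10.0 * math.log10(p)
    return QVResult(n_homozygous_variants, assembly_size, p, qv, int(round(qv)))


# ---------------------------------------------------------------------------
# contiguity
# ---------------------------------------------------------------------------

def n50(lengths) -> int:
    """Length L such that segments >= L sum to at least half the total."""
    arr = sorted((int(x) for x in lengths), reverse=True)
    if not arr:
        raise ValueError("empty length list")
    half = sum(arr) / 2
    acc = 0
    for L in arr:
        acc += L
        if acc >= half:
            return L
    return arr[-1]  # pragma: no cover


@dataclass
class AssemblyStats:
    n_contigs: int
    n_scaffolds: int
    contig_n50: int
    scaffold_n50: int
    total_bases: int
    ungapped_bases: int


def assembly_stats(genome: GenomeSequence, min_gap_run: int = 2) -> AssemblyStats:
    """Contiguity statistics: contigs are scaffold segments split at N runs."""
    if len(genome) == 0:
        raise ValueError("empty genome")
    scaffold_lengths = []
    contig_lengths = []
    ungapped = 0
    pattern = re.compile("N{%d,}" % min_gap_run)
    for chrom in genome:
        seq = genome[chrom]
        scaffold_lengths.append(len(seq))
        ungapped += len(seq) - seq.count("N")
        for part in pattern.split(seq):
            if part:
                contig_lengths.append(len(part))
    return AssemblyStats(
        n_contigs=len(contig_lengths),
        n_scaffolds=len(scaffold_lengths),
        contig_n50=n50(contig_lengths),
        scaffold_n50=n50(scaffold_lengths),
        total_bases=sum(scaffold_lengths),
        ungapped_bases=ungapped,
    )
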