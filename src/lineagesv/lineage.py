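"""Anchor-based pairwise SV calling and ape-specific SV (ASSV) inference.

The alignment layer is deliberately minimal: k-mers that occur exactly once
in each of the two genomes (canonical-form counting) serve as alignment
anchors; the maximum colinear subset of anchors (longest increasing
subsequence on query positions) forms a synteny chain; length differences
between adjacent anchors in a chain are called as insertions or deletions
(>= 50 bp).  Duplications and inversions are not called by this engine --
lineage-specific inference downstream is restricted to the two SV types that
dominate assembly comparisons.

Polarity is ape-centric throughout: with the macaque assembly as the
reference frame, a DEL means the sequence is present in macaque (and, for an
ancestral ape event, in marmoset) and absent in the ape; an INS means the
apes carry sequence the macaque lacks.

The downstream pipeline mirrors a forward/reverse concordance filter, a
cross-ape intersection, a dual human-coordinate overlay, and outgroup
classification of each candidate into high_confident / uncertain / false.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import GenomeSequence, GenomicInterval
from .svcore import SVCallset, SVRecord, reciprocal_overlap

__all__ = [
    "KmerIndex",
    "kmer_index",
    "Anchors",
    "unique_anchors",
    "SyntenyChain",
    "chain_anchors",
    "call_pairwise_svs",
    "call_svs_between",
    "swap_frame",
    "bidirectional_concordance",
    "concordant_pairwise_calls",
    "LineageCall",
    "intersect_across_apes",
    "overlay_human_coordinates",
    "HomologyMap",
    "outgroup_classify",
    "classify_great_ape",
]

# base encoding: A=0 C=1 G=2 T=3, anything else (N) = 4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int):
    """Canonical 2-bit packed k-mer codes for every window of ``codes``.

    Returns (canonical, is_forward, valid) arrays of length ``n - k + 1``;
    windows containing N are invalid.
    """
    n = codes.size - k + 1
    if n <= 0:
        z = np.zeros(0, dtype=np.uint64)
        return z, np.zeros(0, dtype=bool), np.zeros(0, dtype=bool)
    c = codes.astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        fwd = (fwd << np.uint64(2)) | c[i : i + n]
        rev |= ((np.uint64(3) - c[i : i + n]) & np.uint64(3)) << np.uint64(2 * i)
    is_n = (codes == 4).astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(is_n)])
    valid = (cs[k:] - cs[:-k]) == 0
    canonical = np.minimum(fwd, rev)
    is_forward = fwd <= rev
    return canonical, is_forward, valid


@dataclass
class KmerIndex:
    """Genome-wide unique k-mers of one genome, sorted by canonical code."""

    k: int
    codes: np.ndarray       # sorted canonical codes, each occurring once genome-wide
    chrom: np.ndarray       # chromosome index per code
    pos: np.ndarray         # forward-strand start position per code
    strand: np.ndarray      # True where the forward k-mer is the canonical form
    chrom_names: list[str]


def kmer_index(genome: GenomeSequence, k: int = 31) -> KmerIndex:
    """Index the k-mers occurring exactly once (canonical counting) in ``genome``."""
    if not (15 <= k <= 63) or k % 2 == 0:
        raise ValueError(f"k must be odd and in [15, 63], got {k}")
    names = list(genome.chromosomes)
    all_canon, all_chrom, all_pos, all_strand = [], [], [], []
    for ci, chrom in enumerate(names):
        canon, is_fwd, valid = _kmer_codes(_encode(genome[chrom]), k)
        idx = np.nonzero(valid)[0]
        all_canon.append(canon[idx])
        all_chrom.append(np.full(idx.size, ci, dtype=np.int32))
        all_pos.append(idx.astype(np.int64))
        all_strand.append(is_fwd[idx])
    canon = np.concatenate(all_canon) if all_canon else np.zeros(0, dtype=np.uint64)
    chrom = np.concatenate(all_chrom) if all_chrom else np.zeros(0, dtype=np.int32)
    pos = np.concatenate(all_pos) if all_pos else np.zeros(0, dtype=np.int64)
    strand = np.concatenate(all_strand) if all_strand else np.zeros(0, dtype=bool)
    order = np.argsort(canon, kind="stable")
    sc = canon[order]
    first = np.ones(sc.size, dtype=bool)
    if sc.size > 1:
        first[1:] = sc[1:] != sc[:-1]
    boundaries = np.nonzero(first)[0]
    run_len = np.diff(np.append(boundaries, sc.size))
    singles = boundaries[run_len == 1]
    keep = order[singles]
    return KmerIndex(
        k=k,
        codes=canon[keep],
        chrom=chrom[keep],
        pos=pos[keep],
        strand=strand[keep],
        chrom_names=names,
    )


@dataclass
class Anchors:
    """Shared unique k-mer anchors between a reference and a query genome."""

    k: int
    ref_chrom: np.ndarray
    ref_pos: np.ndarray
    qry_chrom: np.ndarray
    qry_pos: np.ndarray
    forward: np.ndarray     # True where the two occurrences share orientation
    ref_names: list[str]
    qry_names: list[str]

    def __len__(self) -> int:
        return self.ref_pos.size


def unique_anchors(genome_a: GenomeSequence | KmerIndex,
                   genome_b: GenomeSequence | KmerIndex,
                   k: int = 31) -> Anchors:
    """Anchors from k-mers unique in both genomes, sorted by reference position.

    Either argument may be a pre-built :class:`KmerIndex` (they are reused
    heavily across pairwise comparisons).
    """
    ia = genome_a if isinstance(genome_a, KmerIndex) else kmer_index(genome_a, k)
    ib = genome_b if isinstance(genome_b, KmerIndex) else kmer_index(genome_b, k)
    if ia.k != ib.k:
        raise ValueError("k-mer indexes built with different k")
    _, ai, bi = np.intersect1d(ia.codes, ib.codes, assume_unique=True, return_indices=True)
    order = np.lexsort((ia.pos[ai], ia.chrom[ai]))
    ai, bi = ai[order], bi[order]
    return Anchors(
        k=ia.k,
        ref_chrom=ia.chrom[ai],
        ref_pos=ia.pos[ai],
        qry_chrom=ib.chrom[bi],
        qry_pos=ib.pos[bi],
        forward=ia.strand[ai] == ib.strand[bi],
        ref_names=ia.chrom_names,
        qry_names=ib.chrom_names,
    )


@dataclass
class SyntenyChain:
    """A colinear run of anchors between one reference and one query chromosome."""

    ref_chrom: str
    qry_chrom: str
    orientation: str        # '+' or '-'
    ref_pos: np.ndarray     # strictly increasing
    qry_pos: np.ndarray     # strictly monotone (direction per orientation)
    k: int

    def __len__(self) -> int:
        return self.ref_pos.size

    @property
    def ref_footprint(self) -> tuple[int, int]:
        return int(self.ref_pos[0]), int(self.ref_pos[-1]) + self.k

    @property
    def qry_footprint(self) -> tuple[int, int]:
        lo, hi = int(self.qry_pos.min()), int(self.qry_pos.max()) + self.k
        return lo, hi

    def anchor_coverage(self, frame: str = "ref") -> int:
        """Total bases covered by the merged anchor footprints on one frame."""
        pos = np.sort(self.ref_pos if frame == "ref" else self.qry_pos)
        if pos.size == 0:
            return 0
        gaps = np.diff(pos)
        return int(self.k + np.minimum(gaps, self.k).sum())


def _lis_indices(values: list[int]) -> list[int]:
    """Indices of a longest strictly increasing subsequence (patience sorting)."""
    tails: list[int] = []
    tails_idx: list[int] = []
    parent = [-1] * len(values)
    for i, x in enumerate(values):
        j = bisect.bisect_left(tails, x)
        if j == len(tails):
            tails.append(x)
            tails_idx.append(i)
        else:
            tails[j] = x
            tails_idx[j] = i
        parent[i] = tails_idx[j - 1] if j > 0 else -1
    out: list[int] = []
    i = tails_idx[-1] if tails_idx else -1
    while i >= 0:
        out.append(i)
        i = parent[i]
    out.reverse()
    return out


def chain_anchors(anchors: Anchors, max_chain_gap: int = 100_000,
                  min_offset_run: int = 2) -> list[SyntenyChain]:
    """Chain anchors into colinear blocks per (ref chrom, qry chrom, orientation).

    Within each block the maximum-cardinality colinear subset is found by a
    longest-increasing-subsequence on query positions (decreasing for '-'
    orientation); chains are split where adjacent anchors are farther apart
    than ``max_chain_gap`` on either genome.

    Anchors whose ref/query offset is not shared with at least
    ``min_offset_run - 1`` neighbouring anchors are removed: orthologous
    regions yield runs of anchors at a constant offset, whereas a k-mer
    accidentally unique in two non-orthologous repeat copies is an offset
    singleton that would otherwise fragment the gap arithmetic between its
    neighbours.  Set ``min_offset_run=1`` to disable the cleaning pass.
    """
    chains: list[SyntenyChain] = []
    if len(anchors) == 0:
        return chains
    keys = (anchors.ref_chrom.astype(np.int64) << 33) \
        | (anchors.qry_chrom.astype(np.int64) << 1) \
        | anchors.forward.astype(np.int64)
    for key in np.unique(keys):
        sel = np.nonzero(keys == key)[0]     # already sorted by ref position
        rpos = anchors.ref_pos[sel]
        qpos = anchors.qry_pos[sel]
        fwd = bool(key & 1)
        mono = qpos if fwd else -qpos
        if mono.size < 2 or bool(np.all(np.diff(mono) > 0)):
            rp, qp = rpos, qpos          # already colinear: LIS is everything
        else:
            lis = _lis_indices(mono.tolist())
            rp = rpos[lis]
            qp = qpos[lis]
        if min_offset_run > 1 and rp.size:
            offs = qp - rp if fwd else qp + rp
            same_prev = np.zeros(rp.size, dtype=bool)
            same_next = np.zeros(rp.size, dtype=bool)
            if rp.size > 1:
                eq = offs[1:] == offs[:-1]
                same_prev[1:] = eq
                same_next[:-1] = eq
            keep = same_prev | same_next
            rp, qp = rp[keep], qp[keep]
        # split on large gaps
        if rp.size == 0:
            continue
        gaps = np.maximum(np.abs(np.diff(rp)), np.abs(np.diff(qp)))
        breaks = np.nonzero(gaps > max_chain_gap)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [rp.size]])
        for s, e in zip(starts, ends):
            if e - s == 0:
                continue
            chains.append(
                SyntenyChain(
                    ref_chrom=anchors.ref_names[int(anchors.ref_chrom[sel[0]])],
                    qry_chrom=anchors.qry_names[int(anchors.qry_chrom[sel[0]])],
                    orientation="+" if fwd else "-",
                    ref_pos=rp[s:e],
                    qry_pos=qp[s:e],
                    k=anchors.k,
                )
            )
    chains.sort(key=lambda c: (c.ref_chrom, int(c.ref_pos[0])))
    return chains


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    if n == 0:
        return 0
    x = np.frombuffer(a[:n].encode(), dtype=np.uint8)
    y = np.frombuffer(b[:n].encode(), dtype=np.uint8)
    neq = np.nonzero(x != y)[0]
    return n if neq.size == 0 else int(neq[0])


def _common_suffix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    if n == 0:
        return 0
    x = np.frombuffer(a[-n:].encode(), dtype=np.uint8)
    y = np.frombuffer(b[-n:].encode(), dtype=np.uint8)
    neq = np.nonzero(x[::-1] != y[::-1])[0]
    return n if neq.size == 0 else int(neq[0])


def _junction_extension(a: str, b: str) -> int:
    """Length of the homologous prefix shared by ``a`` and ``b``.

    Scores +1 per match and -4 per mismatch and returns the end of the
    maximal-scoring prefix: isolated substitutions inside a homologous
    flank are tolerated, while the transition into unrelated sequence at
    the event junction (about 25% chance agreement) turns the score
    decisively downward.  Equals the exact common prefix on divergence-free
    input.
    """
    n = min(len(a), len(b))
    if n == 0:
        return 0
    x = np.frombuffer(a[:n].encode(), dtype=np.uint8)
    y = np.frombuffer(b[:n].encode(), dtype=np.uint8)
    score = np.where(x == y, 1, -4).cumsum()
    j = int(score.argmax())
    return j + 1 if score[j] > 0 else 0


def call_pairwise_svs(chain: SyntenyChain, ref: GenomeSequence, query: GenomeSequence,
                      min_len: int = 50, source: str = "") -> SVCallset:
    """Call insertions/deletions from length differences between adjacent anchors.

    For each adjacent anchor pair let ``d = (query gap) - (ref gap)``;
    ``d >= min_len`` is an INS in the query, ``d <= -min_len`` a DEL in the
    query, coordinates in the reference frame.  Breakpoints are refined by
    extending exact matches inward from both anchors, so on divergence-free
    input the reported interval is the exact event locus.  Only '+' chains
    are called; anchor pairs with overlapping footprints are skipped.
    """
    records: list[SVRecord] = []
    if chain.orientation != "+" or len(chain) < 2:
        return SVCallset(records, source=source)
    k = chain.k
    rseq = ref[chain.ref_chrom]
    qseq = query[chain.qry_chrom]
    skipped = 0
    # vectorised candidate scan: only anchor pairs with |d| >= min_len matter
    dr = np.diff(chain.ref_pos)
    dq = np.diff(chain.qry_pos)
    candidates = np.nonzero(np.abs(dq - dr) >= min_len)[0]
    for i in candidates:
        ri, rj = int(chain.ref_pos[i]), int(chain.ref_pos[i + 1])
        qi, qj = int(chain.qry_pos[i]), int(chain.qry_pos[i + 1])
        if rj <= ri or qj <= qi:  # degenerate ordering; cannot happen in a chain
            skipped += 1
            continue
        gr = rj - (ri + k)
        gq = qj - (qi + k)
        d = gq - gr
        if abs(d) < min_len:
            continue
        cap = min(gr, gq)
        if cap >= 0:
            e_l = _junction_extension(rseq[ri + k : ri + k + cap],
                                      qseq[qi + k : qi + k + cap])
        else:
            # anchors overlap on the shorter side: the junction lies within
            # breakpoint micro-homology; pull the junction back so the event
            # ends exactly at the right anchor
            e_l = cap
        if d <= -min_len:
            s = ri + k + e_l
            length = -d
            records.append(
                SVRecord(
                    interval=GenomicInterval(chain.ref_chrom, s, s + length),
                    type="DEL",
                    length=length,
                    id=f"{source or 'sv'}_DEL_{chain.ref_chrom}_{s}",
                    inserted_sequence=rseq[s : s + length],
                    source=source,
                    mate=(chain.qry_chrom, qi + k + e_l, qi + k + e_l),
                )
            )
        else:
            p = ri + k + e_l
            qp = qi + k + e_l
            records.append(
                SVRecord.insertion(
                    chain.ref_chrom,
                    p,
                    qseq[qp : qp + d],
                    id=f"{source or 'sv'}_INS_{chain.ref_chrom}_{p}",
                    source=source,
                    mate=(chain.qry_chrom, qp, qp + d),
                )
            )
    if skipped:
        warnings.warn(f"{skipped} anchor pairs with overlapping footprints skipped")
    return SVCallset(records, source=source)


def call_svs_between(ref: GenomeSequence | KmerIndex, query: GenomeSequence | KmerIndex,
                     ref_seq: GenomeSequence | None = None,
                     query_seq: GenomeSequence | None = None,
                     k: int = 31, min_len: int = 50,
                     max_chain_gap: int = 100_000, source: str = "") -> SVCallset:
    """Anchor, chain and call SVs between two genomes in one step.

    ``ref``/``query`` may be pre-built k-mer indexes, in which case the
    corresponding ``*_seq`` genome must be supplied for sequence capture.
    """
    rg = ref_seq if isinstance(ref, KmerIndex) else ref
    qg = query_seq if isinstance(query, KmerIndex) else query
    anchors = unique_anchors(ref, query, k)
    records: list[SVRecord] = []
    for chain in chain_anchors(anchors, max_chain_gap):
        records.extend(call_pairwise_svs(chain, rg, qg, min_len=min_len, source=source))
    return SVCallset(records, source=source)


def swap_frame(callset: SVCallset, source: str | None = None) -> SVCallset:
    """Re-express pairwise calls in the partner genome's frame.

    A DEL (query missing reference sequence) becomes an INS in the query
    frame and vice versa; the variant sequence travels unchanged.  Used to
    project reverse-direction calls into the forward (macaque) frame.
    """
    out: list[SVRecord] = []
    src = callset.source if source is None else source
    for r in callset:
        if r.mate is None:
            raise ValueError(f"record {r.id} has no partner-frame coordinates")
        mchrom, ms, me = r.mate
        if r.type == "DEL":
            rec = SVRecord.insertion(
                mchrom, ms, r.inserted_sequence,
                id=f"{src or 'sv'}_INS_{mchrom}_{ms}",
                source=src,
                mate=(r.interval.chrom, r.interval.start, r.interval.end),
            )
        elif r.type == "INS":
            rec = SVRecord(
                interval=GenomicInterval(mchrom, ms, me),
                type="DEL",
                length=r.length,
                id=f"{src or 'sv'}_DEL_{mchrom}_{ms}",
                inserted_sequence=r.inserted_sequence,
                source=src,
                mate=(r.interval.chrom, r.interval.start, r.interval.start),
            )
        else:
            raise ValueError(f"cannot swap frame for type {r.type}")
        out.append(rec)
    return SVCallset(out, source=src)


def _partner(rec: SVRecord, callset: SVCallset, threshold: float) -> SVRecord | None:
    best = None
    best_frac = -1.0
    for other in callset:
        if other.type != rec.type or other.interval.chrom != rec.interval.chrom:
            continue
        ov = rec.interval.overlap_len(other.interval)
        if ov > threshold * rec.length and ov > threshold * other.length:
            frac = min(ov / rec.length, ov / other.length)
            if frac > best_frac:
                best, best_frac = other, frac
    return best


def bidirectional_concordance(forward: SVCallset, reverse: SVCallset,
                              threshold: float = 0.5) -> SVCallset:
    """Keep forward calls with a reciprocal-overlap, type-matched partner in
    the (already projected) reverse callset -- a monotone filter."""
    trees: dict = {}
    for idx, r in enumerate(reverse):
        trees.setdefault((r.interval.chrom, r.type), []).append(r)
    kept = []
    for r in forward:
        for other in trees.get((r.interval.chrom, r.type), ()):
            ov = r.interval.overlap_len(other.interval)
            if ov > threshold * r.length and ov > threshold * other.length:
                kept.append(r)
                break
    return SVCallset(kept, source=forward.source)


def concordant_pairwise_calls(ref, query, ref_seq=None, query_seq=None,
                              k: int = 31, min_len: int = 50,
                              max_chain_gap: int = 100_000,
                              threshold: float = 0.5,
                              source: str = "") -> SVCallset:
    """Forward + reverse calling with concordance filtering for one genome pair."""
    fwd = call_svs_between(ref, query, ref_seq, query_seq, k=k, min_len=min_len,
                           max_chain_gap=max_chain_gap, source=source)
    rev = call_svs_between(query, ref, query_seq, ref_seq, k=k, min_len=min_len,
                           max_chain_gap=max_chain_gap, source=source + "_rev")
    rev_proj = swap_frame(rev)
    return bidirectional_concordance(fwd, rev_proj, threshold=threshold)


# ---------------------------------------------------------------------------
# cross-ape intersection and human-coordinate overlay
# ---------------------------------------------------------------------------

@dataclass
class LineageCall:
    """A candidate lineage-specific SV in the macaque reference frame."""

    sv: SVRecord
    support: dict[str, str] = field(default_factory=dict)   # ape -> matched id
    human_interval: tuple[str, int, int] | None = None
    human_frame_missing: bool = False
    outgroup_class: str | None = None        # high_confident | uncertain | false
    identity_prefilter: float | None = None
    great_ape_class: str | None = None       # ASSV | GASSV | uncertain


def intersect_across_apes(per_ape: dict[str, SVCallset], threshold: float = 0.5,
                          pivot: str = "human") -> list[LineageCall]:
    """Keep SVs supported by *every* ape comparison (the defining ASSV filter).

    The representative record comes from the pivot ape (default human); the
    support map holds the matched call id from each comparison.
    """
    if len(per_ape) < 2:
        raise ValueError("need at least two ape callsets")
    if pivot not in per_ape:
        raise ValueError(f"pivot ape {pivot!r} not among callsets")
    others = [a for a in sorted(per_ape) if a != pivot]
    calls: list[LineageCall] = []
    for rec in per_ape[pivot]:
        support = {pivot: rec.id}
        ok = True
        for ape in others:
            partner = _partner(rec, per_ape[ape], threshold)
            if partner is None:
                ok = False
                break
            support[ape] = partner.id
        if ok:
            calls.append(LineageCall(sv=rec, support=support))
    return calls


def overlay_human_coordinates(calls: list[LineageCall], calls_vs_grch38: SVCallset,
                              threshold: float = 0.5) -> list[LineageCall]:
    """Attach human-frame coordinates by matching against the GRCh38-based callset.

    Both callsets live in the macaque frame; a matched call gains the
    GRCh38-frame interval from the partner's mate coordinates, an unmatched
    call keeps macaque coordinates only and is flagged.
    """
    for call in calls:
        partner = _partner(call.sv, calls_vs_grch38, threshold)
        if partner is not None and partner.mate is not None:
            call.human_interval = partner.mate
            call.human_frame_missing = False
        else:
            call.human_interval = None
            call.human_frame_missing = True
    return calls


# ---------------------------------------------------------------------------
# outgroup classification
# ---------------------------------------------------------------------------

class HomologyMap:
    """Anchor-based coordinate correspondence between a reference genome and
    another genome (marmoset or gibbon role), for local span comparisons."""

    def __init__(self, ref: GenomeSequence, other: GenomeSequence,
                 k: int = 31, max_chain_gap: int = 100_000) -> None:
        self.ref = ref
        self.other = other
        self.k = k
        anchors = unique_anchors(ref, other, k)
        chains = chain_anchors(anchors, max_chain_gap)
        self._per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[tuple[np.ndarray, np.ndarray, str]]] = {}
        for c in chains:
            if c.orientation != "+":
                continue
            by_chrom.setdefault(c.ref_chrom, []).append((c.ref_pos, c.qry_pos, c.qry_chrom))
        other_names = list(other.chromosomes)
        name_idx = {n: i for i, n in enumerate(other_names)}
        self._other_names = other_names
        for chrom, parts in by_chrom.items():
            rp = np.concatenate([p[0] for p in parts])
            qp = np.concatenate([p[1] for p in parts])
            qc = np.concatenate([np.full(p[0].size, name_idx[p[2]]) for p in parts])
            order = np.argsort(rp)
            self._per_chrom[chrom] = (rp[order], qp[order], qc[order])

    def locate_flanks(self, chrom: str, start: int, end: int, flank: int = 1000):
        """Nearest usable anchors left of ``start`` and right of ``end``.

        Both anchors must lie within ``flank`` bp of the locus and map to
        the same chromosome of the other genome in consistent order.
        Returns ``(rl, ql, rr, qr)`` or None when the homologous region
        cannot be co-located.
        """
        entry = self._per_chrom.get(chrom)
        if entry is None:
            return None
        rp, qp, qc = entry
        k = self.k
        i = int(np.searchsorted(rp, start - k, side="right")) - 1
        j = int(np.searchsorted(rp, end, side="left"))
        if i < 0 or j >= rp.size:
            return None
        rl, ql = int(rp[i]), int(qp[i])
        rr, qr = int(rp[j]), int(qp[j])
        if rl + k > start or rl < start - flank:
            return None
        if rr < end or rr + k > end + flank:
            return None
        if qc[i] != qc[j] or qr <= ql:
            return None
        return rl, ql, rr, qr, self._other_names[int(qc[i])]

    def span_delta(self, chrom: str, start: int, end: int, flank: int = 1000,
                   junction_pad: int = 50):
        """Span difference and flank identity at one locus.

        delta = (other-genome inter-anchor span) - (reference inter-anchor
        span).  Identity is the ungapped base identity of the flanking
        sequence, anchored on the located anchors; each exact anchor match
        contributes its k bases, and ``junction_pad`` bases adjacent to the
        locus are excluded because reported breakpoints can sit anywhere
        within junction micro-homology and would otherwise be compared
        across the junction.  Returns ``(delta, identity)`` or None when the
        homologous region cannot be co-located.
        """
        loc = self.locate_flanks(chrom, start, end, flank)
        if loc is None:
            return None
        rl, ql, rr, qr, qchrom = loc
        delta = (qr - ql) - (rr - rl)
        rseq = self.ref[chrom]
        qseq = self.other[qchrom]
        k = self.k
        matches = 2 * k          # the located anchors are exact k-mer matches
        total = 2 * k
        # left flank: from the left anchor's end up to junction_pad before the locus
        stop = max(rl + k, start - junction_pad)
        a = rseq[rl + k : stop]
        b = qseq[ql + k : ql + k + len(a)]
        n = min(len(a), len(b))
        if n:
            x = np.frombuffer(a[:n].encode(), np.uint8)
            y = np.frombuffer(b[:n].encode(), np.uint8)
            matches += int((x == y).sum())
            total += n
        # right flank: from junction_pad past the locus up to the right anchor
        begin = min(rr, end + junction_pad)
        a = rseq[begin:rr]
        b = qseq[qr - (rr - begin) : qr]
        n = min(len(a), len(b))
        if n:
            x = np.frombuffer(a[:n].encode(), np.uint8)
            y = np.frombuffer(b[:n].encode(), np.uint8)
            matches += int((x == y).sum())
            total += n
        identity = matches / total if total else 0.0
        return delta, identity


def _classify_span(svtype: str, length: int, delta: float,
                   span_tol: float) -> tuple[str, str]:
    """Map a span delta to (reference-allele match, derived-allele match)."""
    tol = max(span_tol * length, 10)
    ref_like = abs(delta) <= tol                       # other genome matches macaque allele
    ape_delta = -length if svtype == "DEL" else length  # other genome matches ape allele
    ape_like = abs(delta - ape_delta) <= tol
    return ref_like, ape_like


def outgroup_classify(call: LineageCall, macaque: GenomeSequence | None = None,
                      outgroup: GenomeSequence | None = None,
                      homology: HomologyMap | None = None,
                      flank: int = 1000, min_identity: float = 0.85,
                      span_tol: float = 0.1, k: int = 31) -> LineageCall:
    """Polarize a candidate against the outgroup (marmoset role).

    The outgroup region homologous to SV +/- ``flank`` is located through the
    shared anchor map; loci whose flanks cannot be co-located or whose flank
    identity falls below ``min_identity`` are *uncertain*.  Otherwise the
    inter-flank span is compared against the macaque and ape alleles:
    macaque-like (within +/-``span_tol`` of the SV length) means the variant
    is ape-derived (*high_confident*); ape-like means the variant arose on
    the macaque lineage (*false*); anything intermediate is *uncertain*.
    """
    if homology is None:
        if macaque is None or outgroup is None:
            raise ValueError("provide either a HomologyMap or both genomes")
        homology = HomologyMap(macaque, outgroup, k=k)
    sv = call.sv
    if sv.type == "DEL":
        s, e = sv.interval.start, sv.interval.end
    else:  # INS: physical locus is the insertion point
        s = e = sv.anchor_pos
    res = homology.span_delta(sv.interval.chrom, s, e, flank=flank)
    if res is None:
        call.outgroup_class = "uncertain"
        call.identity_prefilter = None
        return call
    delta, identity = res
    call.identity_prefilter = identity
    if identity < min_identity:
        call.outgroup_class = "uncertain"
        return call
    ref_like, ape_like = _classify_span(sv.type, sv.length, delta, span_tol)
    if ref_like and not ape_like:
        call.outgroup_class = "high_confident"
    elif ape_like and not ref_like:
        call.outgroup_class = "false"
    else:
        call.outgroup_class = "uncertain"
    return call


def classify_great_ape(call: LineageCall, gibbon: GenomeSequence | None = None,
                       homology: HomologyMap | None = None,
                       flank: int = 1000, min_identity: float = 0.85,
                       span_tol: float = 0.1, k: int = 31,
                       macaque: GenomeSequence | None = None) -> str:
    """Distinguish ape-wide from great-ape-specific variants using the gibbon.

    A high-confident ape-derived SV whose locus in the gibbon matches the
    ape allele is an ASSV (shared by lesser apes); a gibbon carrying the
    macaque-like allele makes it a GASSV; an unresolvable locus (or a
    missing gibbon genome) is uncertain.
    """
    if call.outgroup_class != "high_confident":
        raise ValueError("great-ape classification requires a high_confident call")
    if homology is None:
        if gibbon is None:
            call.great_ape_class = "uncertain"
            return "uncertain"
        if macaque is None:
            raise ValueError("provide the macaque genome to build the gibbon homology map")
        homology = HomologyMap(macaque, gibbon, k=k)
    sv = call.sv
    if sv.type == "DEL":
        s, e = sv.interval.start, sv.interval.end
    else:
        s = e = sv.anchor_pos
    res = homology.span_delta(sv.interval.chrom, s, e, flank=flank)
    if res is None:
        call.great_ape_class = "uncertain"
        return "uncertain"
    delta, identity = res
    if identity < min_identity:
        call.great_ape_class = "uncertain"
        return "uncertain"
    ref_like, ape_like = _classify_span(sv.type, sv.length, delta, span_tol)
    if ape_like and not ref_like:
        call.great_ape_class = "ASSV"
    elif ref_like and not ape_like:
        call.great_ape_class = "GASSV"
    else:
        call.great_ape_class = "uncertain"
    return call.great_ape_class
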