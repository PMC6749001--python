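"""SV record model and set-level analyses.

Covers reciprocal-overlap matching between callsets, novelty estimation,
per-type summaries, window densities, subtelomeric enrichment with a
permutation null, and genotype-table summaries.

Insertions are anchored at a single reference position but their interval is
widened to ``[pos, pos + length)`` so that the length-reciprocal overlap rule
applies uniformly to all SV types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GenomicInterval

__all__ = [
    "SVRecord",
    "SVCallset",
    "reciprocal_overlap",
    "match_callsets",
    "MatchResult",
    "sv_summary",
    "window_density",
    "subtelomeric_enrichment",
    "SubtelomereResult",
    "genotype_summary",
    "GenotypeSummary",
]

SV_TYPES = ("DEL", "INS", "DUP", "INV")
MIN_SV_LEN = 50


@dataclass
class SVRecord:
    """A structural variant >= 50 bp anchored on a reference frame.

    ``inserted_sequence`` holds the variant (extra-allele) sequence where it
    is known: the deleted bases for a DEL, the inserted bases for an INS.
    ``mate`` optionally records the homologous locus ``(chrom, start, end)``
    in the partner genome of a pairwise comparison; it may be zero-width
    (e.g. the insertion point of a deletion's missing sequence).
    """

    interval: GenomicInterval
    type: str
    length: int
    id: str
    inserted_sequence: str | None = None
    source: str = ""
    mate: tuple[str, int, int] | None = None

    def __post_init__(self) -> None:
        if self.type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.type!r}")
        if self.length < MIN_SV_LEN:
            raise ValueError(f"SV length {self.length} below the {MIN_SV_LEN} bp floor")
        if len(self.interval) != self.length:
            raise ValueError(
                f"{self.type} record {self.id}: interval length {len(self.interval)} "
                f"!= SV length {self.length}"
            )

    @classmethod
    def insertion(cls, chrom: str, pos: int, inserted_sequence: str, id: str,
                  source: str = "", mate: tuple | None = None) -> "SVRecord":
        """Build an INS anchored at ``pos`` with the widened overlap interval."""
        length = len(inserted_sequence)
        return cls(
            interval=GenomicInterval(chrom, pos, pos + length),
            type="INS",
            length=length,
            id=id,
            inserted_sequence=inserted_sequence,
            source=source,
            mate=mate,
        )

    @property
    def anchor_pos(self) -> int:
        """The physical reference position of the event (INS: insertion point)."""
        return self.interval.start


class SVCallset:
    """An ordered collection of :class:`SVRecord` with a provenance tag."""

    def __init__(self, records: Iterable[SVRecord] = (), source: str = "") -> None:
        self.records: list[SVRecord] = list(records)
        self.source = source

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SVRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def by_id(self) -> dict[str, SVRecord]:
        return {r.id: r for r in self.records}

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "chrom": r.interval.chrom,
                    "start": r.interval.start,
                    "end": r.interval.end,
                    "id": r.id,
                    "type": r.type,
                    "length": r.length,
                    "source": r.source,
                }
            )
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "id", "type", "length", "source"]
        )

    def to_tsv(self, path):
        self.to_dataframe().to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_tsv(cls, path, source: str = "") -> "SVCallset":
        df = pd.read_csv(path, sep="\t")
        records = []
        for row in df.itertuples(index=False):
            records.append(
                SVRecord(
                    interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                    type=row.type,
                    length=int(row.length),
                    id=str(row.id),
                    source=getattr(row, "source", source) or source,
                )
            )
        return cls(records, source=source)


# ---------------------------------------------------------------------------
# reciprocal overlap and callset matching
# ---------------------------------------------------------------------------

def reciprocal_overlap(a: SVRecord, b: SVRecord, threshold: float = 0.5,
                       type_aware: bool = True) -> bool:
    """True iff the two records overlap by strictly more than ``threshold``
    of *each* record's length (and share type, unless ``type_aware=False``)."""
    if type_aware and a.type != b.type:
        return False
    ov = a.interval.overlap_len(b.interval)
    return ov > threshold * a.length and ov > threshold * b.length


def _build_trees(callset: SVCallset, type_aware: bool) -> dict:
    trees: dict = {}
    for idx, rec in enumerate(callset):
        key = (rec.interval.chrom, rec.type if type_aware else None)
        trees.setdefault(key, IntervalTree()).addi(rec.interval.start, rec.interval.end, idx)
    return trees


@dataclass
class MatchResult:
    pairs: list[tuple[str, str]]          # (query id, reference id)
    novelty_fraction: float
    novelty_percent: int                  # nearest integer, as papers print it
    n_query: int
    n_matched: int


def match_callsets(query: SVCallset, reference_set: SVCallset,
                   threshold: float = 0.5, type_aware: bool = True) -> MatchResult:
    """Greedy one-to-one matching by decreasing reciprocal-overlap fraction.

    The pair fraction is ``min(ov/len_q, ov/len_r)``; ties are broken by
    smaller start then smaller id, making the matching deterministic.
    """
    trees = _build_trees(reference_set, type_aware)
    candidates = []
    for qi, q in enumerate(query):
        key = (q.interval.chrom, q.type if type_aware else None)
        tree = trees.get(key)
        if tree is None:
            continue
        for hit in tree.overlap(q.interval.start, q.interval.end):
            r = reference_set[hit.data]
            ov = q.interval.overlap_len(r.interval)
            if ov > threshold * q.length and ov > threshold * r.length:
                frac = min(ov / q.length, ov / r.length)
                candidates.append((-frac, q.interval.start, q.id, r.id, qi, hit.data))
    candidates.sort()
    used_q: set[int] = set()
    used_r: set[int] = set()
    pairs = []
    for _negfrac, _start, qid, rid, qi, ri in candidates:
        if qi in used_q or ri in used_r:
            continue
        used_q.add(qi)
        used_r.add(ri)
        pairs.append((qid, rid))
    n_query = len(query)
    n_matched = len(pairs)
    novelty = (n_query - n_matched) / n_query if n_query else 1.0
    return MatchResult(
        pairs=pairs,
        novelty_fraction=novelty,
        novelty_percent=int(round(100 * novelty)),
        n_query=n_query,
        n_matched=n_matched,
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _union_bp(intervals: list[tuple[str, int, int]]) -> int:
    total = 0
    intervals.sort()
    cur_chrom, cur_s, cur_e = None, 0, 0
    for chrom, s, e in intervals:
        if chrom != cur_chrom or s > cur_e:
            total += cur_e - cur_s
            cur_chrom, cur_s, cur_e = chrom, s, e
        else:
            cur_e = max(cur_e, e)
    total += cur_e - cur_s
    return total


def sv_summary(callset: SVCallset, genome_size: int) -> dict:
    """Counts, percentages and median lengths by type plus affected bp.

    Affected bp is the union of DEL/DUP/INV reference footprints plus the
    summed lengths of insertions (which occupy no reference span).
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    counts = {t: 0 for t in SV_TYPES}
    lengths: dict[str, list[int]] = {t: [] for t in SV_TYPES}
    footprints = []
    ins_bp = 0
    for r in callset:
        counts[r.type] += 1
        lengths[r.type].append(r.length)
        if r.type == "INS":
            ins_bp += r.length
        else:
            footprints.append((r.interval.chrom, r.interval.start, r.interval.end))
    total = len(callset)
    affected = _union_bp(footprints) + ins_bp
    return {
        "total": total,
        "counts": counts,
        "percent_by_type": {
            t: (round(100 * c / total, 2) if total else 0.0) for t, c in counts.items()
        },
        "median_length": {
            t: (float(np.median(v)) if v else None) for t, v in lengths.items()
        },
        "affected_bp": affected,
        "genome_fraction_percent": round(100 * affected / genome_size, 2),
    }


def window_density(callset: SVCallset, chrom_lengths: Mapping[str, int],
                   window: int = 500_000) -> pd.DataFrame:
    """Per-window SV counts over non-overlapping tiling windows.

    An SV is counted in the window containing its start (half-open
    convention); the last partial window is kept.
    """
    rows = []
    starts_by_chrom: dict[str, list[tuple[int, str]]] = {c: [] for c in chrom_lengths}
    for r in callset:
        c = r.interval.chrom
        if c not in chrom_lengths:
            raise ValueError(f"SV {r.id} on unknown chromosome {c!r}")
        if r.interval.start >= chrom_lengths[c]:
            raise ValueError(f"SV {r.id} start beyond chromosome {c!r} length")
        starts_by_chrom[c].append((r.interval.start, r.type))
    for chrom, length in chrom_lengths.items():
        n_win = -(-length // window)
        counts = {t: np.zeros(n_win, dtype=int) for t in SV_TYPES}
        for start, svtype in starts_by_chrom[chrom]:
            counts[svtype][start // window] += 1
        for w in range(n_win):
            row = {
                "chrom": chrom,
                "start": w * window,
                "end": min((w + 1) * window, length),
            }
            row.update({t: int(counts[t][w]) for t in SV_TYPES})
            row["total"] = int(sum(counts[t][w] for t in SV_TYPES))
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SubtelomereResult:
    margin: int
    n_svs: int
    n_subtelomeric: int
    fold: float
    p_value: float
    n_perm: int
    flagged_chroms: list[str] = field(default_factory=list)


def subtelomeric_enrichment(callset: SVCallset, chrom_lengths: Mapping[str, int],
                            margin: int = 5_000_000, n_perm: int = 1000,
                            seed: int = 0) -> SubtelomereResult:
    """SV density fold-change in the terminal ``margin`` bp of each
    chromosome versus the rest, with a permutation p-value.

    The null redraws each SV's start uniformly on its own chromosome
    (lengths kept); the add-one estimator ``p = (1 + #{fold* >= fold}) /
    (1 + n_perm)`` keeps p strictly positive.  Chromosomes shorter than
    ``2 * margin`` are entirely subtelomeric and are flagged.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    chroms = list(chrom_lengths)
    clen = np.array([chrom_lengths[c] for c in chroms], dtype=np.int64)
    flagged = [c for c in chroms if chrom_lengths[c] < 2 * margin]
    chrom_idx = {c: i for i, c in enumerate(chroms)}
    sv_chrom = np.array([chrom_idx[r.interval.chrom] for r in callset], dtype=np.int64)
    sv_start = np.array([r.interval.start for r in callset], dtype=np.int64)
    n_sv = len(callset)
    if n_sv == 0:
        raise ValueError("empty callset")

    sub_bp = int(np.minimum(clen, 2 * margin).sum())
    rest_bp = int(clen.sum()) - sub_bp

    def fold_of(starts: np.ndarray) -> np.ndarray:
        lens = clen[sv_chrom]
        in_sub = (starts < margin) | (starts >= lens - margin)
        n_sub = in_sub.sum(axis=-1)
        n_rest = n_sv - n_sub
        sub_density = n_sub / sub_bp
        rest_density = np.where(rest_bp > 0, n_rest / max(rest_bp, 1), np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(rest_density > 0, sub_density / rest_density, np.inf)

    observed_fold = float(np.atleast_1d(fold_of(sv_start))[0])
    n_sub_obs = int(((sv_start < margin) | (sv_start >= clen[sv_chrom] - margin)).sum())

    rng = np.random.default_rng(seed)
    # permute in blocks to bound memory at ~8 MB
    block = max(1, int(1_000_000 // max(n_sv, 1)))
    exceed = 0
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        starts = rng.integers(0, clen[sv_chrom], size=(b, n_sv))
        folds = fold_of(starts)
        exceed += int(np.sum(folds >= observed_fold))
        done += b
    p = (1 + exceed) / (1 + n_perm)
    return SubtelomereResult(
        margin=margin,
        n_svs=n_sv,
        n_subtelomeric=n_sub_obs,
        fold=observed_fold,
        p_value=p,
        n_perm=n_perm,
        flagged_chroms=flagged,
    )


# ---------------------------------------------------------------------------
# genotype summaries
# ---------------------------------------------------------------------------

@dataclass
class GenotypeSummary:
    n_total: int
    n_invalidated: int
    n_present: int
    n_absent: int
    n_fixed: int
    n_polymorphic: int
    present_percent: float       # of all SVs
    invalidated_percent: float   # of all SVs
    fixed_percent: float         # of present SVs
    polymorphic_percent: float   # of present SVs


def genotype_summary(callset: SVCallset, genotypes: pd.DataFrame,
                     fixed_rule: str = "hom_alt_all") -> GenotypeSummary:
    """Summarise present / fixed / polymorphic / invalidated SV fractions.

    * invalidated: no valid genotype in any individual;
    * present: at least one individual carries at least one alt allele;
    * fixed (default rule): every individual is 1/1 -- the alternative
      ``fixed_rule="carrier_all"`` counts an SV fixed when every individual
      carries >= 1 alt allele;
    * polymorphic: present and not fixed.

    Percentages of present/invalidated are over all SVs; fixed/polymorphic
    over present SVs, each rounded to 2 decimals.
    """
    if fixed_rule not in ("hom_alt_all", "carrier_all"):
        raise ValueError(f"unknown fixed_rule {fixed_rule!r}")
    ids = [r.id for r in callset]
    missing = set(ids) - set(genotypes.index)
    if missing:
        raise ValueError(f"genotype table missing {len(missing)} SV ids (e.g. {sorted(missing)[0]!r})")
    sub = genotypes.loc[ids]
    arr = sub.to_numpy(dtype=object)
    invalid = (arr == "invalidated").all(axis=1)
    carries = np.isin(arr, ("0/1", "1/1"))
    hom = arr == "1/1"
    valid_any = (arr != "invalidated").any(axis=1)
    present = valid_any & carries.any(axis=1)
    if fixed_rule == "hom_alt_all":
        fixed = present & hom.all(axis=1)
    else:
        fixed = present & carries.all(axis=1)
    n_total = len(ids)
    n_inval = int(invalid.sum())
    n_present = int(present.sum())
    n_fixed = int(fixed.sum())
    n_poly = n_present - n_fixed
    n_absent = n_total - n_inval - n_present
    pct = lambda a, b: round(100 * a / b, 2) if b else 0.0
    return GenotypeSummary(
        n_total=n_total,
        n_invalidated=n_inval,
        n_present=n_present,
        n_absent=n_absent,
        n_fixed=n_fixed,
        n_polymorphic=n_poly,
        present_percent=pct(n_present, n_total),
        invalidated_percent=pct(n_inval, n_total),
        fixed_percent=pct(n_fixed, n_present),
        polymorphic_percent=pct(n_poly, n_present),
    )
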