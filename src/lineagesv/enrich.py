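"""Trait-gene-set enrichment of lineage-specific SVs.

The primary procedure is a random-draw permutation null: draw |ASSV|-sized
subsets from the full SV universe and recompute the number of distinct
trait genes they intersect (gene interval +/- a 5 kb window).  The add-one
empirical p-value is never zero.  A two-sided Fisher's exact test on the
2x2 table {in subset} x {hits a trait gene} is provided as the analytic
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GeneSet", "EnrichmentResult", "permutation_enrichment", "fisher_enrichment"]

KNOWN_TRAITS = ("tail_development", "brain_size", "adducted_thumbs", "body_size")


@dataclass
class GeneSet:
    """A trait label plus gene intervals (columns gene_id/chrom/start/end)."""

    trait: str
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "start", "end"}
        missing = required - set(self.genes.columns)
        if missing:
            raise ValueError(f"gene table missing columns {sorted(missing)}")
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("gene ids must be unique within a set")


@dataclass
class EnrichmentResult:
    trait: str
    observed: int            # distinct trait genes hit by the SV subset
    n_subset: int
    n_universe: int
    n_iter: int
    empirical_p: float
    fisher_p: float | None = None
    odds_ratio: float | None = None


def _incidence_matrix(sv_loci: Sequence[tuple[str, int, int]], genes: pd.DataFrame,
                      window: int) -> np.ndarray:
    """Boolean (n_sv x n_gene) matrix: SV overlaps gene interval +/- window."""
    n_sv = len(sv_loci)
    n_gene = len(genes)
    inc = np.zeros((n_sv, n_gene), dtype=bool)
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for gi, row in enumerate(genes.itertuples(index=False)):
        by_chrom.setdefault(row.chrom, []).append(
            (max(0, row.start - window), row.end + window, gi)
        )
    for si, (chrom, s, e) in enumerate(sv_loci):
        if e <= s:
            e = s + 1
        for gs, ge, gi in by_chrom.get(chrom, ()):
            if s < ge and gs < e:
                inc[si, gi] = True
    return inc


def _subset_indices(all_ids: list[str], assv_ids) -> np.ndarray:
    pos = {sid: i for i, sid in enumerate(all_ids)}
    missing = [a for a in assv_ids if a not in pos]
    if missing:
        raise ValueError(f"{len(missing)} subset ids not in the SV universe (e.g. {missing[0]!r})")
    return np.array(sorted(pos[a] for a in assv_ids), dtype=np.int64)


def _loci(all_svs, frame: str) -> tuple[list[str], list[tuple[str, int, int]]]:
    ids, loci = [], []
    for rec in all_svs:
        ids.append(rec.id)
        if frame == "mate":
            if rec.mate is None:
                raise ValueError(f"SV {rec.id} has no partner-frame coordinates")
            loci.append(rec.mate)
        else:
            loci.append((rec.interval.chrom, rec.interval.start, rec.interval.end))
    return ids, loci


def permutation_enrichment(all_svs, assv_ids, genes: GeneSet | pd.DataFrame,
                           gene_window: int = 5000, n_iter: int = 10_000,
                           seed: int = 0, frame: str = "ref",
                           statistic: str = "distinct_genes") -> EnrichmentResult:
    """Empirical enrichment p for the ASSV subset against the trait gene set.

    The observed statistic is the number of distinct trait genes intersected
    (gene +/- ``gene_window``) by the subset; each iteration draws an
    equal-sized subset uniformly without replacement from ``all_svs`` and
    recomputes it.  ``frame="mate"`` uses each SV's partner-genome (human)
    coordinates.  ``statistic="sv_gene_pairs"`` counts SV-gene pairs instead.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    gene_set = genes if isinstance(genes, GeneSet) else GeneSet("custom", genes)
    ids, loci = _loci(all_svs, frame)
    subset = _subset_indices(ids, assv_ids)
    if subset.size > len(ids):
        raise ValueError("subset larger than universe")
    inc = _incidence_matrix(loci, gene_set.genes, gene_window)

    def stat(rows: np.ndarray) -> int:
        sub = inc[rows]
        if statistic == "sv_gene_pairs":
            return int(sub.sum())
        return int(sub.any(axis=0).sum())

    observed = stat(subset)
    rng = np.random.default_rng(seed)
    m = subset.size
    exceed = 0
    for _ in range(n_iter):
        draw = rng.choice(len(ids), size=m, replace=False)
        if stat(draw) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_iter)
    return EnrichmentResult(
        trait=gene_set.trait,
        observed=observed,
        n_subset=m,
        n_universe=len(ids),
        n_iter=n_iter,
        empirical_p=p,
    )


def fisher_enrichment(all_svs, assv_ids, genes: GeneSet | pd.DataFrame,
                      gene_window: int = 5000, frame: str = "ref"
                      ) -> tuple[float, float]:
    """Two-sided Fisher's exact test on {in ASSV subset} x {hits trait gene}.

    Returns (p, sample odds ratio); empty table margins give p = 1.
    """
    gene_set = genes if isinstance(genes, GeneSet) else GeneSet("custom", genes)
    ids, loci = _loci(all_svs, frame)
    subset = set(_subset_indices(ids, assv_ids).tolist())
    inc = _incidence_matrix(loci, gene_set.genes, gene_window)
    hits = inc.any(axis=1)
    in_sub = np.zeros(len(ids), dtype=bool)
    in_sub[list(subset)] = True
    a = int((in_sub & hits).sum())
    b = int((in_sub & ~hits).sum())
    c = int((~in_sub & hits).sum())
    d = int((~in_sub & ~hits).sum())
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return 1.0, float("nan")
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p), float(odds)
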