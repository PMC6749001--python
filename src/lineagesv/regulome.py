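"""Ape-monkey differential enhancer (ADE) calling and related expression tests.

An enhancer is an ADE when its H3K27Ac signal differs between macaque and
human AND between macaque and chimpanzee in the same direction (both two-
tailed p < 0.05) while human and chimpanzee do not differ (p > 0.05).  The
compound criterion makes the null call rate far smaller than the nominal
0.05 of a single test.

Counts are tested on the log2(count + 1) scale; the pooled-variance Student
t is the default because the chimpanzee group has only two replicates,
where Welch degrees of freedom are unstable (Welch is available via
``equal_var=False``).  Fold changes are quantified on raw means with a +1
pseudocount, reported as log2((mean_human + mean_chimp)/2 / mean_macaque).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomicInterval, species_groups

__all__ = [
    "BRAIN_REGIONS",
    "EnhancerMatrix",
    "ADERecord",
    "two_sample_test",
    "call_ades",
    "intersect_assv_ade",
    "annotate_near_genes",
    "layer_expression_test",
]

BRAIN_REGIONS = ("PFC", "PcGm", "OP", "CN", "Put", "CB", "WM", "TN")


@dataclass
class EnhancerMatrix:
    """Per-enhancer, per-sample H3K27Ac counts for one brain region.

    ``counts`` is indexed by enhancer id with ``species_replicate`` columns
    (e.g. ``human_1``); ``intervals`` gives each enhancer's genomic location
    in the frame the matrix was built in.
    """

    counts: pd.DataFrame
    intervals: dict[str, GenomicInterval]
    region: str = "PFC"

    def __post_init__(self) -> None:
        if self.region not in BRAIN_REGIONS:
            raise ValueError(f"unknown brain region {self.region!r}")
        groups = species_groups(self.counts.columns)
        for sp in ("human", "chimp", "macaque"):
            if len(groups.get(sp, ())) < 2:
                raise ValueError(f"need >= 2 {sp} samples for testing")
        if len(self.counts) and (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.groups = groups

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class ADERecord:
    enhancer: str
    region: str
    p_mh: float
    p_mc: float
    p_hc: float
    direction: str          # gain | loss (ape relative to macaque)
    log2fc: float
    is_ade: bool
    interval: GenomicInterval | None = None


def two_sample_test(x: Sequence[float], y: Sequence[float],
                    equal_var: bool = True) -> tuple[float, int]:
    """Two-tailed two-sample t test; returns (p, direction of mean(x)-mean(y)).

    Degenerate zero-variance groups with identical values give p = 1;
    zero-variance groups with different means give p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 values")
    direction = int(np.sign(np.mean(x) - np.mean(y)))
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return (1.0 if x[0] == y[0] else 0.0), direction
    p = stats.ttest_ind(x, y, equal_var=equal_var).pvalue
    if np.isnan(p):
        p = 1.0
    return float(p), direction


def _vector_ttest(a: np.ndarray, b: np.ndarray, equal_var: bool) -> np.ndarray:
    """Row-wise two-sample t p-values with degenerate rows handled."""
    res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        same = np.abs(a.mean(axis=1) - b.mean(axis=1)) < 1e-12
        p[degenerate & same] = 1.0
        p[degenerate & ~same] = 0.0
    return p


def call_ades(matrix: EnhancerMatrix, alpha: float = 0.05,
              equal_var: bool = True, log_transform: bool = True) -> list[ADERecord]:
    """Apply the three-test, same-direction ADE criterion to every enhancer."""
    counts = matrix.counts
    h = counts[matrix.groups["human"]].to_numpy(dtype=float)
    c = counts[matrix.groups["chimp"]].to_numpy(dtype=float)
    m = counts[matrix.groups["macaque"]].to_numpy(dtype=float)
    th, tc, tm = (np.log2(v + 1) if log_transform else v for v in (h, c, m))
    p_mh = _vector_ttest(tm, th, equal_var)
    p_mc = _vector_ttest(tm, tc, equal_var)
    p_hc = _vector_ttest(th, tc, equal_var)
    mh, mc, mm = h.mean(axis=1), c.mean(axis=1), m.mean(axis=1)
    dir_h = np.sign(mh - mm)
    dir_c = np.sign(mc - mm)
    same_direction = (dir_h == dir_c) & (dir_h != 0)
    is_ade = (p_mh < alpha) & (p_mc < alpha) & (p_hc > alpha) & same_direction
    log2fc = np.log2(((mh + mc) / 2 + 1) / (mm + 1))
    records = []
    for i, enh in enumerate(counts.index):
        records.append(
            ADERecord(
                enhancer=str(enh),
                region=matrix.region,
                p_mh=float(p_mh[i]),
                p_mc=float(p_mc[i]),
                p_hc=float(p_hc[i]),
                direction="gain" if dir_h[i] > 0 else "loss",
                log2fc=float(log2fc[i]),
                is_ade=bool(is_ade[i]),
                interval=matrix.intervals.get(str(enh)),
            )
        )
    return records


def _as_interval(value, min_width: int = 1) -> tuple[str, int, int]:
    """Normalise (chrom, start, end) tuples/intervals, widening zero-width loci."""
    if isinstance(value, GenomicInterval):
        return value.chrom, value.start, value.end
    chrom, start, end = value
    if end <= start:
        end = start + min_width
    return chrom, start, end


def intersect_assv_ade(assvs, ades: list[ADERecord]) -> pd.DataFrame:
    """All (ASSV, ADE) pairs with >= 1 bp overlap in the human frame.

    ``assvs`` are :class:`~lineagesv.lineage.LineageCall` objects; calls
    without human-frame coordinates raise, because the enhancer catalogue is
    defined on human coordinates.  Deletion loci that are points in the
    human frame are treated as 1 bp for the overlap test.
    """
    rows = []
    ade_loci = [(a, *_as_interval(a.interval)) for a in ades if a.interval is not None]
    for call in assvs:
        if call.human_interval is None:
            raise ValueError(
                f"ASSV {call.sv.id} lacks human-frame coordinates; run the human overlay first"
            )
        chrom, s, e = _as_interval(call.human_interval)
        for ade, achrom, as_, ae in ade_loci:
            if achrom == chrom and s < ae and as_ < e:
                rows.append(
                    {
                        "assv_id": call.sv.id,
                        "ade": ade.enhancer,
                        "region": ade.region,
                        "direction": ade.direction,
                        "sv_type": call.sv.type,
                        "is_ade": ade.is_ade,
                    }
                )
    return pd.DataFrame(rows, columns=["assv_id", "ade", "region", "direction",
                                       "sv_type", "is_ade"])


def annotate_near_genes(svs, genes: pd.DataFrame, window: int = 5000) -> dict[str, list[str]]:
    """Assign each SV to every gene whose interval +/- ``window`` it overlaps.

    ``svs`` maps SV id -> (chrom, start, end); ``genes`` needs columns
    gene_id/chrom/start/end.  SVs hitting nothing get an empty list
    (intergenic).
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for row in genes.itertuples(index=False):
        by_chrom.setdefault(row.chrom, []).append(
            (max(0, row.start - window), row.end + window, str(row.gene_id))
        )
    out: dict[str, list[str]] = {}
    for sv_id, locus in svs.items():
        chrom, s, e = _as_interval(locus)
        hits = [g for gs, ge, g in by_chrom.get(chrom, ()) if s < ge and gs < e]
        out[sv_id] = sorted(set(hits))
    return out


def layer_expression_test(profile_a: Sequence[float], profile_b: Sequence[float]
                          ) -> tuple[float, int]:
    """Two-tailed paired t test across matched cortical sections.

    Profiles are per-section species means (the study design uses 16
    neocortical layers plus adjacent white matter, 17 sections); the
    pairing is by section.  Returns (p, direction of a - b).
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal section counts")
    diff = a - b
    direction = int(np.sign(diff.mean()))
    if np.ptp(diff) == 0:
        return (1.0 if diff[0] == 0 else 0.0), direction
    p = stats.ttest_rel(a, b).pvalue
    return float(p), direction
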