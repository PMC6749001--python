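"""Readers and writers for the genomic file formats the package touches.

One coordinate convention is enforced at this boundary: every in-memory
coordinate is 0-based half-open (the BED convention).  BED emission is
verbatim; the VCF writer/reader adds and removes the 1-based anchor base.
Soft-masked (lowercase) bases are uppercased on read -- repeat logic in this
package always uses explicit annotation, never case.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "GenomeSequence",
    "read_fasta",
    "write_fasta",
    "write_sv_vcf",
    "read_sv_vcf",
    "read_counts_table",
    "write_counts_table",
    "species_groups",
]

_VALID_SEQ = re.compile(r"[ACGTN]*\Z")
_INVALID_CHARS = re.compile(r"[^ACGTN]")

#: species recognised in count-table column headers, e.g. ``human_1``
SPECIES = ("human", "chimp", "macaque")

_GT_VALUES = frozenset({"0/0", "0/1", "1/1", "invalidated"})


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval (``start`` inclusive, ``end`` exclusive)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class GenomeSequence:
    """Named chromosome sequences over the alphabet {A, C, G, T, N}.

    Parameters
    ----------
    name
        Assembly/genome label (e.g. ``"macaque"``).
    chromosomes
        Ordered mapping of chromosome name to sequence string.  Order is
        preserved; names must be unique and sequences non-empty.
    repeat_annotation
        Optional list of ``(chrom, start, end, repeat_class)`` tuples for
        planted or annotated repeats; intervals must lie within bounds.
    """

    def __init__(
        self,
        name: str,
        chromosomes: Mapping[str, str],
        repeat_annotation: Sequence[tuple] | None = None,
    ) -> None:
        self.name = name
        self.chromosomes: dict[str, str] = {}
        for chrom, seq in chromosomes.items():
            if chrom in self.chromosomes:
                raise ValueError(f"duplicate chromosome name {chrom!r}")
            if not seq:
                raise ValueError(f"empty sequence for chromosome {chrom!r}")
            if not _VALID_SEQ.match(seq):
                bad = _INVALID_CHARS.search(seq).group()
                raise ValueError(f"invalid base {bad!r} in chromosome {chrom!r}")
            self.chromosomes[chrom] = seq
        self.repeat_annotation: list[tuple] = list(repeat_annotation or [])
        for chrom, start, end, _cls in self.repeat_annotation:
            if chrom not in self.chromosomes:
                raise ValueError(f"repeat annotation on unknown chromosome {chrom!r}")
            if not (0 <= start < end <= len(self.chromosomes[chrom])):
                raise ValueError(f"repeat interval out of bounds: {chrom}:{start}-{end}")

    # -- container protocol ------------------------------------------------
    def __getitem__(self, chrom: str) -> str:
        return self.chromosomes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def __iter__(self):
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chromosomes.items()}

    @property
    def total_bases(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.chromosomes[chrom][start:end]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, name: str | None = None, on_invalid: str = "error") -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Bases are uppercased.  Characters outside {A,C,G,T,N} either raise
    (``on_invalid="error"``, default) or are mapped to N
    (``on_invalid="to-n"``).
    """
    path = Path(path)
    if on_invalid not in ("error", "to-n"):
        raise ValueError(f"unknown on_invalid policy {on_invalid!r}")
    if not path.exists():
        raise FileNotFoundError(str(path))
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise ValueError(f"duplicate FASTA record name {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r} in {path}")
        if not _VALID_SEQ.match(seq):
            if on_invalid == "to-n":
                seq = _INVALID_CHARS.sub("N", seq)
            else:
                bad = _INVALID_CHARS.search(seq).group()
                raise ValueError(f"invalid base {bad!r} in record {rec.id!r}")
        chroms[rec.id] = seq
    if not chroms:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeSequence(name or path.stem, chroms)


def write_fasta(genome: GenomeSequence, path, width: int = 60):
    """Write a genome as wrapped FASTA (default 60 columns)."""
    path = Path(path)
    with open(path, "w") as fh:
        for chrom, seq in genome.chromosomes.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# VCF 4.2 for structural variants
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=lineagesv
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant (negative for deletions)">
##INFO=<ID=END,Number=1,Type=Integer,Description="1-based end of the variant on the reference">
"""


def write_sv_vcf(callset, reference: GenomeSequence, path):
    """Write an SV callset as sequence-resolved VCF 4.2.

    Deletions and insertions carry the 1-based anchor base in REF/ALT;
    duplications and inversions are written as symbolic ALTs with END and
    SVLEN INFO keys.  Internal 0-based starts map to POS = start (the anchor
    base is the reference base immediately before the event).
    """
    path = Path(path)
    lines = [_VCF_HEADER]
    for chrom, length in reference.chrom_lengths.items():
        lines.append(f"##contig=<ID={chrom},length={length}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for rec in callset:
        chrom = rec.interval.chrom
        if chrom not in reference:
            raise ValueError(f"record {rec.id}: chromosome {chrom!r} not in reference")
        ref_seq = reference[chrom]
        start = rec.interval.start
        if start < 1:
            raise ValueError(f"record {rec.id}: start {start} leaves no room for a VCF anchor base")
        anchor = ref_seq[start - 1]
        if rec.type == "DEL":
            end = start + rec.length
            if end > len(ref_seq):
                raise ValueError(f"record {rec.id}: deletion exceeds {chrom} length")
            ref_allele = ref_seq[start - 1 : end]
            alt_allele = anchor
            info = f"SVTYPE=DEL;SVLEN={-rec.length};END={end}"
        elif rec.type == "INS":
            if not rec.inserted_sequence:
                raise ValueError(f"record {rec.id}: insertion lacks inserted sequence")
            ref_allele = anchor
            alt_allele = anchor + rec.inserted_sequence
            info = f"SVTYPE=INS;SVLEN={rec.length};END={start}"
        elif rec.type in ("DUP", "INV"):
            end = rec.interval.end
            if end > len(ref_seq):
                raise ValueError(f"record {rec.id}: {rec.type} exceeds {chrom} length")
            ref_allele = anchor
            alt_allele = f"<{rec.type}>"
            info = f"SVTYPE={rec.type};SVLEN={rec.length};END={end}"
        else:  # pragma: no cover - guarded by SVRecord validation
            raise ValueError(f"unknown SV type {rec.type!r}")
        lines.append(
            f"{chrom}\t{start}\t{rec.id}\t{ref_allele}\t{alt_allele}\t.\tPASS\t{info}\n"
        )
    with open(path, "w") as fh:
        fh.writelines(lines)
    return path


def read_sv_vcf(path, source: str = "vcf"):
    """Read a VCF written by :func:`write_sv_vcf` back into an ``SVCallset``."""
    import pysam

    from .svcore import SVCallset, SVRecord

    records = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            svtype = rec.info["SVTYPE"]
            svlen = abs(int(rec.info["SVLEN"]))
            start = rec.start + 1  # back to the 0-based event start
            if svtype == "DEL":
                sv = SVRecord(
                    interval=GenomicInterval(rec.chrom, start, start + svlen),
                    type="DEL",
                    length=svlen,
                    id=rec.id,
                    inserted_sequence=rec.ref[1:],
                    source=source,
                )
            elif svtype == "INS":
                inserted = rec.alts[0][1:]
                sv = SVRecord.insertion(rec.chrom, start, inserted, id=rec.id, source=source)
            else:
                end = int(rec.stop)   # pysam exposes the END INFO key as .stop
                sv = SVRecord(
                    interval=GenomicInterval(rec.chrom, start, end),
                    type=svtype,
                    length=end - start,
                    id=rec.id,
                    source=source,
                )
            records.append(sv)
    return SVCallset(records, source=source)


# ---------------------------------------------------------------------------
# TSV count / genotype / expression tables
# ---------------------------------------------------------------------------

def species_groups(columns: Iterable[str]) -> dict[str, list[str]]:
    """Group ``species_replicate`` sample columns by species."""
    groups: dict[str, list[str]] = {}
    for col in columns:
        m = re.match(r"(?P<sp>[A-Za-z]+)_(?P<rep>\d+)\Z", col)
        if m and m.group("sp") in SPECIES:
            groups.setdefault(m.group("sp"), []).append(col)
    return groups


def read_counts_table(path, schema: str) -> pd.DataFrame:
    """Read a TSV table of one of the three supported schemas.

    ``enhancer``
        first column ``enhancer`` (interval id, e.g. ``chr1:100-600``),
        remaining columns ``species_replicate`` numeric counts >= 0.
    ``expression``
        first column ``section``, remaining columns numeric values.
    ``genotype``
        first column ``sv_id``, remaining columns individuals with cells in
        {0/0, 0/1, 1/1, invalidated}.
    """
    if schema not in ("enhancer", "expression", "genotype"):
        raise ValueError(f"unknown schema {schema!r}")
    key = {"enhancer": "enhancer", "expression": "section", "genotype": "sv_id"}[schema]
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != key:
        raise ValueError(f"{schema} table must start with a {key!r} column, got {df.columns[0]!r}")
    df = df.set_index(key)
    if schema == "genotype":
        for col in df.columns:
            bad = df.index[~df[col].isin(_GT_VALUES)]
            if len(bad):
                raise ValueError(f"invalid genotype at row {bad[0]!r}, column {col!r}")
        return df
    # numeric schemas
    out = {}
    for col in df.columns:
        values = pd.to_numeric(df[col], errors="coerce")
        if values.isna().any():
            row = df.index[values.isna()][0]
            raise ValueError(f"non-numeric cell at row {row!r}, column {col!r}")
        out[col] = values
    num = pd.DataFrame(out, index=df.index)
    if schema == "enhancer" and len(num) and (num.to_numpy() < 0).any():
        raise ValueError("negative counts in enhancer table")
    return num


def write_counts_table(df: pd.DataFrame, path, schema: str):
    key = {"enhancer": "enhancer", "expression": "section", "genotype": "sv_id"}[schema]
    df = df.copy()
    df.index.name = key
    df.to_csv(path, sep="\t")
    return Path(path)
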