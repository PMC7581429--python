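"""Readers and writers for the standard formats the pipeline touches.

Everything downstream works on the plain domain types defined here:
:class:`GenotypedVariant` (one biallelic VCF site with per-sample calls),
:class:`Pedigree` (family structure), and :class:`DETRecord` (one row of a
differential-expression table).  Multi-allelic VCF records are split into
per-alternate-allele records on read, because every downstream threshold
(population frequency, CADD, genotype class) is defined per alternate allele.

Coordinates are 1-based, fully closed (VCF convention); FASTA access converts
internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
import pysam
from pyfaidx import Fasta

from chdprio.errors import DataError

log = logging.getLogger(__name__)

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"
AFFECTED = "affected"
UNAFFECTED = "unaffected"

#: DET comparison labels
PROBAND_VS_MOTHER = "proband_vs_mother"
PROBAND_VS_FATHER = "proband_vs_father"

X_CHROM_NAMES = {"X", "chrX"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at one (split, biallelic) site.

    ``alleles`` holds 0 (reference), 1 (the analyzed alternate) or ``None``
    (missing); length 1 encodes a hemizygous call (male X).  A genotype that
    carried a *different* alternate allele of the original multi-allelic
    record is recoded 0 for this split record and flagged ``has_other_alt``:
    the sample is a carrier of "other", a non-carrier of this allele.
    """

    alleles: tuple
    depth: int = 0
    depth_available: bool = True
    quality: float = 0.0
    quality_available: bool = True
    phased: bool = False
    has_other_alt: bool = False

    @property
    def is_missing(self) -> bool:
        return all(a is None for a in self.alleles)

    @property
    def ploidy(self) -> int:
        return len(self.alleles)

    @property
    def dosage(self) -> Optional[int]:
        """Count of the analyzed alternate allele; None when missing."""
        if self.is_missing:
            return None
        return sum(1 for a in self.alleles if a == 1)

    @property
    def is_hom_ref(self) -> bool:
        return not self.is_missing and all(a == 0 for a in self.alleles)

    @property
    def is_het(self) -> bool:
        return self.ploidy == 2 and self.dosage == 1

    @property
    def is_hom_alt(self) -> bool:
        return self.ploidy == 2 and self.dosage == 2

    @property
    def is_hemi_alt(self) -> bool:
        return self.ploidy == 1 and self.dosage == 1

    @property
    def is_carrier(self) -> bool:
        return (self.dosage or 0) >= 1


MISSING_DIPLOID = GenotypeCall(alleles=(None, None), depth=0, depth_available=False,
                               quality=0.0, quality_available=False)


@dataclass(frozen=True)
class GenotypedVariant:
    """One biallelic site with per-sample calls and the site FILTER label."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    filter_status: str = "PASS"
    variant_id: str = "."
    calls: dict = field(default_factory=dict)  # sample_id -> GenotypeCall

    @property
    def variant_key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def key_str(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def on_x(self) -> bool:
        return self.chrom in X_CHROM_NAMES

    def with_calls(self, calls: dict) -> "GenotypedVariant":
        return replace(self, calls=calls)


@dataclass(frozen=True)
class PedigreeMember:
    sample_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str = UNKNOWN
    affected: str = UNKNOWN


@dataclass
class Pedigree:
    """A family with a designated proband.

    The proband must have both parents present; unaffected siblings are the
    members sharing both parents with the proband and marked unaffected.
    """

    members: list
    proband_id: str

    def __post_init__(self):
        ids = {m.sample_id for m in self.members}
        if self.proband_id not in ids:
            raise DataError(f"proband {self.proband_id!r} not in pedigree")
        by_id = {m.sample_id: m for m in self.members}
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in ids:
                    raise DataError(
                        f"member {m.sample_id!r} references absent parent {pid!r}")
            # no member may be its own ancestor
            seen = set()
            stack = [m.father_id, m.mother_id]
            while stack:
                a = stack.pop()
                if a is None or a in seen:
                    continue
                if a == m.sample_id:
                    raise DataError(f"member {m.sample_id!r} is its own ancestor")
                seen.add(a)
                pa = by_id[a]
                stack.extend([pa.father_id, pa.mother_id])
        p = self.proband
        if p.father_id is None or p.mother_id is None:
            raise DataError("proband must have both parents in the pedigree")

    def member(self, sample_id: str) -> PedigreeMember:
        for m in self.members:
            if m.sample_id == sample_id:
                return m
        raise DataError(f"no pedigree member {sample_id!r}")

    @property
    def proband(self) -> PedigreeMember:
        return self.member(self.proband_id)

    @property
    def father_id(self) -> str:
        return self.proband.father_id

    @property
    def mother_id(self) -> str:
        return self.proband.mother_id

    @property
    def unaffected_siblings(self) -> list:
        p = self.proband
        return [
            m for m in self.members
            if m.sample_id != p.sample_id
            and m.father_id == p.father_id
            and m.mother_id == p.mother_id
            and m.affected == UNAFFECTED
        ]

    @property
    def sample_ids(self) -> list:
        return [m.sample_id for m in self.members]


@dataclass(frozen=True)
class DETRecord:
    """One differential-expression result: proband versus one parent."""

    gene: str
    comparison: str  # PROBAND_VS_MOTHER or PROBAND_VS_FATHER
    log2_fold_change: float
    adjusted_p: float
    timepoint: str  # "d0" or "d25"

    def __post_init__(self):
        if not 0.0 <= self.adjusted_p <= 1.0:
            raise DataError(
                f"adjusted_p {self.adjusted_p} outside [0,1] for {self.gene}")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _split_gt_allele(allele: Optional[int], alt_index: int) -> tuple:
    """Remap one original allele index for the split record of ``alt_index``.

    Returns (new_allele, saw_other_alt).
    """
    if allele is None:
        return None, False
    if allele == alt_index:
        return 1, False
    if allele == 0:
        return 0, False
    return 0, True  # a different alt: non-carrier of this allele


def read_vcf(path, samples: Optional[Sequence[str]] = None) -> Iterator[GenotypedVariant]:
    """Stream :class:`GenotypedVariant` records from a VCF (plain or bgzipped).

    Multi-allelic records are split into one record per alternate allele with
    genotype indices remapped; sample order is preserved and the FILTER column
    is retained verbatim.
    """
    path = str(path)
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot parse VCF {path}: {exc}") from exc
    available = list(vcf.header.samples)
    if samples is not None:
        missing = [s for s in samples if s not in available]
        if missing:
            raise DataError(
                f"samples {missing} not in VCF; available: {available}")
        use = list(samples)
    else:
        use = available

    for lineno, rec in enumerate(vcf, start=1):
        try:
            yield from _split_record(rec, use)
        except DataError:
            raise
        except Exception as exc:  # malformed record
            raise DataError(
                f"malformed VCF record #{lineno} in {path}: {exc}") from exc
    vcf.close()


def _split_record(rec, samples) -> Iterator[GenotypedVariant]:
    alts = rec.alts or ()
    filt = ";".join(rec.filter.keys()) if list(rec.filter) else "PASS"
    vid = rec.id or "."
    for k, alt in enumerate(alts, start=1):
        calls = {}
        for s in samples:
            sd = rec.samples[s]
            gt = sd.get("GT", (None,))
            if gt is None:
                gt = (None,)
            new_alleles = []
            other = False
            for a in gt:
                na, saw = _split_gt_allele(a, k)
                other = other or saw
                new_alleles.append(na)
            dp = sd.get("DP")
            gq = sd.get("GQ")
            phased = bool(sd.phased) and len(new_alleles) > 1
            if not phased:
                # unphased allele order carries no information: normalize
                new_alleles.sort(key=lambda a: (a is None, a))
            calls[s] = GenotypeCall(
                alleles=tuple(new_alleles),
                depth=int(dp) if dp is not None else 0,
                depth_available=dp is not None,
                quality=float(gq) if gq is not None else 0.0,
                quality_available=gq is not None,
                phased=phased,
                has_other_alt=other,
            )
        yield GenotypedVariant(
            chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
            filter_status=filt, variant_id=vid, calls=calls,
        )


def write_vcf(path, variants: Iterable[GenotypedVariant],
              sample_ids: Sequence[str]) -> None:
    """Write biallelic records as VCF v4.2 with GT:DP:GQ genotype fields."""
    variants = list(variants)
    contigs = []
    filters = []
    for v in variants:
        if v.chrom not in contigs:
            contigs.append(v.chrom)
        for f in v.filter_status.split(";"):
            if f not in ("PASS", ".") and f not in filters:
                filters.append(f)
    lines = ["##fileformat=VCFv4.2"]
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    for f in filters:
        lines.append(f'##FILTER=<ID={f},Description="{f}">')
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_ids),
    ]
    for v in variants:
        fields = [v.chrom, str(v.pos), v.variant_id, v.ref, v.alt, ".",
                  v.filter_status, ".", "GT:DP:GQ"]
        for s in sample_ids:
            call = v.calls.get(s, MISSING_DIPLOID)
            sep = "|" if call.phased else "/"
            gt = sep.join("." if a is None else str(a) for a in call.alleles)
            dp = str(call.depth) if call.depth_available else "."
            gq = str(int(call.quality)) if call.quality_available else "."
            fields.append(f"{gt}:{dp}:{gq}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

_SEX = {"1": MALE, "2": FEMALE}
_PHENO = {"1": UNAFFECTED, "2": AFFECTED}


def read_pedigree(path, proband_id: Optional[str] = None) -> Pedigree:
    """Read a 6-column PED file.

    The proband is the unique affected offspring (member with both parents in
    the file) unless ``proband_id`` overrides it.
    """
    members = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise DataError(f"PED line {lineno}: expected 6 columns, got {len(parts)}")
        _fam, iid, fid, mid, sex, pheno = parts[:6]
        members.append(PedigreeMember(
            sample_id=iid,
            father_id=None if fid in ("0", ".") else fid,
            mother_id=None if mid in ("0", ".") else mid,
            sex=_SEX.get(sex, UNKNOWN),
            affected=_PHENO.get(pheno, UNKNOWN),
        ))
    if not members:
        raise DataError(f"empty PED file: {path}")
    if proband_id is None:
        affected_offspring = [
            m.sample_id for m in members
            if m.affected == AFFECTED and m.father_id and m.mother_id
        ]
        if len(affected_offspring) != 1:
            raise DataError(
                "expected exactly one affected offspring with both parents; "
                f"found {affected_offspring or 'none'} (pass an explicit proband)")
        proband_id = affected_offspring[0]
    return Pedigree(members=members, proband_id=proband_id)


# ---------------------------------------------------------------------------
# DET tables
# ---------------------------------------------------------------------------

_DET_COLUMNS = ("gene", "comparison", "log2fc", "adj_p")


def read_det_table(path, timepoint: str) -> list:
    """Read a tab-separated differential-expression table.

    Required columns: gene, comparison, log2fc, adj_p.  Duplicate
    (gene, comparison) rows are collapsed keeping the smallest adjusted p
    (this also covers transcript-keyed input mapped to genes upstream).
    """
    if timepoint not in ("d0", "d25"):
        raise DataError(f"unknown timepoint {timepoint!r}")
    df = pd.read_csv(path, sep="\t")
    for col in _DET_COLUMNS:
        if col not in df.columns:
            raise DataError(f"DET table {path} missing required column {col!r}")
    df = df.sort_values("adj_p").drop_duplicates(["gene", "comparison"], keep="first")
    records = []
    for row in df.itertuples(index=False):
        records.append(DETRecord(
            gene=str(row.gene),
            comparison=str(row.comparison),
            log2_fold_change=float(row.log2fc),
            adjusted_p=float(row.adj_p),
            timepoint=timepoint,
        ))
    return records


# ---------------------------------------------------------------------------
# FASTA flanks
# ---------------------------------------------------------------------------


def fetch_flank(reference, chrom: str, pos: int, window: int,
                ref_len: int = 1) -> tuple:
    """Return up to ``window`` uppercase bases on each side of a variant.

    The variant's reference span is [pos, pos + ref_len - 1], 1-based closed.
    """
    fa = Fasta(str(reference))
    if chrom not in fa:
        raise DataError(f"contig {chrom!r} not in FASTA {reference}; "
                        f"available: {list(fa.keys())}")
    contig_len = len(fa[chrom])
    end = pos + ref_len - 1
    if pos < 1 or end > contig_len:
        raise DataError(
            f"{chrom}:{pos} (span {ref_len}) outside contig of length {contig_len}")
    left_start = max(1, pos - window)
    left = str(fa[chrom][left_start - 1:pos - 1]).upper() if pos > 1 else ""
    right = str(fa[chrom][end:min(contig_len, end + window)]).upper()
    return left, right
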