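"""Variant- and gene-level annotations and the rarity/function rules.

The pipeline consumes a pre-computed annotation table (one row per biallelic
variant) rather than calling an annotator.  The table schema is:

    CHROM POS REF ALT GENE TRANSCRIPT CONSEQUENCE MAF_ESP MAF_1KG MAF_GNOMAD
    CADD INTERNAL_COUNT PLI REGULATORY

Frequencies are fractions in [0,1]; an absent frequency means the variant is
novel and is treated as 0.  Each variant carries exactly one primary
consequence class, severity-ranked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from chdprio.errors import ConfigError, DataError

log = logging.getLogger(__name__)

CONSEQUENCES = (
    "frameshift", "stop_gain", "stop_loss", "missense", "synonymous",
    "essential_splice", "splice_region", "intronic", "utr5", "utr3",
    "upstream_1kb", "promoter", "encode_tfbs", "mirna_site", "enhancer",
    "other",
)

#: one-class-per-variant ranking, most severe first
SEVERITY_ORDER = (
    "frameshift", "stop_gain", "stop_loss", "essential_splice", "missense",
    "splice_region", "synonymous", "utr5", "utr3", "promoter", "encode_tfbs",
    "mirna_site", "enhancer", "upstream_1kb", "intronic", "other",
)

#: consequence classes counted as functional in the family cascade
FUNCTIONAL_CLASSES = frozenset({
    "frameshift", "stop_gain", "stop_loss", "missense", "essential_splice",
    "mirna_site", "enhancer", "encode_tfbs", "promoter",
})

LOF_CLASSES = frozenset({"frameshift", "stop_gain", "stop_loss"})

BURDEN_CATEGORIES = (
    "all_gene_body", "missense", "intronic", "splice_region", "synonymous",
    "utr3", "utr5", "upstream_1kb", "regulatory_fetal_heart", "tfbs_clusters",
)


@dataclass(frozen=True)
class VariantAnnotation:
    variant_key: tuple  # (chrom, pos, ref, alt)
    gene: str
    consequence: str
    transcript: Optional[str] = None
    pop_maf: dict = field(default_factory=dict)  # database -> fraction
    cadd_phred: Optional[float] = None
    internal_cohort_count: int = 0
    pli: Optional[float] = None
    regulatory_region: bool = False

    def __post_init__(self):
        if self.consequence not in CONSEQUENCES:
            raise DataError(f"unknown consequence {self.consequence!r}")
        for db, f in self.pop_maf.items():
            if not 0.0 <= f <= 1.0:
                raise DataError(f"MAF {f} for {db} outside [0,1]")
        if self.pli is not None and not 0.0 <= self.pli <= 1.0:
            raise DataError(f"pLI {self.pli} outside [0,1]")

    def max_maf(self, databases: Optional[Sequence[str]] = None) -> float:
        """Maximum frequency over the configured databases; absent -> 0."""
        dbs = databases if databases is not None else list(self.pop_maf)
        vals = [self.pop_maf.get(db, 0.0) for db in dbs]
        return max(vals) if vals else 0.0


@dataclass(frozen=True)
class RarityPolicy:
    maf_threshold_dominant: float = 0.01
    maf_threshold_recessive: float = 0.03
    databases: tuple = ("ESP", "1KG", "GNOMAD")
    #: which frequency column set the fixture generator annotated with
    frequency_era: str = "study_initiation"

    def __post_init__(self):
        for t in (self.maf_threshold_dominant, self.maf_threshold_recessive):
            if not 0.0 < t < 1.0:
                raise ConfigError("rarity thresholds must be in (0,1)")

    def threshold(self, mode: str) -> float:
        if mode == "dominant":
            return self.maf_threshold_dominant
        if mode == "recessive":
            return self.maf_threshold_recessive
        raise ConfigError(f"unknown rarity mode {mode!r}")


@dataclass(frozen=True)
class BurdenInclusionPolicy:
    maf_threshold: float = 0.01
    consequence_whitelist: frozenset = frozenset({
        "frameshift", "missense", "stop_gain", "stop_loss", "essential_splice",
    })
    cadd_min_for_missense: float = 24.0

    def __post_init__(self):
        if self.maf_threshold <= 0 or self.cadd_min_for_missense <= 0:
            raise ConfigError("burden policy thresholds must be positive")


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------


def is_rare(annotation: VariantAnnotation, mode: str,
            policy: RarityPolicy) -> bool:
    """True iff the max database frequency is strictly below the mode's
    threshold (<1% dominant / de novo, <3% recessive)."""
    return annotation.max_maf(policy.databases) < policy.threshold(mode)


def is_functional(annotation: VariantAnnotation) -> bool:
    """True iff the consequence impacts protein sequence, a canonical splice
    site, a microRNA site, an enhancer, or an ENCODE-validated TFBS/promoter."""
    return annotation.consequence in FUNCTIONAL_CLASSES


def panel_screen(annotations: Iterable[VariantAnnotation],
                 panel_genes: Sequence[str],
                 policy: Optional[RarityPolicy] = None) -> pd.DataFrame:
    """Report rare (<1%) functional variants in CHD-panel genes.

    This is a pre-screen for manual review; it does not remove variants from
    the cascade.  An empty panel yields a warning and an empty report.
    """
    policy = policy or RarityPolicy()
    if not panel_genes:
        log.warning("panel_screen called with an empty panel gene list")
        return _empty_panel_report()
    panel = set(panel_genes)
    rows = []
    for ann in annotations:
        if ann.gene in panel and is_functional(ann) and is_rare(ann, "dominant", policy):
            rows.append({
                "gene": ann.gene,
                "variant": ":".join(map(str, ann.variant_key)),
                "consequence": ann.consequence,
                "max_maf": ann.max_maf(policy.databases),
            })
    return pd.DataFrame(rows) if rows else _empty_panel_report()


def _empty_panel_report() -> pd.DataFrame:
    return pd.DataFrame(columns=["gene", "variant", "consequence", "max_maf"])


_CATEGORY_CLASSES = {
    "missense": {"missense"},
    "intronic": {"intronic"},
    "splice_region": {"splice_region"},
    "synonymous": {"synonymous"},
    "utr3": {"utr3"},
    "utr5": {"utr5"},
    "upstream_1kb": {"upstream_1kb"},
}


def burden_variant_mask(annotations: Sequence[VariantAnnotation],
                        policy: BurdenInclusionPolicy,
                        category: Optional[str] = None,
                        relax_cadd: bool = False,
                        regions: Optional[Sequence[tuple]] = None) -> np.ndarray:
    """Boolean inclusion mask for the burden analysis.

    Default mode (``category=None``) applies the strict-impact consequence
    whitelist, the CADD > 24 rule on missense variants, and the MAF < 0.01
    rule.  Category mode selects by consequence class (or, for the two
    regulatory categories, by overlap with the supplied BED-style intervals)
    with the rarity rule only; ``relax_cadd`` additionally drops the CADD
    restriction in default mode.
    """
    if category is not None and category not in BURDEN_CATEGORIES:
        raise ConfigError(
            f"unknown burden category {category!r}; valid: {BURDEN_CATEGORIES}")
    mask = np.zeros(len(annotations), dtype=bool)
    for i, ann in enumerate(annotations):
        if ann.max_maf() >= policy.maf_threshold:
            continue
        if category is None:
            if ann.consequence not in policy.consequence_whitelist:
                continue
            if (ann.consequence == "missense" and not relax_cadd
                    and (ann.cadd_phred is None
                         or ann.cadd_phred <= policy.cadd_min_for_missense)):
                continue
            mask[i] = True
        elif category == "all_gene_body":
            mask[i] = True
        elif category in ("regulatory_fetal_heart", "tfbs_clusters"):
            if regions is None:
                raise ConfigError(
                    f"category {category!r} requires a BED-style region list")
            chrom, pos = ann.variant_key[0], ann.variant_key[1]
            mask[i] = any(c == chrom and start < pos <= end
                          for c, start, end in regions)
        else:
            mask[i] = ann.consequence in _CATEGORY_CLASSES[category]
    return mask


# ---------------------------------------------------------------------------
# Annotation table I/O
# ---------------------------------------------------------------------------

_ANN_COLUMNS = ["CHROM", "POS", "REF", "ALT", "GENE", "TRANSCRIPT",
                "CONSEQUENCE", "MAF_ESP", "MAF_1KG", "MAF_GNOMAD", "CADD",
                "INTERNAL_COUNT", "PLI", "REGULATORY"]


def read_annotation_table(path) -> Dict[tuple, VariantAnnotation]:
    """Read the tab-separated annotation table into a key-exact mapping."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _ANN_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"annotation table {path} missing columns {missing}")
    out: Dict[tuple, VariantAnnotation] = {}
    for row in df.itertuples(index=False):
        key = (str(row.CHROM), int(row.POS), str(row.REF), str(row.ALT))
        pop_maf = {}
        for db, col in (("ESP", row.MAF_ESP), ("1KG", row.MAF_1KG),
                        ("GNOMAD", row.MAF_GNOMAD)):
            if pd.notna(col):
                pop_maf[db] = float(col)
        out[key] = VariantAnnotation(
            variant_key=key,
            gene=str(row.GENE),
            transcript=None if pd.isna(row.TRANSCRIPT) else str(row.TRANSCRIPT),
            consequence=str(row.CONSEQUENCE),
            pop_maf=pop_maf,
            cadd_phred=None if pd.isna(row.CADD) else float(row.CADD),
            internal_cohort_count=int(row.INTERNAL_COUNT),
            pli=None if pd.isna(row.PLI) else float(row.PLI),
            regulatory_region=bool(row.REGULATORY),
        )
    return out


def write_annotation_table(path, annotations: Iterable[VariantAnnotation]) -> None:
    rows = []
    for ann in annotations:
        chrom, pos, ref, alt = ann.variant_key
        rows.append({
            "CHROM": chrom, "POS": pos, "REF": ref, "ALT": alt,
            "GENE": ann.gene, "TRANSCRIPT": ann.transcript or "",
            "CONSEQUENCE": ann.consequence,
            "MAF_ESP": ann.pop_maf.get("ESP", ""),
            "MAF_1KG": ann.pop_maf.get("1KG", ""),
            "MAF_GNOMAD": ann.pop_maf.get("GNOMAD", ""),
            "CADD": "" if ann.cadd_phred is None else ann.cadd_phred,
            "INTERNAL_COUNT": ann.internal_cohort_count,
            "PLI": "" if ann.pli is None else ann.pli,
            "REGULATORY": int(ann.regulatory_region),
        })
    pd.DataFrame(rows, columns=_ANN_COLUMNS).to_csv(path, sep="\t", index=False)
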