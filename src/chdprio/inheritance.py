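"""Inheritance-mode classification over a sequenced family quintet.

Qualifying (rare, functional) variants are classified per gene into de novo,
homozygous recessive, compound heterozygous, X-linked recessive, or inherited
loss-of-function (retained only in genes intolerant of loss of function,
pLI > 0.75).  Compound-heterozygote phase is inferred by transmission: the
parent of origin is read from the parental genotypes, not from read-backed
phasing.  A variant heterozygous in both parents has ambiguous origin and may
satisfy either side of a compound pair, but not both simultaneously; two
distinct variants are always required.

Unaffected-sibling exclusion operates on the *full* causal configuration: a
candidate call is voided only when a sibling's genotypes reproduce the
proband's complete genotype state for that call (both alleles of a homozygous
call; at least one maternal and one paternal variant of a compound-het set;
the hemizygous state for an X-linked call).  A sibling heterozygous for a
single variant of a compound pair is a consistent carrier and does not void
the call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from chdprio.annotation import (
    LOF_CLASSES,
    RarityPolicy,
    VariantAnnotation,
    is_functional,
    is_rare,
)
from chdprio.errors import DataError
from chdprio.genomic_io import (
    FEMALE,
    MALE,
    GenotypedVariant,
    Pedigree,
)
from chdprio.qc_filters import (
    FamilyQCConfig,
    depth_filter,
    homopolymer_adjacent,
    internal_cohort_filter,
)

log = logging.getLogger(__name__)

DE_NOVO = "de_novo"
HOM_RECESSIVE = "homozygous_recessive"
COMPOUND_HET = "compound_heterozygous"
X_LINKED = "x_linked_recessive"
INHERITED_LOF = "inherited_lof"

CONSISTENT = "consistent"


@dataclass(frozen=True)
class InheritanceCall:
    """Per-gene inheritance verdict with supporting evidence."""

    gene: str
    mode: str
    #: list of (variant_key, parental_origin in {maternal, paternal, both, de_novo})
    supporting_variants: tuple
    #: sibling_id -> "consistent" or "excluded_by:<variant keys>"
    sibling_exclusion: dict = field(default_factory=dict)

    @property
    def is_excluded(self) -> bool:
        return any(v != CONSISTENT for v in self.sibling_exclusion.values())

    @property
    def variant_keys(self) -> list:
        return [k for k, _ in self.supporting_variants]


def _call(variant: GenotypedVariant, sample_id: str):
    c = variant.calls.get(sample_id)
    return c


def _is_carrier(variant: GenotypedVariant, sample_id: str) -> bool:
    c = _call(variant, sample_id)
    return bool(c is not None and c.is_carrier)


def _is_hemi_or_hom_alt(variant, sample_id) -> bool:
    c = _call(variant, sample_id)
    return bool(c is not None and (c.is_hemi_alt or c.is_hom_alt))


def _is_explicit_hom_ref(variant, sample_id) -> bool:
    c = _call(variant, sample_id)
    return bool(c is not None and not c.is_missing and (c.dosage or 0) == 0)


# ---------------------------------------------------------------------------
# De novo
# ---------------------------------------------------------------------------


def classify_de_novo(variant: GenotypedVariant, annotation: VariantAnnotation,
                     pedigree: Pedigree, qc: FamilyQCConfig,
                     policy: Optional[RarityPolicy] = None) -> bool:
    """True iff the proband carries the allele, both parents are explicitly
    homozygous reference at adequate depth, and the variant is rare at the
    dominant (<1%) threshold."""
    policy = policy or RarityPolicy()
    trio = [pedigree.proband_id, pedigree.father_id, pedigree.mother_id]
    for parent in (pedigree.father_id, pedigree.mother_id):
        c = _call(variant, parent)
        if c is None or c.is_missing:
            log.info("de novo check at %s: parent %s genotype missing",
                     variant.key_str, parent)
            return False
    if not _is_carrier(variant, pedigree.proband_id):
        return False
    if not (_is_explicit_hom_ref(variant, pedigree.father_id)
            and _is_explicit_hom_ref(variant, pedigree.mother_id)):
        return False
    if not depth_filter(variant, trio, qc):
        return False
    return is_rare(annotation, "dominant", policy)


# ---------------------------------------------------------------------------
# Recessive / compound het / X-linked
# ---------------------------------------------------------------------------


def _sibling_verdict_hom(variant, sibling) -> str:
    if _is_hemi_or_hom_alt(variant, sibling.sample_id):
        return f"excluded_by:{variant.key_str}"
    return CONSISTENT


def classify_x_linked(gene_variants: Sequence[tuple],
                      pedigree: Pedigree) -> Optional[InheritanceCall]:
    """Classify an X-chromosome gene as X-linked recessive.

    Male proband: hemizygous alternate with a carrier mother and non-carrier
    father.  Female proband: homozygous alternate with carrier parents.  The
    call is voided if an unaffected brother is hemizygous alternate (or an
    unaffected sister reproduces the homozygous state); heterozygous sisters
    are carriers and do not void.
    """
    call = _classify_x_raw(gene_variants, pedigree)
    if call is None or call.is_excluded:
        return None
    return call


def _log_excluded(call: InheritanceCall) -> None:
    log.info("%s call in %s voided by unaffected sibling(s): %s",
             call.mode, call.gene,
             {k: v for k, v in call.sibling_exclusion.items() if v != CONSISTENT})


def classify_gene_recessive(gene_variants: Sequence[tuple], pedigree: Pedigree,
                            policy: Optional[RarityPolicy] = None,
                            ) -> Optional[InheritanceCall]:
    """Classify one gene's qualifying variants into a recessive mode.

    ``gene_variants`` is a list of (GenotypedVariant, VariantAnnotation)
    restricted to one gene, each already functional and rare at the recessive
    threshold.  Returns the retained call or None (no fitting mode, or the
    call was voided by an unaffected sibling).
    """
    call = classify_gene_recessive_raw(gene_variants, pedigree, policy)
    if call is None or call.is_excluded:
        return None
    return call


def classify_gene_recessive_raw(gene_variants: Sequence[tuple],
                                pedigree: Pedigree,
                                policy: Optional[RarityPolicy] = None,
                                ) -> Optional[InheritanceCall]:
    """As :func:`classify_gene_recessive` but returns voided calls too (their
    ``sibling_exclusion`` map says which sibling matched the configuration)."""
    if not gene_variants:
        return None
    gene = gene_variants[0][1].gene
    if any(ann.gene != gene for _v, ann in gene_variants):
        raise DataError("classify_gene_recessive requires single-gene input")

    if gene_variants[0][0].on_x:
        raw = _classify_x_raw(gene_variants, pedigree)
        return raw

    proband_id = pedigree.proband_id
    father_id, mother_id = pedigree.father_id, pedigree.mother_id

    # homozygous recessive: proband hom-alt, both parents het
    for variant, _ann in gene_variants:
        pc = _call(variant, proband_id)
        if pc is None or not pc.is_hom_alt:
            continue
        fc, mc = _call(variant, father_id), _call(variant, mother_id)
        if not (fc is not None and fc.is_het and mc is not None and mc.is_het):
            continue
        exclusion = {
            sib.sample_id: _sibling_verdict_hom(variant, sib)
            for sib in pedigree.unaffected_siblings
        }
        call = InheritanceCall(
            gene=gene, mode=HOM_RECESSIVE,
            supporting_variants=((variant.variant_key, "both"),),
            sibling_exclusion=exclusion,
        )
        if call.is_excluded:
            _log_excluded(call)
        return call

    # compound heterozygous: >=1 maternal and >=1 paternal het variant
    maternal, paternal, ambiguous = [], [], []
    hap_index = {"maternal": {}, "paternal": {}}  # key -> haplotype of alt
    for variant, _ann in gene_variants:
        pc = _call(variant, proband_id)
        if pc is None or not pc.is_het:
            continue
        m = _is_carrier(variant, mother_id)
        f = _is_carrier(variant, father_id)
        if m and f:
            ambiguous.append(variant)
        elif m:
            maternal.append(variant)
            if pc.phased:
                hap_index["maternal"][variant.key_str] = pc.alleles.index(1)
        elif f:
            paternal.append(variant)
            if pc.phased:
                hap_index["paternal"][variant.key_str] = pc.alleles.index(1)
    _check_phase_consistency(hap_index)

    feasible = ((maternal and paternal)
                or (maternal and ambiguous)
                or (paternal and ambiguous)
                or len(ambiguous) >= 2)
    if feasible:
        support = (
            [(v.variant_key, "maternal") for v in maternal]
            + [(v.variant_key, "paternal") for v in paternal]
            + [(v.variant_key, "both") for v in ambiguous]
        )
        mat_capable = {v.variant_key for v in maternal + ambiguous}
        pat_capable = {v.variant_key for v in paternal + ambiguous}
        exclusion = {}
        for sib in pedigree.unaffected_siblings:
            carried = {v.variant_key for v in maternal + paternal + ambiguous
                       if _is_carrier(v, sib.sample_id)}
            cm, cp = carried & mat_capable, carried & pat_capable
            # a full configuration needs two distinct variants, one per side
            matched = bool(cm and cp) and not (len(cm | cp) == 1)
            if matched:
                keys = sorted(":".join(map(str, k)) for k in (cm | cp))
                exclusion[sib.sample_id] = "excluded_by:" + ";".join(keys)
            else:
                exclusion[sib.sample_id] = CONSISTENT
        call = InheritanceCall(
            gene=gene, mode=COMPOUND_HET,
            supporting_variants=tuple(support),
            sibling_exclusion=exclusion,
        )
        if call.is_excluded:
            _log_excluded(call)
        return call
    return None


def _check_phase_consistency(hap_index: dict) -> None:
    """Phased proband genotypes must place all maternal-origin alternates on
    one haplotype and all paternal-origin alternates on the other."""
    for side, mapping in hap_index.items():
        if len(set(mapping.values())) > 1:
            raise DataError(
                f"phased genotypes contradict {side} transmission inference at "
                + ", ".join(sorted(mapping)))
    mat, pat = hap_index["maternal"], hap_index["paternal"]
    if mat and pat and set(mat.values()) == set(pat.values()):
        raise DataError(
            "phased genotypes place maternal and paternal alternates on the "
            "same haplotype: " + ", ".join(sorted(list(mat) + list(pat))))


def _classify_x_raw(gene_variants, pedigree) -> Optional[InheritanceCall]:
    """X-linked classification that reports voided calls (internal)."""
    proband = pedigree.proband
    if proband.sex not in (MALE, FEMALE):
        raise DataError("proband sex must be known for X-linked analysis")
    gene = gene_variants[0][1].gene
    best_voided = None
    for variant, _ann in gene_variants:
        pc = _call(variant, pedigree.proband_id)
        if pc is None or pc.is_missing:
            continue
        if proband.sex == MALE:
            if pc.ploidy == 2 and pc.is_het:
                log.warning("diploid-coded male X het at %s flagged "
                            "inconsistent; dropped from X-linked analysis",
                            variant.key_str)
                continue
            ok = ((pc.is_hemi_alt or pc.is_hom_alt)
                  and _is_carrier(variant, pedigree.mother_id)
                  and not _is_carrier(variant, pedigree.father_id))
        else:
            ok = (pc.is_hom_alt
                  and _is_carrier(variant, pedigree.mother_id)
                  and _is_carrier(variant, pedigree.father_id))
        if not ok:
            continue
        exclusion = {}
        for sib in pedigree.unaffected_siblings:
            if sib.sex == MALE:
                exclusion[sib.sample_id] = _sibling_verdict_hom(variant, sib)
            else:
                sc = _call(variant, sib.sample_id)
                excluded = sc is not None and sc.is_hom_alt
                exclusion[sib.sample_id] = (
                    f"excluded_by:{variant.key_str}" if excluded else CONSISTENT)
        call = InheritanceCall(
            gene=gene, mode=X_LINKED,
            supporting_variants=((variant.variant_key, "maternal"),),
            sibling_exclusion=exclusion,
        )
        if not call.is_excluded:
            return call
        best_voided = call
        _log_excluded(call)
    return best_voided


# ---------------------------------------------------------------------------
# Inherited loss-of-function retention
# ---------------------------------------------------------------------------


def inherited_lof_retention(annotation: VariantAnnotation) -> bool:
    """Retain an inherited frameshift / start-stop variant only in a gene
    intolerant to loss of function (pLI strictly above 0.75)."""
    if annotation.consequence not in LOF_CLASSES:
        return False
    if annotation.pli is None:
        log.warning("pLI missing for %s; inherited LoF variant not retained",
                    annotation.gene)
        return False
    return annotation.pli > 0.75


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

STAGE_CANDIDATE = "candidate"
STAGES = ("unannotated", "depth", "sibling_depth", "homopolymer",
          "internal_cohort", "rarity", "function", "proband_non_carrier",
          "sibling_excluded", "no_inheritance_mode", STAGE_CANDIDATE)


def run_family_cascade(variants: Iterable[GenotypedVariant],
                       pedigree: Pedigree,
                       annotations: Dict[tuple, VariantAnnotation],
                       family_qc: Optional[FamilyQCConfig] = None,
                       rarity_policy: Optional[RarityPolicy] = None,
                       reference=None) -> tuple:
    """Run QC -> rarity/function -> inheritance classification on a family.

    Returns (calls, audit) where ``calls`` is a list of retained
    :class:`InheritanceCall` and ``audit`` a DataFrame recording, for every
    input variant, the stage at which it was removed (or "candidate").
    """
    qc = family_qc or FamilyQCConfig()
    policy = rarity_policy or RarityPolicy()
    trio = [pedigree.proband_id, pedigree.father_id, pedigree.mother_id]
    all_members = pedigree.sample_ids

    stage_of: Dict[tuple, str] = {}
    gene_of: Dict[tuple, str] = {}
    survivors: List[tuple] = []  # (variant, annotation, sibling_depth_ok)

    for variant in variants:
        key = variant.variant_key
        ann = annotations.get(key)
        gene_of[key] = ann.gene if ann else ""
        if ann is None:
            stage_of[key] = "unannotated"
            continue
        if not depth_filter(variant, trio, qc):
            stage_of[key] = "depth"
            continue
        sib_depth_ok = depth_filter(variant, all_members, qc)
        if reference is not None and homopolymer_adjacent(variant, reference, qc):
            stage_of[key] = "homopolymer"
            continue
        if not internal_cohort_filter(ann, qc):
            stage_of[key] = "internal_cohort"
            continue
        if not is_rare(ann, "recessive", policy):
            stage_of[key] = "rarity"
            continue
        if not is_functional(ann):
            stage_of[key] = "function"
            continue
        if not _is_carrier(variant, pedigree.proband_id):
            stage_of[key] = "proband_non_carrier"
            continue
        survivors.append((variant, ann, sib_depth_ok))

    calls: List[InheritanceCall] = []
    supporting_keys = set()
    voided_keys = set()

    # de novo (variant-level, dominant threshold)
    for variant, ann, _sd in survivors:
        if classify_de_novo(variant, ann, pedigree, qc, policy):
            calls.append(InheritanceCall(
                gene=ann.gene, mode=DE_NOVO,
                supporting_variants=((variant.variant_key, "de_novo"),),
                sibling_exclusion={},
            ))
            supporting_keys.add(variant.variant_key)

    # inherited loss-of-function retention (dominant threshold, pLI gate)
    for variant, ann, _sd in survivors:
        if variant.variant_key in supporting_keys:
            continue
        inherited = (_is_carrier(variant, pedigree.father_id)
                     or _is_carrier(variant, pedigree.mother_id))
        if (inherited and is_rare(ann, "dominant", policy)
                and inherited_lof_retention(ann)):
            origin = "both" if (_is_carrier(variant, pedigree.father_id)
                                and _is_carrier(variant, pedigree.mother_id)) else (
                "paternal" if _is_carrier(variant, pedigree.father_id) else "maternal")
            calls.append(InheritanceCall(
                gene=ann.gene, mode=INHERITED_LOF,
                supporting_variants=((variant.variant_key, origin),),
                sibling_exclusion={},
            ))
            supporting_keys.add(variant.variant_key)

    # per-gene recessive classification (requires depth in all members)
    by_gene: Dict[str, list] = {}
    sib_depth_fail = set()
    for variant, ann, sd in survivors:
        if not sd:
            sib_depth_fail.add(variant.variant_key)
            continue
        by_gene.setdefault(ann.gene, []).append((variant, ann))
    for gene, gvars in sorted(by_gene.items()):
        raw = classify_gene_recessive_raw(gvars, pedigree, policy)
        if raw is None:
            continue
        if raw.is_excluded:
            voided_keys.update(raw.variant_keys)
        else:
            calls.append(raw)
            supporting_keys.update(raw.variant_keys)

    for variant, ann, _sd in survivors:
        key = variant.variant_key
        if key in supporting_keys:
            stage_of[key] = STAGE_CANDIDATE
        elif key in voided_keys:
            stage_of[key] = "sibling_excluded"
        elif key in sib_depth_fail:
            stage_of[key] = "sibling_depth"
        else:
            stage_of[key] = "no_inheritance_mode"

    audit = pd.DataFrame({
        "variant": [":".join(map(str, k)) for k in stage_of],
        "gene": [gene_of[k] for k in stage_of],
        "stage": [stage_of[k] for k in stage_of],
    })
    return calls, audit
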