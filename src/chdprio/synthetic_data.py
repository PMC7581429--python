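"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators live here:

* :func:`make_quintet_fixture` writes a five-sample family VCF (father, mother,
  two unaffected siblings, affected male proband), PED, annotation table,
  reference FASTA fragment and two differential-expression tables that encode
  the published worked example of the prioritization cascade: 22 qualifying
  variant rows across ten genes (seven compound-heterozygous, one homozygous
  recessive, two X-linked) plus configurable decoy genes that each violate
  exactly one cascade rule.  Variants are placed on synthetic contigs - the
  fixture makes no real-genome coordinate claims; dbSNP identifiers are
  carried verbatim in the VCF ID column for traceability.  In
  ``study_initiation`` frequency mode, population frequencies above the 3%
  recessive threshold are clamped to 2.9% to emulate the sparser frequency
  databases available when the study began (an emulation, not historical
  data); in ``current`` mode the printed gnomAD frequencies are used, which
  eliminates the two genes whose qualifying variant is now known to be common.

* :func:`simulate_cohort` draws a case-control genotype matrix with planted
  per-gene carrier effects through a logistic disease model.

* :func:`simulate_det_tables` draws differential-expression tables with
  planted concordant and discordant genes.

All generators are seed-deterministic and emit files that
:mod:`chdprio.genomic_io` reads without special-casing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from chdprio.annotation import VariantAnnotation, write_annotation_table
from chdprio.burden import CohortDataset
from chdprio.errors import ConfigError, DataError
from chdprio.genomic_io import (
    AFFECTED,
    FEMALE,
    MALE,
    UNAFFECTED,
    GenotypeCall,
    GenotypedVariant,
    Pedigree,
    PedigreeMember,
    write_vcf,
)

FATHER, MOTHER = "I.1", "I.2"
BROTHER, SISTER, PROBAND = "II.1", "II.2", "II.3"
SAMPLE_ORDER = (FATHER, MOTHER, BROTHER, SISTER, PROBAND)

#: the published worked-example variant rows: (gene, mode, consequence,
#: variant label, origin, brother genotype, sister genotype, gnomAD MAF in
#: percent (None = absent/novel), dbSNP id).
WORKED_EXAMPLE_ROWS: Tuple[tuple, ...] = (
    ("HSPG2", "cmpd_het", "missense", "c.2074G>A", "maternal", "WT", "WT", 0.288, "rs143669458"),
    ("HSPG2", "cmpd_het", "missense", "c.326G>A", "paternal", "Het", "Het", 0.0, "rs773796176"),
    ("HSPG2", "cmpd_het", "promoter", "c.-227C>A", "paternal", "WT", "WT", 1.392, "rs566166086"),
    ("SLC9A1", "cmpd_het", "promoter", "c.-906T>C", "paternal", "Het", "Het", 1.227, "rs114101904"),
    ("SLC9A1", "cmpd_het", "promoter", "c.-947T>G", "maternal", "WT", "WT", 27.175, "rs11588974"),
    ("SLC9A1", "cmpd_het", "promoter", "c.-1085A>G", "paternal", "Het", "Het", 0.841, "rs116299278"),
    ("SLC9A1", "cmpd_het", "encode_tfbs", "c.-1138C>T", "paternal", "Het", "Het", 0.93, "rs75089536"),
    ("SLC9A1", "cmpd_het", "promoter", "c.-1311G>A", "paternal", "Het", "Het", 0.93, "rs77414471"),
    ("APOB", "cmpd_het", "missense", "c.13441G>A", "maternal", "WT", "Het", 2.475, "rs1801695"),
    ("APOB", "cmpd_het", "missense", "c.751G>A", "paternal", "Het", "WT", 0.071, "rs61741625"),
    ("LRP2", "cmpd_het", "missense", "c.9613A>G", "maternal", "WT", "WT", 0.407, "rs35734447"),
    ("LRP2", "cmpd_het", "missense", "c.170C>T", "paternal", "WT", "WT", 0.032, "rs115350461"),
    ("SDHD", "cmpd_het", "promoter", "c.-815G>C", "maternal", "Het", "WT", 0.573, "rs117661257"),
    ("SDHD", "cmpd_het", "encode_tfbs", "c.-205G>A", "paternal", "WT", "WT", 0.241, "rs61734353"),
    ("SDHD", "cmpd_het", "missense", "c.34G>A", "maternal", "Het", "WT", 0.729, "rs34677591"),
    ("PRTG", "cmpd_het", "mirna_site", "c.*3501T>G", "paternal", "Het", "WT", 0.739, "rs77181316"),
    ("PRTG", "cmpd_het", "mirna_site", "c.*2678A>G", "maternal", "WT", "Het", 0.019, "rs756136447"),
    ("HN1", "cmpd_het", "encode_tfbs", "c.56+617C>T", "maternal", "Het", "WT", 3.764, "rs117213586"),
    ("HN1", "cmpd_het", "promoter", "c.-1748A>C", "paternal", "WT", "Het", 0.816, "rs73995795"),
    ("SIK1", "hom_rec", "missense", "c.2087C>T", "both", "WT", "Het", None, "rs1256991707"),
    ("ELF4", "x_linked", "missense", "c.1144G>A", "maternal", "WT", "Het", 0.025, "rs148953158"),
    ("HS6ST2", "x_linked", "missense", "c.948-40041G>A", "maternal", "WT", "Het", 0.146, "rs201239951"),
)

WORKED_EXAMPLE_GENES = ("HSPG2", "SLC9A1", "APOB", "LRP2", "SDHD", "PRTG", "HN1",
                "SIK1", "ELF4", "HS6ST2")
X_GENES = ("ELF4", "HS6ST2")
#: genes whose qualifying variant exceeds the 3% threshold in current gnomAD
CURRENT_ERA_ELIMINATED = ("SLC9A1", "HN1")

#: ESP-era emulation clamp: just below the 3% recessive rarity threshold
_STUDY_ERA_CLAMP = 0.029

DECOY_RULES = ("depth", "homopolymer", "internal_cohort", "rarity",
               "function", "sibling", "no_mode", "det_discordant",
               "det_missing_timepoint")

#: cascade stage at which each decoy rule's variants must be removed
DECOY_EXPECTED_STAGE = {
    "depth": "depth",
    "homopolymer": "homopolymer",
    "internal_cohort": "internal_cohort",
    "rarity": "rarity",
    "function": "function",
    "sibling": "sibling_excluded",
    "no_mode": "no_inheritance_mode",
    "det_discordant": "candidate",  # survives the cascade, fails DET
    "det_missing_timepoint": "candidate",
}


@dataclass(frozen=True)
class QuintetFixtureSpec:
    frequency_mode: str = "study_initiation"  # study_initiation | current | off
    n_decoys_per_rule: int = 3
    genotype_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.frequency_mode not in ("study_initiation", "current", "off"):
            raise ConfigError(f"unknown frequency_mode {self.frequency_mode!r}")
        if not 0.0 <= self.genotype_error_rate < 1.0:
            raise ConfigError("genotype_error_rate must be in [0,1)")


@dataclass
class QuintetFixture:
    """Paths of the generated inputs plus machine-readable ground truth."""

    vcf: Path
    ped: Path
    annotations: Path
    reference: Path
    det_d0: Path
    det_d25: Path
    truth: dict


@dataclass(frozen=True)
class CohortSimSpec:
    n_cases: int = 130
    n_controls: int = 861
    n_genes: int = 2
    variants_per_gene: int = 10
    maf_range: tuple = (0.001, 0.01)
    carrier_log_odds: Optional[tuple] = None  # per gene; None = all null
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_cases, self.n_controls, self.n_genes,
               self.variants_per_gene) <= 0:
            raise ConfigError("counts must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5)")
        if self.carrier_log_odds is None:
            object.__setattr__(self, "carrier_log_odds",
                               (0.0,) * self.n_genes)
        if len(self.carrier_log_odds) != self.n_genes:
            raise ConfigError("carrier_log_odds must have one entry per gene")


@dataclass(frozen=True)
class DETSimSpec:
    n_genes: int = 100
    n_concordant: int = 40
    n_discordant: int = 30
    effect_log2fc: float = 2.0
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_concordant + self.n_discordant > self.n_genes:
            raise ConfigError("concordant + discordant genes exceed n_genes")


# ---------------------------------------------------------------------------
# Worked-example quintet fixture
# ---------------------------------------------------------------------------

_ALT_OF = {"A": "G", "C": "T", "G": "A", "T": "C"}

_WT = "WT"


def _random_sequence(rng: np.random.Generator, length: int) -> list:
    """Random A/C/G/T sequence with no homopolymer run longer than 3."""
    bases = "ACGT"
    seq: List[str] = []
    for _ in range(length):
        b = bases[rng.integers(4)]
        while len(seq) >= 3 and seq[-1] == seq[-2] == seq[-3] == b:
            b = bases[rng.integers(4)]
        seq.append(b)
    return seq


def _diploid(dosage: int) -> tuple:
    return {0: (0, 0), 1: (0, 1), 2: (1, 1)}[dosage]


def _geno_from_label(label: str) -> int:
    return {"WT": 0, "Het": 1, "Hom": 2}[label]


def _quintet_calls(origin: str, brother: str, sister: str, on_x: bool,
                   proband_dosage: Optional[int] = None,
                   depth: int = 35, proband_depth: Optional[int] = None) -> dict:
    """Genotypes for the five family members implied by a variant's origin
    and the printed sibling genotypes."""
    def call(alleles, dp):
        return GenotypeCall(alleles=alleles, depth=dp, quality=99.0)

    dp_p = proband_depth if proband_depth is not None else depth
    if on_x:
        # male proband and brother are hemizygous on X
        mother = _diploid({"maternal": 1, "both": 1}.get(origin, 0))
        father = (1,) if origin in ("paternal", "both") else (0,)
        pro = (1,) if proband_dosage is None or proband_dosage >= 1 else (0,)
        bro = (1,) if _geno_from_label(brother) >= 1 else (0,)
        sis = _diploid(_geno_from_label(sister))
        return {
            FATHER: call(father, depth), MOTHER: call(mother, depth),
            BROTHER: call(bro, depth), SISTER: call(sis, depth),
            PROBAND: call(pro, dp_p),
        }
    father_d = 1 if origin in ("paternal", "both") else 0
    mother_d = 1 if origin in ("maternal", "both") else 0
    if proband_dosage is None:
        proband_dosage = 2 if origin == "both" else 1
    return {
        FATHER: call(_diploid(father_d), depth),
        MOTHER: call(_diploid(mother_d), depth),
        BROTHER: call(_diploid(_geno_from_label(brother)), depth),
        SISTER: call(_diploid(_geno_from_label(sister)), depth),
        PROBAND: call(_diploid(proband_dosage), dp_p),
    }


def quintet_pedigree() -> Pedigree:
    """The two-parent, three-offspring family with an affected male proband."""
    members = [
        PedigreeMember(FATHER, None, None, MALE, UNAFFECTED),
        PedigreeMember(MOTHER, None, None, FEMALE, UNAFFECTED),
        PedigreeMember(BROTHER, FATHER, MOTHER, MALE, UNAFFECTED),
        PedigreeMember(SISTER, FATHER, MOTHER, FEMALE, UNAFFECTED),
        PedigreeMember(PROBAND, FATHER, MOTHER, MALE, AFFECTED),
    ]
    return Pedigree(members=members, proband_id=PROBAND)


def write_quintet_ped(path) -> None:
    lines = [
        f"5H\t{FATHER}\t0\t0\t1\t1",
        f"5H\t{MOTHER}\t0\t0\t2\t1",
        f"5H\t{BROTHER}\t{FATHER}\t{MOTHER}\t1\t1",
        f"5H\t{SISTER}\t{FATHER}\t{MOTHER}\t2\t1",
        f"5H\t{PROBAND}\t{FATHER}\t{MOTHER}\t1\t2",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def _decoy_variant_specs(n_per_rule: int) -> list:
    """Per-decoy-gene variant plans: each gene violates exactly one rule.

    Unless the rule dictates otherwise, every decoy gene carries a valid
    compound-het pair (one maternal, one paternal, siblings clean) so that the
    violated rule is the only thing standing between it and candidacy.
    """
    plans = []
    for rule in DECOY_RULES:
        for i in range(n_per_rule):
            gene = f"DECOY_{rule.upper()}_{i + 1}"
            base = dict(consequence="missense", maf=0.001, internal_count=0,
                        proband_depth=None, homopolymer=False)
            if rule == "no_mode":
                variants = [dict(base, origin="paternal", brother=_WT, sister=_WT)]
            else:
                variants = [
                    dict(base, origin="maternal", brother=_WT, sister=_WT),
                    dict(base, origin="paternal", brother=_WT, sister=_WT),
                ]
            if rule == "depth":
                for v in variants:
                    v["proband_depth"] = 9
            elif rule == "homopolymer":
                for v in variants:
                    v["homopolymer"] = True
            elif rule == "internal_cohort":
                for v in variants:
                    v["internal_count"] = 6
            elif rule == "rarity":
                for v in variants:
                    v["maf"] = 0.10
            elif rule == "function":
                for v in variants:
                    v["consequence"] = "intronic"
            elif rule == "sibling":
                # the brother reproduces the full compound-het configuration
                for v in variants:
                    v["brother"] = "Het"
            plans.append((gene, rule, variants))
    return plans


def make_quintet_fixture(spec: Optional[QuintetFixtureSpec] = None,
                        outdir=None) -> QuintetFixture:
    """Write the worked-example quintet fixture (VCF, PED, annotations,
    reference FASTA, DET tables) and return paths plus ground truth."""
    spec = spec or QuintetFixtureSpec()
    outdir = Path(outdir) if outdir is not None else Path.cwd() / "fixture"
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    variants: List[GenotypedVariant] = []
    annotations: List[VariantAnnotation] = []
    contigs: Dict[str, list] = {}
    det_plan: Dict[str, str] = {}  # gene -> DET behaviour
    decoy_truth: Dict[str, str] = {}

    def add_contig(name: str, n_slots: int) -> None:
        if name not in contigs:
            contigs[name] = _random_sequence(rng, 200 + 60 * n_slots)

    def place(contig: str, slot: int) -> int:
        return 100 + 60 * slot

    def add_variant(gene, contig, slot, consequence, maf, internal_count,
                    calls, homopolymer=False, dbsnp=".", pli=None):
        pos = place(contig, slot)
        seq = contigs[contig]
        if homopolymer:
            run_base = "A" if seq[pos - 1] != "A" else "C"
            for k in range(pos - 8, pos - 1):
                seq[k] = run_base
            if seq[pos - 9] == run_base:
                seq[pos - 9] = "G" if run_base != "G" else "T"
        ref = seq[pos - 1]
        alt = _ALT_OF[ref]
        v = GenotypedVariant(chrom=contig, pos=pos, ref=ref, alt=alt,
                             filter_status="PASS", variant_id=dbsnp,
                             calls=calls)
        variants.append(v)
        pop = {} if maf is None else {"GNOMAD": float(maf)}
        annotations.append(VariantAnnotation(
            variant_key=v.variant_key, gene=gene, consequence=consequence,
            pop_maf=pop, cadd_phred=25.0 if consequence == "missense" else None,
            internal_cohort_count=internal_count, pli=pli,
            regulatory_region=consequence in ("promoter", "encode_tfbs",
                                              "enhancer"),
        ))

    # --- the published worked-example rows -------------------------------
    if spec.frequency_mode != "off":
        add_contig("X", sum(1 for r in WORKED_EXAMPLE_ROWS if r[0] in X_GENES))
        x_slot = 0
        slot_by_gene: Dict[str, int] = {}
        for gene, _mode, consequence, _label, origin, bro, sis, maf_pct, dbsnp in WORKED_EXAMPLE_ROWS:
            on_x = gene in X_GENES
            if on_x:
                contig, slot = "X", x_slot
                x_slot += 1
            else:
                contig = f"ctg_{gene}"
                slot = slot_by_gene.get(gene, 0)
                slot_by_gene[gene] = slot + 1
                add_contig(contig, sum(1 for r in WORKED_EXAMPLE_ROWS if r[0] == gene))
            maf = None if maf_pct is None else maf_pct / 100.0
            if maf is not None and spec.frequency_mode == "study_initiation":
                maf = min(maf, _STUDY_ERA_CLAMP)
            calls = _quintet_calls(origin, bro, sis, on_x)
            add_variant(gene, contig, slot, consequence, maf, 0, calls,
                        dbsnp=dbsnp)
            det_plan[gene] = "concordant"

    # --- decoys ------------------------------------------------------------
    for gene, rule, plans in _decoy_variant_specs(spec.n_decoys_per_rule):
        contig = f"ctg_{gene}"
        add_contig(contig, len(plans))
        for slot, vp in enumerate(plans):
            calls = _quintet_calls(vp["origin"], vp["brother"], vp["sister"],
                                   on_x=False, proband_depth=vp["proband_depth"])
            add_variant(gene, contig, slot, vp["consequence"], vp["maf"],
                        vp["internal_count"], calls,
                        homopolymer=vp["homopolymer"])
        det_plan[gene] = {
            "det_discordant": "discordant_d25",
            "det_missing_timepoint": "missing_d25",
        }.get(rule, "concordant")
        decoy_truth[gene] = DECOY_EXPECTED_STAGE[rule]

    # --- optional genotype noise ------------------------------------------
    if spec.genotype_error_rate > 0:
        variants = [_perturb_genotypes(v, spec.genotype_error_rate, rng)
                    for v in variants]

    # --- write files --------------------------------------------------------
    vcf_path = outdir / "quintet.vcf"
    write_vcf(vcf_path, variants, SAMPLE_ORDER)
    ped_path = outdir / "family.ped"
    write_quintet_ped(ped_path)
    ann_path = outdir / "annotations.tsv"
    write_annotation_table(ann_path, annotations)
    ref_path = outdir / "reference.fa"
    with open(ref_path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            s = "".join(seq)
            for k in range(0, len(s), 70):
                fh.write(s[k:k + 70] + "\n")

    det_d0 = outdir / "det_d0.tsv"
    det_d25 = outdir / "det_d25.tsv"
    _write_det_tables(det_plan, det_d0, det_d25, rng)

    expected = [] if spec.frequency_mode == "off" else [
        g for g in WORKED_EXAMPLE_GENES
        if spec.frequency_mode == "study_initiation"
        or g not in CURRENT_ERA_ELIMINATED
    ]
    truth = {
        "expected_candidates": sorted(expected),
        "decoy_expected_stage": decoy_truth,
        "mode_by_gene": {g: m for g, m, *_ in WORKED_EXAMPLE_ROWS},
    }
    return QuintetFixture(vcf=vcf_path, ped=ped_path, annotations=ann_path,
                          reference=ref_path, det_d0=det_d0, det_d25=det_d25,
                          truth=truth)


def _perturb_genotypes(variant: GenotypedVariant, rate: float,
                       rng: np.random.Generator) -> GenotypedVariant:
    new_calls = {}
    for s, call in variant.calls.items():
        if not call.is_missing and rng.random() < rate:
            alleles = list(call.alleles)
            i = int(rng.integers(len(alleles)))
            alleles[i] = 1 - alleles[i]
            call = GenotypeCall(alleles=tuple(alleles), depth=call.depth,
                                depth_available=call.depth_available,
                                quality=call.quality,
                                quality_available=call.quality_available,
                                phased=call.phased)
        new_calls[s] = call
    return variant.with_calls(new_calls)


def _write_det_tables(det_plan: Dict[str, str], path_d0, path_d25,
                      rng: np.random.Generator) -> None:
    rows_d0, rows_d25 = [], []
    for gene, behaviour in sorted(det_plan.items()):
        lfc = 2.0 + float(rng.normal(0, 0.1))
        for comparison in ("proband_vs_mother", "proband_vs_father"):
            rows_d0.append((gene, comparison, lfc, 0.001))
        if behaviour == "concordant":
            for comparison in ("proband_vs_mother", "proband_vs_father"):
                rows_d25.append((gene, comparison, lfc, 0.001))
        elif behaviour == "discordant_d25":
            rows_d25.append((gene, "proband_vs_mother", lfc, 0.001))
            rows_d25.append((gene, "proband_vs_father", -lfc, 0.001))
        elif behaviour == "missing_d25":
            for comparison in ("proband_vs_mother", "proband_vs_father"):
                rows_d25.append((gene, comparison, 0.05, 0.9))
    cols = ["gene", "comparison", "log2fc", "adj_p"]
    pd.DataFrame(rows_d0, columns=cols).to_csv(path_d0, sep="\t", index=False)
    pd.DataFrame(rows_d25, columns=cols).to_csv(path_d25, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Random quintets for classifier sweeps
# ---------------------------------------------------------------------------


def simulate_quintet(mode: str, seed: int) -> tuple:
    """One random in-memory quintet with a single planted inheritance mode.

    Returns (variants, annotations, pedigree, planted_gene).  Besides the
    planted gene, several decoy genes carry configurations that must NOT be
    called (single inherited het, common variant, sibling-matching compound
    pair, non-functional consequence, proband homozygote with a
    non-heterozygous parent).
    """
    from chdprio.inheritance import COMPOUND_HET, DE_NOVO, HOM_RECESSIVE, X_LINKED
    rng = np.random.default_rng(seed)
    pedigree = quintet_pedigree()
    variants: List[GenotypedVariant] = []
    annotations: Dict[tuple, VariantAnnotation] = {}
    counter = [0]

    def call(dosage, ploidy=2, depth=35):
        alleles = _diploid(dosage) if ploidy == 2 else ((1,) if dosage else (0,))
        return GenotypeCall(alleles=alleles, depth=depth, quality=99.0)

    def add(gene, chrom, calls, consequence="missense", maf=0.0):
        counter[0] += 1
        pos = 100 + 60 * counter[0]
        ref = "ACGT"[rng.integers(4)]
        v = GenotypedVariant(chrom=chrom, pos=pos, ref=ref, alt=_ALT_OF[ref],
                             calls=calls)
        variants.append(v)
        annotations[v.variant_key] = VariantAnnotation(
            variant_key=v.variant_key, gene=gene, consequence=consequence,
            pop_maf={"GNOMAD": maf} if maf else {},
            cadd_phred=25.0, internal_cohort_count=0,
        )

    gene = f"PLANT_{mode.upper()}"
    sib_benign = lambda: int(rng.integers(2))  # 0/0 or 0/1, never hom-alt
    if mode == DE_NOVO:
        add(gene, "ctg_plant", {
            FATHER: call(0), MOTHER: call(0), BROTHER: call(0),
            SISTER: call(0), PROBAND: call(1)})
    elif mode == HOM_RECESSIVE:
        add(gene, "ctg_plant", {
            FATHER: call(1), MOTHER: call(1), BROTHER: call(sib_benign()),
            SISTER: call(sib_benign()), PROBAND: call(2)})
    elif mode == COMPOUND_HET:
        # maternal variant: siblings may carry it; paternal variant: siblings
        # must not also carry the maternal one -> keep paternal siblings clean
        add(gene, "ctg_plant", {
            FATHER: call(0), MOTHER: call(1), BROTHER: call(sib_benign()),
            SISTER: call(sib_benign()), PROBAND: call(1)})
        add(gene, "ctg_plant", {
            FATHER: call(1), MOTHER: call(0), BROTHER: call(0),
            SISTER: call(0), PROBAND: call(1)})
    elif mode == X_LINKED:
        add(gene, "X", {
            FATHER: call(0, ploidy=1), MOTHER: call(1),
            BROTHER: call(0, ploidy=1), SISTER: call(int(rng.integers(2))),
            PROBAND: call(1, ploidy=1)})
    else:
        raise ConfigError(f"unknown plantable mode {mode!r}")

    # decoys that must not be called
    add("DECOY_SINGLE_HET", "ctg_d1", {
        FATHER: call(1), MOTHER: call(0), BROTHER: call(sib_benign()),
        SISTER: call(sib_benign()), PROBAND: call(1)})
    add("DECOY_COMMON", "ctg_d2", {
        FATHER: call(1), MOTHER: call(1), BROTHER: call(0),
        SISTER: call(0), PROBAND: call(2)}, maf=0.10)
    add("DECOY_SIBMATCH", "ctg_d3", {
        FATHER: call(0), MOTHER: call(1), BROTHER: call(1),
        SISTER: call(0), PROBAND: call(1)})
    add("DECOY_SIBMATCH", "ctg_d3", {
        FATHER: call(1), MOTHER: call(0), BROTHER: call(1),
        SISTER: call(0), PROBAND: call(1)})
    add("DECOY_NONFUNCTIONAL", "ctg_d4", {
        FATHER: call(1), MOTHER: call(1), BROTHER: call(0),
        SISTER: call(0), PROBAND: call(2)}, consequence="intronic")
    add("DECOY_BAD_PARENT", "ctg_d5", {
        FATHER: call(0), MOTHER: call(1), BROTHER: call(0),
        SISTER: call(0), PROBAND: call(2)})
    return variants, annotations, pedigree, gene


# ---------------------------------------------------------------------------
# Case-control cohort simulation
# ---------------------------------------------------------------------------


def simulate_cohort(spec: Optional[CohortSimSpec] = None) -> tuple:
    """Simulate a case-control dosage matrix with planted carrier effects.

    Variant MAFs are uniform in ``maf_range`` and genotypes drawn at
    Hardy-Weinberg proportions.  Under the all-null specification, case labels
    are a random permutation with the exact requested group sizes; with any
    non-zero per-gene carrier log-odds, case status is drawn from a logistic
    model on carrier state whose intercept is solved to give the requested
    expected case count.  Returns (CohortDataset, truth DataFrame).
    """
    spec = spec or CohortSimSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cases + spec.n_controls
    m = spec.n_genes * spec.variants_per_gene
    mafs = rng.uniform(*spec.maf_range, size=m)
    G = rng.binomial(2, mafs[None, :], size=(n, m)).astype(float)

    gene_names = [f"G{g + 1:04d}" for g in range(spec.n_genes)]
    gene_of_variant = np.repeat(np.arange(spec.n_genes), spec.variants_per_gene)
    effects = np.asarray(spec.carrier_log_odds, dtype=float)

    if np.all(effects == 0.0):
        phenotype = np.zeros(n, dtype=int)
        phenotype[rng.permutation(n)[:spec.n_cases]] = 1
    else:
        carrier = np.zeros((n, spec.n_genes))
        for g in range(spec.n_genes):
            carrier[:, g] = (G[:, gene_of_variant == g] >= 1).any(axis=1)
        eta_gene = carrier @ effects
        target = spec.n_cases / n
        lo, hi = -30.0, 30.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if expit(mid + eta_gene).mean() < target:
                lo = mid
            else:
                hi = mid
        phenotype = (rng.random(n) < expit((lo + hi) / 2 + eta_gene)).astype(int)
        if phenotype.sum() == 0 or phenotype.sum() == n:
            raise DataError("infeasible case count under the planted effects")

    if spec.missing_rate > 0:
        G[rng.random(G.shape) < spec.missing_rate] = np.nan

    anns = []
    keys = []
    for j in range(m):
        gene = gene_names[gene_of_variant[j]]
        key = ("ctg_sim", 100 + j, "A", "G")
        keys.append(key)
        anns.append(VariantAnnotation(
            variant_key=key, gene=gene, consequence="missense",
            pop_maf={"GNOMAD": float(mafs[j])}, cadd_phred=30.0,
            internal_cohort_count=0))
    ancestry = np.ones(n)
    dataset = CohortDataset(
        dosage=G, phenotype=phenotype, ancestry_fraction=ancestry,
        variant_annotations=anns,
        sample_ids=[f"S{i:05d}" for i in range(n)],
        variant_keys=keys,
    )
    truth = pd.DataFrame({
        "gene": gene_names,
        "carrier_log_odds": effects,
    })
    return dataset, truth


def plant_exact_carriers(n_cases: int, n_controls: int,
                         carriers_cases: int, carriers_controls: int) -> CohortDataset:
    """Deterministic single-variant dataset with exact carrier counts per
    phenotype group (for worked-example arithmetic)."""
    if carriers_cases > n_cases or carriers_controls > n_controls:
        raise ConfigError("carrier counts exceed group sizes")
    n = n_cases + n_controls
    dosage = np.zeros((n, 1))
    dosage[:carriers_cases, 0] = 1.0
    dosage[n_cases:n_cases + carriers_controls, 0] = 1.0
    phenotype = np.concatenate([np.ones(n_cases, int), np.zeros(n_controls, int)])
    ann = VariantAnnotation(
        variant_key=("ctg_sim", 100, "A", "G"), gene="LRP2",
        consequence="missense", pop_maf={"GNOMAD": 0.001}, cadd_phred=30.0)
    return CohortDataset(dosage=dosage, phenotype=phenotype,
                         ancestry_fraction=np.ones(n),
                         variant_annotations=[ann],
                         sample_ids=[f"S{i:05d}" for i in range(n)],
                         variant_keys=[ann.variant_key])


# ---------------------------------------------------------------------------
# DET table simulation
# ---------------------------------------------------------------------------


def simulate_det_tables(spec: Optional[DETSimSpec] = None,
                        timepoints: Sequence[str] = ("d0", "d25")) -> tuple:
    """Simulate DET tables with planted concordant/discordant genes.

    Returns ({timepoint: DataFrame}, truth) where truth maps each gene to
    "concordant", "discordant" or "null".
    """
    spec = spec or DETSimSpec()
    rng = np.random.default_rng(spec.seed)
    genes = [f"DG{g + 1:04d}" for g in range(spec.n_genes)]
    labels = (["concordant"] * spec.n_concordant
              + ["discordant"] * spec.n_discordant
              + ["null"] * (spec.n_genes - spec.n_concordant - spec.n_discordant))
    tables = {}
    for tp in timepoints:
        rows = []
        for gene, label in zip(genes, labels):
            sign = 1.0 if rng.random() < 0.5 else -1.0
            if label == "concordant":
                lm = sign * spec.effect_log2fc + rng.normal(0, spec.noise_sd)
                lf = sign * spec.effect_log2fc + rng.normal(0, spec.noise_sd)
                qm = qf = 0.001
            elif label == "discordant":
                lm = sign * spec.effect_log2fc + rng.normal(0, spec.noise_sd)
                lf = -sign * spec.effect_log2fc + rng.normal(0, spec.noise_sd)
                qm = qf = 0.001
            else:
                lm, lf = rng.normal(0, spec.noise_sd, 2)
                qm, qf = rng.uniform(0.2, 1.0, 2)
            rows.append((gene, "proband_vs_mother", lm, qm))
            rows.append((gene, "proband_vs_father", lf, qf))
        tables[tp] = pd.DataFrame(
            rows, columns=["gene", "comparison", "log2fc", "adj_p"])
    truth = dict(zip(genes, labels))
    return tables, truth
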