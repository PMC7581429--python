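"""Inheritance-mode classification: worked-example genotypes, sibling
exclusion semantics, and the full cascade's audit bookkeeping."""

import itertools

import pytest

from chdprio import synthetic_data as syn
from chdprio.annotation import RarityPolicy, VariantAnnotation
from chdprio.errors import DataError
from chdprio.genomic_io import (
    AFFECTED,
    FEMALE,
    MALE,
    UNAFFECTED,
    GenotypeCall,
    GenotypedVariant,
    Pedigree,
    PedigreeMember,
)
from chdprio.inheritance import (
    COMPOUND_HET,
    DE_NOVO,
    HOM_RECESSIVE,
    X_LINKED,
    classify_de_novo,
    classify_gene_recessive,
    classify_x_linked,
    inherited_lof_retention,
    run_family_cascade,
)
from chdprio.qc_filters import FamilyQCConfig

F, M, BRO, SIS, PRO = "I.1", "I.2", "II.1", "II.2", "II.3"


def _ped():
    return syn.quintet_pedigree()


def _gc(dosage, ploidy=2, depth=35, missing=False):
    if missing:
        return GenotypeCall((None, None), depth=0, depth_available=False,
                            quality=0.0, quality_available=False)
    alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[dosage] if ploidy == 2 \
        else ((1,) if dosage else (0,))
    return GenotypeCall(alleles, depth=depth, quality=99.0)


def _gv(pos, father=0, mother=0, brother=0, sister=0, proband=0,
        chrom="c1", ploidy_male=2, proband_depth=35):
    calls = {
        F: _gc(father, ploidy=ploidy_male),
        M: _gc(mother),
        BRO: _gc(brother, ploidy=ploidy_male),
        SIS: _gc(sister),
        PRO: (_gc(proband, ploidy=ploidy_male, depth=proband_depth)
              if proband != "missing" else _gc(0, missing=True)),
    }
    return GenotypedVariant(chrom=chrom, pos=pos, ref="A", alt="G", calls=calls)


def _ann(v, gene="G1", consequence="missense", maf=0.001, pli=None):
    return VariantAnnotation(
        variant_key=v.variant_key, gene=gene, consequence=consequence,
        pop_maf={"GNOMAD": maf}, cadd_phred=25.0, pli=pli)


class TestDeNovo:
    def test_proband_het_parents_homref(self):
        v = _gv(10, proband=1)
        assert classify_de_novo(v, _ann(v), _ped(), FamilyQCConfig())

    def test_carrier_parent_blocks(self):
        v = _gv(10, proband=1, mother=1)
        assert not classify_de_novo(v, _ann(v), _ped(), FamilyQCConfig())

    def test_missing_parent_blocks_and_logs(self, caplog):
        v = _gv(10, proband=1)
        calls = dict(v.calls)
        calls[F] = _gc(0, missing=True)
        v = v.with_calls(calls)
        with caplog.at_level("INFO"):
            assert not classify_de_novo(v, _ann(v), _ped(), FamilyQCConfig())
        assert "missing" in caplog.text

    def test_low_parental_depth_blocks(self):
        v = _gv(10, proband=1)
        calls = dict(v.calls)
        calls[M] = _gc(0, depth=9)
        v = v.with_calls(calls)
        assert not classify_de_novo(v, _ann(v), _ped(), FamilyQCConfig())

    def test_dominant_rarity_threshold(self):
        v = _gv(10, proband=1)
        assert not classify_de_novo(v, _ann(v, maf=0.02), _ped(),
                                    FamilyQCConfig())


class TestCompoundHet:
    def test_worked_example_three_variant_gene_retained(self):
        """Maternal missense + two paternal variants, the paternal missense
        het in both siblings: no sibling carries a maternal variant, so the
        compound-het call stands."""
        v1 = _gv(10, mother=1, proband=1)                      # maternal
        v2 = _gv(20, father=1, brother=1, sister=1, proband=1)  # paternal
        v3 = _gv(30, father=1, proband=1)                      # paternal
        gv = [(v, _ann(v, gene="HSPG2")) for v in (v1, v2, v3)]
        call = classify_gene_recessive(gv, _ped())
        assert call is not None and call.mode == COMPOUND_HET
        origins = dict(call.supporting_variants)
        assert origins[v1.variant_key] == "maternal"
        assert origins[v2.variant_key] == "paternal"
        assert call.sibling_exclusion == {BRO: "consistent", SIS: "consistent"}

    def test_sibling_with_full_configuration_voids(self):
        v1 = _gv(10, mother=1, proband=1, brother=1)
        v2 = _gv(20, father=1, proband=1, brother=1)
        gv = [(v, _ann(v)) for v in (v1, v2)]
        assert classify_gene_recessive(gv, _ped()) is None

    def test_sibling_exclusion_matches_brute_force(self):
        """Over all 3^2 sibling genotype combinations for a maternal+paternal
        pair, the call is voided exactly when the sibling carries both."""
        for bg, sg in itertools.product(range(3), repeat=2):
            v1 = _gv(10, mother=1, proband=1, brother=bg)
            v2 = _gv(20, father=1, proband=1, brother=sg)
            gv = [(v, _ann(v)) for v in (v1, v2)]
            call = classify_gene_recessive(gv, _ped())
            should_void = bg >= 1 and sg >= 1
            assert (call is None) == should_void, (bg, sg)

    def test_single_parent_side_is_not_compound(self):
        v1 = _gv(10, father=1, proband=1)
        v2 = _gv(20, father=1, proband=1)
        gv = [(v, _ann(v)) for v in (v1, v2)]
        assert classify_gene_recessive(gv, _ped()) is None

    def test_both_parent_het_variant_cannot_anchor_alone(self):
        v1 = _gv(10, father=1, mother=1, proband=1)
        gv = [(v1, _ann(v1))]
        assert classify_gene_recessive(gv, _ped()) is None

    def test_two_ambiguous_variants_suffice(self):
        v1 = _gv(10, father=1, mother=1, proband=1)
        v2 = _gv(20, father=1, mother=1, proband=1)
        gv = [(v, _ann(v)) for v in (v1, v2)]
        call = classify_gene_recessive(gv, _ped())
        assert call is not None and call.mode == COMPOUND_HET
        assert all(o == "both" for _k, o in call.supporting_variants)

    def test_phase_contradiction_raises(self):
        v1 = _gv(10, mother=1, proband=1)
        v2 = _gv(20, father=1, proband=1)
        # place both alternates on the same phased haplotype
        for v in (v1, v2):
            calls = dict(v.calls)
            calls[PRO] = GenotypeCall((1, 0), depth=35, quality=99.0,
                                      phased=True)
            v.calls.update(calls)
        gv = [(v, _ann(v)) for v in (v1, v2)]
        with pytest.raises(DataError, match="phase"):
            classify_gene_recessive(gv, _ped())


class TestHomozygousRecessive:
    def test_worked_example_sister_het_retained(self):
        v = _gv(10, father=1, mother=1, proband=2, sister=1)
        call = classify_gene_recessive([(v, _ann(v, gene="SIK1"))], _ped())
        assert call is not None and call.mode == HOM_RECESSIVE
        assert call.supporting_variants == ((v.variant_key, "both"),)

    def test_sibling_homozygote_voids(self):
        v = _gv(10, father=1, mother=1, proband=2, brother=2)
        assert classify_gene_recessive([(v, _ann(v))], _ped()) is None

    def test_parent_homref_blocks(self):
        v = _gv(10, father=0, mother=1, proband=2)
        assert classify_gene_recessive([(v, _ann(v))], _ped()) is None


class TestXLinked:
    def test_male_proband_maternal_carrier_retained(self):
        v = _gv(10, chrom="X", ploidy_male=1, mother=1, proband=1, sister=1)
        call = classify_x_linked([(v, _ann(v, gene="ELF4"))], _ped())
        assert call is not None and call.mode == X_LINKED
        assert call.sibling_exclusion[SIS] == "consistent"

    def test_hemizygous_brother_voids(self):
        v = _gv(10, chrom="X", ploidy_male=1, mother=1, proband=1, brother=1)
        assert classify_x_linked([(v, _ann(v))], _ped()) is None

    def test_carrier_father_blocks(self):
        v = _gv(10, chrom="X", ploidy_male=1, father=1, mother=1, proband=1)
        assert classify_x_linked([(v, _ann(v))], _ped()) is None

    def test_unknown_proband_sex_errors(self):
        members = [
            PedigreeMember(F, None, None, MALE, UNAFFECTED),
            PedigreeMember(M, None, None, FEMALE, UNAFFECTED),
            PedigreeMember(PRO, F, M, "unknown", AFFECTED),
        ]
        ped = Pedigree(members=members, proband_id=PRO)
        v = _gv(10, chrom="X", ploidy_male=1, mother=1, proband=1)
        with pytest.raises(DataError, match="sex"):
            classify_x_linked([(v, _ann(v))], ped)


@pytest.mark.parametrize("consequence,pli,expected", [
    ("frameshift", 0.99, True),
    ("frameshift", 0.75, False),  # strict boundary
    ("stop_gain", 0.2, False),
    ("missense", 0.99, False),
    ("stop_loss", 0.9, True),
])
def test_inherited_lof_retention(consequence, pli, expected):
    v = _gv(10, father=1, proband=1)
    assert inherited_lof_retention(
        _ann(v, consequence=consequence, pli=pli)) is expected


def test_inherited_lof_missing_pli_warns(caplog):
    v = _gv(10, father=1, proband=1)
    with caplog.at_level("WARNING"):
        assert not inherited_lof_retention(_ann(v, consequence="frameshift"))
    assert "pLI" in caplog.text


class TestCascade:
    def test_audit_conservation(self, study_inputs):
        """Every input variant appears exactly once in the audit table."""
        variants, annotations, pedigree = study_inputs
        _calls, audit = run_family_cascade(variants, pedigree, annotations)
        assert len(audit) == len(variants)
        assert audit["variant"].is_unique

    def test_empty_input_gives_empty_calls_and_audit(self, quintet):
        calls, audit = run_family_cascade([], quintet, {})
        assert calls == [] and audit.empty

    def test_sibling_monotonicity(self):
        """Adding an unaffected sibling can only remove calls, never add."""
        for seed in range(20):
            variants, annotations, ped5, _gene = syn.simulate_quintet(
                COMPOUND_HET, seed)
            trio = Pedigree(
                members=[m for m in ped5.members
                         if m.sample_id in (F, M, PRO)],
                proband_id=PRO)
            calls5, _ = run_family_cascade(variants, ped5, annotations)
            calls3, _ = run_family_cascade(variants, trio, annotations)
            genes5 = {(c.gene, c.mode) for c in calls5}
            genes3 = {(c.gene, c.mode) for c in calls3}
            assert genes5 <= genes3

    @pytest.mark.parametrize("mode", [DE_NOVO, HOM_RECESSIVE, COMPOUND_HET,
                                      X_LINKED])
    def test_planted_mode_recovered(self, mode):
        variants, annotations, ped, gene = syn.simulate_quintet(mode, seed=11)
        calls, _ = run_family_cascade(variants, ped, annotations)
        assert {(c.gene, c.mode) for c in calls} == {(gene, mode)}
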