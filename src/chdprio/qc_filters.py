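"""Genotype- and site-level quality control.

Two rule sets live here.  The family rules gate the quintet prioritization
cascade: per-sample read depth >= 10, no adjacent homopolymer run longer than
five bases, and presence in fewer than 5 of 147 internal whole-exome datasets.
The cohort rules gate the case-control burden analysis: sites must PASS the
upstream variant-quality recalibration filter, genotypes with GQ < 20 are
masked, sites with call rate < 0.95 or an exact Hardy-Weinberg p-value below
1e-8 are excluded.

The Hardy-Weinberg test is the conditional exact test (two-sided,
probability-ordering definition): given the observed allele counts, the
p-value sums the probabilities of all heterozygote counts whose conditional
probability does not exceed that of the observed table.  A large-sample
chi-square variant is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

from chdprio.errors import ConfigError, DataError
from chdprio.genomic_io import GenotypedVariant, fetch_flank


@dataclass(frozen=True)
class FamilyQCConfig:
    min_depth: int = 10
    homopolymer_max_run: int = 5
    internal_cohort_max_count: int = 5
    internal_cohort_size: int = 147
    #: strict mode treats a missing DP/GQ field as failing the threshold
    missing_qc: str = "strict"

    def __post_init__(self):
        for name in ("min_depth", "homopolymer_max_run",
                     "internal_cohort_max_count", "internal_cohort_size"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.missing_qc not in ("strict", "permissive"):
            raise ConfigError("missing_qc must be 'strict' or 'permissive'")


@dataclass(frozen=True)
class CohortQCConfig:
    min_gq: float = 20.0
    min_call_rate: float = 0.95
    min_hwe_p: float = 1e-8
    require_pass_filter: bool = True
    #: compute HWE on "all" samples or "controls" only
    hwe_samples: str = "all"

    def __post_init__(self):
        if not 0.0 < self.min_call_rate <= 1.0:
            raise ConfigError("min_call_rate must be in (0,1]")
        if not 0.0 < self.min_hwe_p < 1.0:
            raise ConfigError("min_hwe_p must be in (0,1)")
        if self.hwe_samples not in ("all", "controls"):
            raise ConfigError("hwe_samples must be 'all' or 'controls'")


@dataclass(frozen=True)
class GenotypeCounts:
    n_hom_ref: int
    n_het: int
    n_hom_alt: int

    def __post_init__(self):
        if min(self.n_hom_ref, self.n_het, self.n_hom_alt) < 0:
            raise DataError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt

    @property
    def n_alt_alleles(self) -> int:
        return self.n_het + 2 * self.n_hom_alt


# ---------------------------------------------------------------------------
# Family filters
# ---------------------------------------------------------------------------


def depth_filter(variant: GenotypedVariant, samples: Sequence[str],
                 config: FamilyQCConfig) -> bool:
    """True iff every listed sample's read depth is at least ``min_depth``."""
    for s in samples:
        call = variant.calls.get(s)
        if call is None:
            raise DataError(f"sample {s!r} has no call at {variant.key_str}")
        if not call.depth_available:
            if config.missing_qc == "strict":
                return False
            continue
        if call.depth < config.min_depth:
            return False
    return True


def _run_length_inward(seq: str, from_left: bool) -> int:
    """Length of the maximal single-base run at the variant-adjacent end."""
    if not seq:
        return 0
    s = seq[::-1] if from_left else seq
    base = s[0]
    n = 0
    for c in s:
        if c != base:
            break
        n += 1
    return n


def homopolymer_adjacent(variant: GenotypedVariant, reference,
                         config: FamilyQCConfig) -> bool:
    """True (variant *fails*) iff a run of identical bases longer than
    ``homopolymer_max_run`` immediately flanks the variant's reference span.

    The run is anchored at the base immediately left or right of the span and
    may not include the variant bases themselves.
    """
    window = config.homopolymer_max_run + 2
    left, right = fetch_flank(reference, variant.chrom, variant.pos, window,
                              ref_len=len(variant.ref))
    return (_run_length_inward(left, from_left=True) > config.homopolymer_max_run
            or _run_length_inward(right, from_left=False) > config.homopolymer_max_run)


def internal_cohort_filter(annotation, config: FamilyQCConfig) -> bool:
    """True iff the variant appears in fewer than ``internal_cohort_max_count``
    internal whole-exome datasets."""
    return annotation.internal_cohort_count < config.internal_cohort_max_count


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def _hwe_log_probs(n: int, n_alt: int) -> tuple:
    """Conditional log-probabilities of every attainable heterozygote count.

    Returns (het_counts, log_probs) for all het counts h with the parity of
    ``n_alt`` and h <= min(n_alt, 2n - n_alt), normalized to sum to 1.
    """
    n_ref = 2 * n - n_alt
    h_max = min(n_alt, n_ref)
    hs = np.arange(n_alt % 2, h_max + 1, 2)
    hom_alt = (n_alt - hs) // 2
    hom_ref = n - hs - hom_alt
    logp = (
        gammaln(n + 1)
        - gammaln(hom_ref + 1) - gammaln(hs + 1) - gammaln(hom_alt + 1)
        + hs * np.log(2.0)
        + gammaln(n_alt + 1) + gammaln(n_ref + 1) - gammaln(2 * n + 1)
    )
    logp -= _logsumexp(logp)
    return hs, logp


def _logsumexp(x: np.ndarray) -> float:
    m = np.max(x)
    return m + np.log(np.sum(np.exp(x - m)))


def hwe_exact_p(counts: GenotypeCounts) -> float:
    """Two-sided conditional exact Hardy-Weinberg p-value.

    Sums the probabilities of all heterozygote counts no more probable than
    the observed one, conditional on the observed allele counts.
    """
    n = counts.n
    if n < 1:
        raise DataError("HWE test requires at least one genotype")
    n_alt = counts.n_alt_alleles
    if n_alt == 0 or n_alt == 2 * n:
        return 1.0  # monomorphic: single attainable configuration
    hs, logp = _hwe_log_probs(n, n_alt)
    obs = np.flatnonzero(hs == counts.n_het)
    if obs.size != 1:
        raise DataError(
            f"heterozygote count {counts.n_het} unattainable for "
            f"n={n}, alt alleles={n_alt}")
    lp_obs = logp[obs[0]]
    # probability-ordering: include tables with P <= P_obs (float-safe margin)
    p = float(np.sum(np.exp(logp[logp <= lp_obs + 1e-10])))
    return min(1.0, p)


def hwe_chisq_p(counts: GenotypeCounts) -> float:
    """Large-sample one-df chi-square Hardy-Weinberg p-value (comparison aid)."""
    n = counts.n
    if n < 1:
        raise DataError("HWE test requires at least one genotype")
    q = counts.n_alt_alleles / (2 * n)
    if q in (0.0, 1.0):
        return 1.0
    exp = np.array([n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q ** 2])
    obs = np.array([counts.n_hom_ref, counts.n_het, counts.n_hom_alt])
    stat = float(np.sum((obs - exp) ** 2 / exp))
    return float(chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# Cohort site QC
# ---------------------------------------------------------------------------


def mask_low_gq(variant: GenotypedVariant, config: CohortQCConfig) -> GenotypedVariant:
    """Set calls with genotype quality below ``min_gq`` to missing (idempotent)."""
    from chdprio.genomic_io import MISSING_DIPLOID
    new_calls = {}
    for s, call in variant.calls.items():
        if call.is_missing:
            new_calls[s] = call
            continue
        gq_ok = call.quality_available and call.quality >= config.min_gq
        new_calls[s] = call if gq_ok else MISSING_DIPLOID
    return variant.with_calls(new_calls)


def site_call_rate(variant: GenotypedVariant, config: CohortQCConfig) -> float:
    """Fraction of non-missing calls after GQ masking."""
    if not variant.calls:
        raise DataError(f"no samples at {variant.key_str}")
    masked = mask_low_gq(variant, config)
    n_called = sum(1 for c in masked.calls.values() if not c.is_missing)
    return n_called / len(masked.calls)


def genotype_counts(variant: GenotypedVariant,
                    samples: Optional[Iterable[str]] = None) -> GenotypeCounts:
    """Tabulate diploid genotype classes (hemizygous/missing calls skipped)."""
    ids = list(samples) if samples is not None else list(variant.calls)
    a = b = c = 0
    for s in ids:
        call = variant.calls[s]
        if call.is_missing or call.ploidy != 2:
            continue
        if call.is_hom_ref:
            a += 1
        elif call.is_het:
            b += 1
        elif call.is_hom_alt:
            c += 1
    return GenotypeCounts(a, b, c)


def cohort_site_qc(variant: GenotypedVariant, config: CohortQCConfig,
                   control_ids: Optional[Sequence[str]] = None) -> tuple:
    """Apply the cohort site filters in order; return (keep, reason).

    Order: PASS requirement, GQ masking, call rate, Hardy-Weinberg exact test
    on the remaining genotypes.  ``reason`` is None when the site is kept,
    otherwise the first failing rule ("filter", "call_rate", "hwe").
    """
    if config.require_pass_filter and variant.filter_status not in ("PASS", "."):
        return False, "filter"
    masked = mask_low_gq(variant, config)
    n_called = sum(1 for c in masked.calls.values() if not c.is_missing)
    rate = n_called / len(masked.calls) if masked.calls else 0.0
    if rate < config.min_call_rate:
        return False, "call_rate"
    ids = control_ids if config.hwe_samples == "controls" else None
    counts = genotype_counts(masked, ids)
    if counts.n >= 1 and hwe_exact_p(counts) < config.min_hwe_p:
        return False, "hwe"
    return True, None


def qc_audit_row(variant: GenotypedVariant, config: CohortQCConfig) -> dict:
    """Per-variant QC audit record for the traceability table."""
    keep, reason = cohort_site_qc(variant, config)
    return {
        "variant": variant.key_str,
        "filter_status": variant.filter_status,
        "call_rate": site_call_rate(variant, config),
        "keep": keep,
        "fail_reason": reason or "",
    }
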