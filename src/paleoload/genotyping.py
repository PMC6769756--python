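"""Genotype likelihoods from allele read counts and strict homozygous calling.

The per-read model is the classic one used by GATK-style callers: a read
with base ``b`` has probability ``1 - e`` of matching its template allele
and ``e/3`` of being each of the other three bases; for a diploid genotype
``{A1, A2}`` the read probability is the even mixture
``0.5*P(b|A1) + 0.5*P(b|A2)``.  Likelihoods are evaluated for the three
genotypes of the biallelic site and normalised to sum to one (a flat-prior
posterior).  A site is *called* only when the most likely genotype is
homozygous and its normalised likelihood strictly exceeds the call
threshold (default 0.99); it is *masked* otherwise, because the phenotypic
effect of a deleterious allele in the heterozygous state depends on its
unknown mode of inheritance.

Read-level quality filtering (mapping quality, base quality, proper
pairing) is assumed to have happened upstream of the counts input.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Tuple

import numpy as np
from scipy.special import logsumexp

MASKED = "MASKED"

#: reason codes for per-site calls
REASON_OK = "ok"
REASON_BELOW = "below_threshold"
REASON_HET = "heterozygous"
REASON_NODATA = "no_data"

# integer genotype codes used by the matrix caller
GENO_HOM_MAJOR = 0
GENO_HET = 1
GENO_HOM_DEL = 2
GENO_MASKED = -1

_REASON_CODES = {0: REASON_OK, 1: REASON_BELOW, 2: REASON_HET, 3: REASON_NODATA}


@dataclass(frozen=True)
class GenotypeCall:
    genotype: Optional[Tuple[str, str]]  # None == masked
    norm_likelihoods: dict  # genotype tuple -> normalised likelihood
    reason: str


def genotype_likelihoods(
    base_counts: Mapping[str, int], alleles: Tuple[str, str], error_rate: float
) -> dict:
    """Normalised genotype likelihoods over the three biallelic genotypes.

    ``base_counts`` tallies observed read bases (any of ACGT); reads
    matching neither allele contribute error probability symmetrically to
    every candidate genotype.  With zero reads the three genotypes are
    returned uniform.
    """
    if not (0.0 <= error_rate < 0.75):
        raise ValueError("error rate must lie in [0, 0.75)")
    a1, a2 = alleles
    genotypes = [(a1, a1), (a1, a2), (a2, a2)]
    total = sum(base_counts.values())
    if total == 0:
        return {g: 1.0 / 3.0 for g in genotypes}
    e = error_rate
    loglik = np.zeros(3)
    for base, count in base_counts.items():
        if count == 0:
            continue
        for k, (g1, g2) in enumerate(genotypes):
            p1 = 1.0 - e if base == g1 else e / 3.0
            p2 = 1.0 - e if base == g2 else e / 3.0
            p = 0.5 * p1 + 0.5 * p2
            loglik[k] += count * np.log(p) if p > 0 else -np.inf
    norm = np.exp(loglik - logsumexp(loglik))
    return {g: float(x) for g, x in zip(genotypes, norm)}


def call_genotype(norm_likelihoods: Mapping, call_threshold: float = 0.99) -> GenotypeCall:
    """Call the most likely genotype if homozygous and above threshold.

    Masks with reason ``heterozygous`` when the maximum-likelihood genotype
    is heterozygous, ``below_threshold`` when a homozygous winner does not
    strictly exceed the threshold, and ``no_data`` on uniform likelihoods
    from zero reads.
    """
    probs = dict(norm_likelihoods)
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("likelihoods must be normalised")
    if len(set(np.round(list(probs.values()), 12))) == 1:
        return GenotypeCall(None, probs, REASON_NODATA)
    best = max(sorted(probs), key=lambda g: probs[g])
    if best[0] != best[1]:
        return GenotypeCall(None, probs, REASON_HET)
    if probs[best] <= call_threshold:
        return GenotypeCall(None, probs, REASON_BELOW)
    return GenotypeCall(best, probs, REASON_OK)


def call_matrix(
    acm,
    error_rate: float = 0.005,
    call_threshold: float = 0.99,
    strict: bool = True,
):
    """Vectorised genotype calling over an :class:`AlleleCountMatrix`.

    The counts input records deleterious-allele support ``r`` and depth
    ``d``; the ``d - r`` remaining reads are treated as the major allele.
    Returns ``(genotypes, reasons, probs)``: genotype codes (0 hom-major,
    1 het, 2 hom-deleterious, -1 masked), integer reason codes indexing
    :data:`_REASON_CODES`, and the (n_samples, n_sites, 3) normalised
    likelihood array.

    With ``strict=False`` the maximum-likelihood genotype is reported for
    every covered cell (no homozygosity or threshold masking) — used by
    analyses that need heterozygote indicators rather than the
    conservative load-calling protocol.
    """
    if not (0.0 <= error_rate < 0.75):
        raise ValueError("error rate must lie in [0, 0.75)")
    from scipy.special import xlogy

    r = np.asarray(acm.r, dtype=float)
    d = np.asarray(acm.d, dtype=float)
    m = d - r
    e = error_rate
    # per-read probabilities of a deleterious-base read under each genotype;
    # xlogy keeps 0*log(0) = 0 so e = 0 stays exact
    p_err = e / 3.0
    p_het = 0.5 * (1.0 - e) + 0.5 * p_err
    ll = np.stack(
        [
            xlogy(r, p_err) + xlogy(m, 1.0 - e),
            xlogy(r + m, p_het),
            xlogy(r, 1.0 - e) + xlogy(m, p_err),
        ],
        axis=-1,
    )
    ll = np.where(np.isneginf(ll), -1e300, ll)
    probs = np.exp(ll - logsumexp(ll, axis=-1, keepdims=True))
    argmax = np.argmax(probs, axis=-1)
    pmax = np.take_along_axis(probs, argmax[..., None], axis=-1)[..., 0]

    no_data = d == 0
    probs[no_data] = 1.0 / 3.0

    genotypes = argmax.astype(np.int8)
    reasons = np.zeros(genotypes.shape, dtype=np.int8)
    if strict:
        het = genotypes == GENO_HET
        below = (~het) & (pmax <= call_threshold)
        genotypes[het | below | no_data] = GENO_MASKED
        reasons[below] = 1
        reasons[het] = 2
    else:
        genotypes[no_data] = GENO_MASKED
    reasons[no_data] = 3
    return genotypes, reasons, probs


def masked_fraction(genotypes: np.ndarray) -> np.ndarray:
    """Per-sample fraction of masked sites (diagnostic)."""
    return (genotypes == GENO_MASKED).mean(axis=1)


def reason_name(code: int) -> str:
    return _REASON_CODES[int(code)]
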