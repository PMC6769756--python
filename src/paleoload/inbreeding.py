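"""Inbreeding coefficients, IBD tracts, LD pruning and the purging proxy.

Inbreeding is estimated from per-site heterozygosity indicators with a
two-state hidden Markov model along each chromosome.  In the outbred
state a site is heterozygous with its Hardy-Weinberg probability
``2p(1-p)`` (attenuated by a genotyping-error leak ``eps``); in the
identical-by-descent (IBD) state heterozygotes arise only through error or
recent mutation, at rate ``eps``.  Transitions between the states over a
physical gap ``g`` follow a reversible exponential kernel with one rate
parameter and stationary IBD probability ``F``:

    P(i -> j | g) = pi_j * (1 - exp(-rate * g)) + delta_ij * exp(-rate * g).

``(F, rate, eps)`` are fit by expectation-maximisation with a numerically
maximised M-step, so the observed-data likelihood is non-decreasing across
iterations; convergence is declared when the largest parameter change
drops below ``em_epsilon``.  IBD tracts come from posterior decoding
(state probability > 0.5).

Sites are first reduced to approximate linkage equilibrium: r-squared is
computed for SNP pairs closer than 50 Kb, linked pairs are clustered into
blocks (connected components of the r-squared graph), and the most central
SNP — highest degree, leftmost position on ties — represents each block.

Genetic purging is quantified by the dN-dS proxy: the mismatch fraction of
a (pseudo-haploid) genome against an outgroup at constrained sites (dN)
minus the same at neutral sites (dS).  Strong negative selection removes
derived alleles at constrained sites, driving dN-dS negative; relaxed
selection lets dN approach dS.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy.optimize import minimize

from .loadstats import spearman


# ---------------------------------------------------------------------------
# closed-form demography helpers


def effective_population_size(n_males: float, n_females: float) -> float:
    """Effective population size of a breeding stock with unequal sex
    contributions: ``Ne = 4*Nm*Nf / (Nm + Nf)``.

    A stud of 20 stallions and 5000 mares has Ne ≈ 80 despite its census
    size — the arithmetic behind recent bottleneck-driven load bursts.
    """
    if n_males <= 0 or n_females <= 0:
        raise ValueError("breeding numbers must be positive")
    return 4.0 * n_males * n_females / (n_males + n_females)


def log2_tract_to_kb(log2_length: float) -> float:
    """Convert a log2-scaled tract length to kilobases (rounded).

    Tract-length distributions are reported on a log2(bp) axis; a value of
    18 corresponds to 2^18 bp = 262 Kb, 24 to 16 Mb.
    """
    return round(2.0 ** log2_length / 1000.0)


# ---------------------------------------------------------------------------
# dN - dS purging proxy


@dataclass(frozen=True)
class DivergenceEstimate:
    sample_id: str
    dn: float
    ds: float
    n_constrained: int
    n_neutral: int

    @property
    def dn_minus_ds(self) -> float:
        return self.dn - self.ds


def dn_ds(
    hap_individual: np.ndarray,
    hap_outgroup: np.ndarray,
    constrained_mask: np.ndarray,
    neutral_mask: np.ndarray,
    sample_id: str = "",
) -> DivergenceEstimate:
    """Divergence to the outgroup at constrained (dN) vs neutral (dS) sites.

    Inputs are haploid allele codes with -1 for missing; a site contributes
    only when both genomes are called.  Raises when either comparable set
    is empty.
    """
    hap_individual = np.asarray(hap_individual)
    hap_outgroup = np.asarray(hap_outgroup)
    ok = (hap_individual >= 0) & (hap_outgroup >= 0)
    rates = {}
    ns = {}
    for name, mask in (("dn", constrained_mask), ("ds", neutral_mask)):
        m = np.asarray(mask) & ok
        ns[name] = int(m.sum())
        if ns[name] == 0:
            raise ValueError(f"no comparable sites for {name}")
        rates[name] = float((hap_individual[m] != hap_outgroup[m]).mean())
    return DivergenceEstimate(
        sample_id=sample_id,
        dn=rates["dn"],
        ds=rates["ds"],
        n_constrained=ns["dn"],
        n_neutral=ns["ds"],
    )


# ---------------------------------------------------------------------------
# LD pruning


def missingness_filter(dosage: np.ndarray, max_missing_frac: float = 0.10) -> np.ndarray:
    """Mask of sites whose missing fraction is at most ``max_missing_frac``."""
    dosage = np.asarray(dosage)
    frac = (dosage < 0).mean(axis=0)
    return frac <= max_missing_frac


def ld_r2_pairs(
    dosage: np.ndarray,
    positions: np.ndarray,
    chroms: np.ndarray,
    max_dist_bp: int = 50_000,
) -> list:
    """Squared dosage correlation for same-chromosome SNP pairs closer than
    ``max_dist_bp``.

    Missing genotypes (negative codes) are dropped pairwise; monomorphic
    sites yield no pairs.  Returns ``[(i, j, r2), ...]`` with site indices
    into the input arrays.
    """
    dosage = np.asarray(dosage, dtype=float)
    positions = np.asarray(positions)
    chroms = np.asarray(chroms)
    n_sites = dosage.shape[1]
    pairs = []
    for i in range(n_sites):
        j = i + 1
        while (
            j < n_sites
            and chroms[j] == chroms[i]
            and positions[j] - positions[i] < max_dist_bp
        ):
            gi, gj = dosage[:, i], dosage[:, j]
            ok = (gi >= 0) & (gj >= 0)
            if ok.sum() >= 2:
                a, b = gi[ok], gj[ok]
                if a.std() > 0 and b.std() > 0:
                    r = np.corrcoef(a, b)[0, 1]
                    pairs.append((i, j, float(r * r)))
            j += 1
    return pairs


def cluster_ld_blocks(
    pairs: Sequence[Tuple[int, int, float]],
    positions: np.ndarray,
    r2_threshold: float = 0.2,
) -> Tuple[list, np.ndarray]:
    """Cluster linked SNPs and pick one representative per block.

    Pairs with r² at or above the threshold become graph edges; connected
    components are blocks; the representative is the highest-degree node,
    ties broken by leftmost position.  Sites involved in no retained edge
    are their own singleton blocks.  Returns ``(blocks, representatives)``.
    """
    positions = np.asarray(positions)
    graph = nx.Graph()
    graph.add_nodes_from(range(len(positions)))
    for i, j, r2 in pairs:
        if r2 >= r2_threshold:
            graph.add_edge(i, j)
    blocks = []
    reps = []
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        rep = min(members, key=lambda k: (-graph.degree[k], positions[k]))
        blocks.append(members)
        reps.append(rep)
    order = np.argsort([positions[r] for r in reps], kind="stable")
    blocks = [blocks[k] for k in order]
    reps = np.array([reps[k] for k in order], dtype=int)
    return blocks, reps


# ---------------------------------------------------------------------------
# two-state IBD HMM


@dataclass
class IBDResult:
    sample_id: str
    f: float  # genome fraction IBD (mean posterior occupancy)
    f_stationary: float  # fitted stationary IBD probability
    rate: float  # transition kernel rate (1/bp)
    eps: float  # heterozygote leak in the IBD state
    tracts: list  # (chrom, start_bp, end_bp)
    em_iterations: int
    converged: bool
    loglik: float
    loglik_path: list = field(default_factory=list)
    posterior_ibd: Optional[np.ndarray] = None


def _transition_probs(gaps: np.ndarray, f: float, rate: float):
    """Per-step 2x2 transition matrices for the exponential distance kernel.

    Returns arrays (a00, a01, a10, a11) aligned with ``gaps``; an infinite
    gap (chromosome break) resets the chain to its stationary law.
    """
    decay = np.exp(-rate * gaps)
    decay = np.where(np.isfinite(gaps), decay, 0.0)
    a00 = (1.0 - f) * (1.0 - decay) + decay
    a01 = f * (1.0 - decay)
    a10 = (1.0 - f) * (1.0 - decay)
    a11 = f * (1.0 - decay) + decay
    return a00, a01, a10, a11


def _emissions(het: np.ndarray, freqs: np.ndarray, eps: float):
    """P(observation | state) per site: columns (non-IBD, IBD)."""
    hw = 2.0 * freqs * (1.0 - freqs)
    p_het_out = hw * (1.0 - eps) + (1.0 - hw) * eps
    p_het_ibd = eps
    e_out = np.where(het == 1, p_het_out, 1.0 - p_het_out)
    e_ibd = np.where(het == 1, p_het_ibd, 1.0 - p_het_ibd)
    return np.stack([e_out, e_ibd], axis=1)


def _forward_backward(emit: np.ndarray, gaps: np.ndarray, f: float, rate: float):
    """Scaled forward-backward pass.

    Returns ``(loglik, gamma, xi_stats)`` where ``gamma`` is the (n, 2)
    posterior and ``xi_stats`` the (n-1, 4) expected transition counts
    (00, 01, 10, 11) per step, for the M-step.
    """
    n = emit.shape[0]
    a00, a01, a10, a11 = _transition_probs(gaps, f, rate)
    pi0, pi1 = 1.0 - f, f

    e0 = emit[:, 0].tolist()
    e1 = emit[:, 1].tolist()
    t00, t01, t10, t11 = a00.tolist(), a01.tolist(), a10.tolist(), a11.tolist()

    alpha0 = [0.0] * n
    alpha1 = [0.0] * n
    scale = [0.0] * n
    a0 = pi0 * e0[0]
    a1 = pi1 * e1[0]
    c = a0 + a1
    alpha0[0], alpha1[0], scale[0] = a0 / c, a1 / c, c
    for t in range(1, n):
        p0, p1 = alpha0[t - 1], alpha1[t - 1]
        a0 = (p0 * t00[t - 1] + p1 * t10[t - 1]) * e0[t]
        a1 = (p0 * t01[t - 1] + p1 * t11[t - 1]) * e1[t]
        c = a0 + a1
        if c <= 0.0:
            c = 1e-300
        alpha0[t], alpha1[t], scale[t] = a0 / c, a1 / c, c

    beta0 = [1.0] * n
    beta1 = [1.0] * n
    for t in range(n - 2, -1, -1):
        b0n, b1n = beta0[t + 1], beta1[t + 1]
        e0n, e1n = e0[t + 1], e1[t + 1]
        c = scale[t + 1]
        beta0[t] = (t00[t] * e0n * b0n + t01[t] * e1n * b1n) / c
        beta1[t] = (t10[t] * e0n * b0n + t11[t] * e1n * b1n) / c

    alpha = np.stack([np.array(alpha0), np.array(alpha1)], axis=1)
    beta = np.stack([np.array(beta0), np.array(beta1)], axis=1)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    # expected transition counts, vectorised
    if n > 1:
        sc = np.array(scale[1:])
        xi00 = alpha[:-1, 0] * a00 * emit[1:, 0] * beta[1:, 0] / sc
        xi01 = alpha[:-1, 0] * a01 * emit[1:, 1] * beta[1:, 1] / sc
        xi10 = alpha[:-1, 1] * a10 * emit[1:, 0] * beta[1:, 0] / sc
        xi11 = alpha[:-1, 1] * a11 * emit[1:, 1] * beta[1:, 1] / sc
        xi = np.stack([xi00, xi01, xi10, xi11], axis=1)
        norm = xi.sum(axis=1, keepdims=True)
        xi = xi / np.maximum(norm, 1e-300)
    else:
        xi = np.zeros((0, 4))
    loglik = float(np.log(np.array(scale)).sum())
    return loglik, gamma, xi


def _m_step(gamma, xi, gaps, het, freqs, theta0):
    """Maximise the expected complete-data log-likelihood over
    (F, rate, eps), parameterised on unconstrained scales."""
    hw = 2.0 * freqs * (1.0 - freqs)
    het = np.asarray(het, dtype=float)

    def unpack(z):
        f = 1.0 / (1.0 + math.exp(-z[0]))
        rate = math.exp(z[1])
        eps = 1.0 / (1.0 + math.exp(-z[2]))
        return f, rate, eps

    def neg_q(z):
        f, rate, eps = unpack(z)
        f = min(max(f, 1e-9), 1.0 - 1e-9)
        eps = min(max(eps, 1e-12), 0.5)
        a00, a01, a10, a11 = _transition_probs(gaps, f, rate)
        trans = (
            xi[:, 0] * np.log(np.maximum(a00, 1e-300))
            + xi[:, 1] * np.log(np.maximum(a01, 1e-300))
            + xi[:, 2] * np.log(np.maximum(a10, 1e-300))
            + xi[:, 3] * np.log(np.maximum(a11, 1e-300))
        ).sum()
        p_het_out = hw * (1.0 - eps) + (1.0 - hw) * eps
        l_out = np.where(het == 1, np.log(p_het_out), np.log1p(-p_het_out))
        l_ibd = np.where(het == 1, math.log(eps), math.log1p(-eps))
        emit = (gamma[:, 0] * l_out + gamma[:, 1] * l_ibd).sum()
        start = gamma[0, 0] * math.log(1.0 - f) + gamma[0, 1] * math.log(f)
        return -(trans + emit + start)

    f0, rate0, eps0 = theta0
    z0 = np.array(
        [
            math.log(f0 / (1.0 - f0)),
            math.log(rate0),
            math.log(eps0 / (1.0 - eps0)),
        ]
    )
    res = minimize(neg_q, z0, method="L-BFGS-B")
    z = res.x if res.fun <= neg_q(z0) else z0
    f, rate, eps = unpack(z)
    return (
        min(max(f, 1e-6), 1.0 - 1e-6),
        min(max(rate, 1e-12), 1.0),
        min(max(eps, 1e-9), 0.5),
    )


def fit_ibd_hmm(
    het: np.ndarray,
    positions: np.ndarray,
    chroms: np.ndarray,
    freqs: np.ndarray,
    em_epsilon: float = 1e-7,
    max_iter: int = 100,
    init: Optional[Tuple[float, float, float]] = None,
    sample_id: str = "",
) -> IBDResult:
    """Co-estimate the inbreeding coefficient and IBD tracts of one genome.

    Parameters
    ----------
    het : 0/1 heterozygosity indicators at LD-pruned sites (ordered by
        chromosome then position).
    positions, chroms : site coordinates; chromosome changes reset the
        Markov chain to its stationary law.
    freqs : population allele frequencies, strictly inside (0, 1).
    """
    het = np.asarray(het, dtype=np.int8)
    positions = np.asarray(positions, dtype=float)
    chroms = np.asarray(chroms)
    freqs = np.asarray(freqs, dtype=float)
    n = het.size
    if n < 2:
        raise ValueError("need at least two sites")
    if np.any(freqs <= 0.0) or np.any(freqs >= 1.0):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")

    gaps = np.diff(positions)
    gaps = np.where(chroms[1:] == chroms[:-1], np.maximum(gaps, 1.0), np.inf)

    if init is None:
        hw = 2.0 * freqs * (1.0 - freqs)
        f0 = 1.0 - het.mean() / max(hw.mean(), 1e-9)
        f0 = min(max(f0, 0.02), 0.95)
        init = (f0, 1.0 / 5e6, 1e-3)
    f, rate, eps = init

    loglik_path = []
    converged = False
    gamma = None
    it = 0
    for it in range(1, max_iter + 1):
        emit = _emissions(het, freqs, eps)
        loglik, gamma, xi = _forward_backward(emit, gaps, f, rate)
        loglik_path.append(loglik)
        new_f, new_rate, new_eps = _m_step(gamma, xi, gaps, het, freqs, (f, rate, eps))
        change = max(
            abs(new_f - f),
            abs(new_eps - eps),
            abs(math.log(new_rate) - math.log(rate)),
        )
        f, rate, eps = new_f, new_rate, new_eps
        if change < em_epsilon:
            converged = True
            break
    emit = _emissions(het, freqs, eps)
    loglik, gamma, _ = _forward_backward(emit, gaps, f, rate)
    loglik_path.append(loglik)

    post = gamma[:, 1]
    tracts = _decode_tracts(post, positions, chroms)
    return IBDResult(
        sample_id=sample_id,
        f=float(post.mean()),
        f_stationary=float(f),
        rate=float(rate),
        eps=float(eps),
        tracts=tracts,
        em_iterations=it,
        converged=converged,
        loglik=loglik,
        loglik_path=loglik_path,
        posterior_ibd=post,
    )


def _decode_tracts(posterior_ibd: np.ndarray, positions: np.ndarray, chroms: np.ndarray) -> list:
    """Posterior decoding (P(IBD) > 0.5) into merged tracts."""
    state = posterior_ibd > 0.5
    tracts = []
    start = None
    for k in range(len(state)):
        new_chrom = k > 0 and chroms[k] != chroms[k - 1]
        if state[k] and (start is None or new_chrom):
            if start is not None and new_chrom:
                tracts.append((str(chroms[k - 1]), int(start), int(positions[k - 1])))
            start = positions[k]
        elif not state[k] and start is not None:
            tracts.append((str(chroms[k - 1]), int(start), int(positions[k - 1])))
            start = None
    if start is not None:
        tracts.append((str(chroms[-1]), int(start), int(positions[-1])))
    return tracts


def correlate_load_inbreeding(
    loads: Sequence[float], f_values: Sequence[float], min_n: int = 5
) -> Tuple[float, float]:
    """Spearman correlation between per-individual load and inbreeding F.

    A strong positive correlation is the signature of inbreeding
    depression without purging; purging attenuates it.
    """
    loads = np.asarray(loads, dtype=float)
    f_values = np.asarray(f_values, dtype=float)
    ok = ~(np.isnan(loads) | np.isnan(f_values))
    if ok.sum() < min_n:
        raise ValueError(f"need at least {min_n} matched samples")
    return spearman(loads[ok], f_values[ok])
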