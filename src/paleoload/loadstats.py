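"""The phyloP-weighted mutational-load statistic and group comparisons.

The load of a genome over a set of positions is

    load = sum_i phyloP_i / n_hom

where ``i`` runs over the called-homozygous positions carrying the
deleterious allele with phyloP at or above the constraint threshold, and
``n_hom`` counts *all* called homozygous positions in the region set
(deleterious-carrying or not).  Masked sites enter neither term.  The
statistic is a per-homozygous-site average fitness-proxy burden: it rises
when inbreeding or drift exposes conserved-site derived alleles in the
homozygous state.
"""
from __future__ import annotations

from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import REGION_CLASSES
from .genotyping import GENO_HOM_DEL, GENO_HOM_MAJOR

GENOME_WIDE = "GENOME_WIDE"

#: breed -> group assignment used when metadata does not override it
BREED_GROUPS = {
    # traditional working / draft / farm breeds
    **{
        b: "working"
        for b in (
            "Jeju",
            "Shetland",
            "Icelandic",
            "Haflinger",
            "Percheron",
            "Noriker",
            "Friesian",
            "Marwari",
            "Sorraia",
            "Lipizzan",
            "FranchesMontagnes",
        )
    },
    **{b: "hotblood" for b in ("AkhalTeke", "Arabian", "Thoroughbred")},
    **{
        b: "warmblood"
        for b in (
            "Bavarian",
            "Oldenburger",
            "Wurtemberg",
            "Dutch",
            "Hanoverian",
            "Holsteiner",
            "Morgan",
            "AmericanPaint",
            "AmericanQuarter",
            "Standardbred",
            "Trakehner",
            "SwissWarmblood",
        )
    },
}


def compute_loads(
    genotypes: np.ndarray,
    sites: pd.DataFrame,
    samples: Sequence,
    region_filter: Optional[Iterable[str]] = None,
    phylop_threshold: float = 1.5,
    per_region: bool = True,
) -> pd.DataFrame:
    """Per-sample load estimates, per region class and genome-wide.

    ``genotypes`` is the (n_samples, n_sites) coded call matrix from
    :func:`paleoload.genotyping.call_matrix` (strict mode); ``sites`` the
    frame from :func:`paleoload.io.sites_to_frame`.  Samples with no called
    homozygous site in a region set get a missing (NaN) load, not zero.
    """
    if genotypes.shape != (len(samples), len(sites)):
        raise ValueError("genotype matrix not aligned to samples x sites")
    regions = (
        list(region_filter) if region_filter is not None else list(REGION_CLASSES)
    )
    hom = (genotypes == GENO_HOM_MAJOR) | (genotypes == GENO_HOM_DEL)
    eligible = (
        (sites["phylop"].to_numpy() >= phylop_threshold)
        & sites["deleterious_allele"].notna().to_numpy()
    )
    hom_del = (genotypes == GENO_HOM_DEL) & eligible[None, :]
    phylop = sites["phylop"].to_numpy()

    region_masks = {}
    if per_region:
        for rc in regions:
            region_masks[rc] = (sites["region_class"] == rc).to_numpy()
    region_masks[GENOME_WIDE] = np.isin(sites["region_class"].to_numpy(), regions)

    rows = []
    for rc, mask in region_masks.items():
        n_hom = hom[:, mask].sum(axis=1)
        n_del = hom_del[:, mask].sum(axis=1)
        sum_phylop = (hom_del[:, mask] * phylop[mask][None, :]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            load = np.where(n_hom > 0, sum_phylop / np.maximum(n_hom, 1), np.nan)
        for i, s in enumerate(samples):
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "region_class": rc,
                    "n_hom_total": int(n_hom[i]),
                    "n_hom_deleterious": int(n_del[i]),
                    "sum_phylop": float(sum_phylop[i]),
                    "load": float(load[i]) if n_hom[i] > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def breed_summary(loads: pd.DataFrame, samples: Sequence) -> pd.DataFrame:
    """Mean/median/range of loads per breed and region class.

    Breeds represented by fewer than three genomes are flagged
    ``low_confidence`` — with one or two genomes the within-breed range of
    load values is essentially unexplored.
    """
    breed_of = {s.sample_id: s.breed for s in samples}
    df = loads.copy()
    df["breed"] = df["sample_id"].map(lambda x: breed_of.get(x, "other"))
    out = (
        df.groupby(["breed", "region_class"])["load"]
        .agg(n="count", mean="mean", median="median", min="min", max="max")
        .reset_index()
    )
    out["low_confidence"] = out["n"] < 3
    return out


def group_compare(
    loads_a: Sequence[float],
    loads_b: Sequence[float],
    alternative: str = "two-sided",
) -> Tuple[float, float]:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney U) comparison of loads.

    Exact enumeration of labelings for small samples (total n <= 12, no
    ties); normal approximation with tie correction otherwise.  Returns
    ``(U, p)``; degenerate all-tied data gives p = 1.
    """
    a = np.asarray(loads_a, dtype=float)
    b = np.asarray(loads_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return len(a) * len(b) / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative=alternative, method=method, use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


def region_correlation(loads: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlation of per-sample loads across region classes.

    Ties receive average ranks; p-values use the t-approximation.  Pairs
    with a constant load vector yield a missing coefficient.
    """
    wide = loads[loads["region_class"] != GENOME_WIDE].pivot(
        index="sample_id", columns="region_class", values="load"
    )
    rows = []
    cols = list(wide.columns)
    for i, ra in enumerate(cols):
        for rb in cols[i + 1 :]:
            sub = wide[[ra, rb]].dropna()
            if len(sub) < 5:
                rho, p = np.nan, np.nan
            elif sub[ra].nunique() == 1 or sub[rb].nunique() == 1:
                rho, p = np.nan, np.nan
            else:
                rho, p = stats.spearmanr(sub[ra], sub[rb])
            rows.append(
                {"region_a": ra, "region_b": rb, "n": len(sub), "rho": rho, "p": p}
            )
    return pd.DataFrame(rows)


def spearman(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rank correlation (shared helper)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
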