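"""Temporal allele-frequency trajectories from ancient read counts.

Within a time bin the frequency of a deleterious allele is estimated by
maximum likelihood under a shared-frequency binomial model: with read
counts ``r_i`` out of depth ``d_i`` for the ``n`` individuals genotyped in
the bin,

    f = argmax_p  prod_i Binomial(r_i; d_i, p),

whose maximiser is the pooled ratio ``sum(r) / sum(d)``.  Samples are
binned in sliding 1000-year windows stepped every 250 years, a bin being
usable for a site only when at least ``min_bin_n`` individuals have data
there.  Trajectories are classified as *fixed* (every estimate >= 0.99),
*absent* (every estimate < 0.01) or *dynamic*; frequency shifts (the
|delta| statistic) are measured between non-overlapping 1000-year bins
centred at 3250, 2250, 1250 and 250 years before present so that adjacent
intervals do not share samples.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .datamodel import AlleleCountMatrix, Config

CLASS_FIXED = "fixed"
CLASS_ABSENT = "absent"
CLASS_DYNAMIC = "dynamic"
CLASS_UNCLASSIFIED = "unclassified"

#: non-overlapping 1000-year bin centres used for the delta statistic;
#: centre 0 is the modern panel, entering as its own bin at 0 BP
DELTA_CENTERS = (3250.0, 2250.0, 1250.0, 250.0, 0.0)


@dataclass(frozen=True)
class TimeBin:
    center_bp: float
    member_indices: tuple  # indices into the sample list

    @property
    def n_members(self) -> int:
        return len(self.member_indices)


def pooled_frequency(r: np.ndarray, d: np.ndarray) -> float:
    """Closed-form pooled-binomial MLE, ``sum(r) / sum(d)``."""
    total_d = float(np.sum(d))
    if total_d == 0:
        return np.nan
    return float(np.sum(r)) / total_d


def ml_frequency(r: Sequence[float], d: Sequence[float]) -> float:
    """Numerically maximised shared-frequency binomial likelihood.

    Individuals with zero depth are ignored; with no data at all the
    estimate is missing (NaN).  The bounded optimiser is polished with two
    Newton steps on the score function so the result agrees with the
    analytic maximiser to machine precision.
    """
    r = np.asarray(r, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(r < 0) or np.any(r > d):
        raise ValueError("need 0 <= r <= d elementwise")
    keep = d > 0
    r, d = r[keep], d[keep]
    if r.size == 0:
        return np.nan
    sr, sd = r.sum(), d.sum()
    if sr == 0.0:
        return 0.0
    if sr == sd:
        return 1.0

    def negloglik(p):
        return -(sr * np.log(p) + (sd - sr) * np.log1p(-p))

    res = minimize_scalar(
        negloglik, bounds=(1e-12, 1.0 - 1e-12), method="bounded",
        options={"xatol": 1e-12},
    )
    p = float(res.x)
    for _ in range(2):  # Newton polish on the score
        score = sr / p - (sd - sr) / (1.0 - p)
        info = sr / p**2 + (sd - sr) / (1.0 - p) ** 2
        p = min(max(p + score / info, 1e-15), 1.0 - 1e-15)
    return p


def ml_frequency_matrix(
    acm: AlleleCountMatrix,
    sample_indices: Sequence[int],
    min_bin_n: int = 1,
) -> np.ndarray:
    """Per-site pooled MLE over a sample subset, vectorised.

    A site's estimate is missing when fewer than ``min_bin_n`` of the
    subset's individuals are genotyped (depth > 0) there.
    """
    idx = np.asarray(sample_indices, dtype=int)
    if idx.size == 0:
        return np.full(acm.n_sites, np.nan)
    r = acm.r[idx].sum(axis=0).astype(float)
    d = acm.d[idx].sum(axis=0).astype(float)
    n_genotyped = (acm.d[idx] > 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(d > 0, r / np.maximum(d, 1.0), np.nan)
    f[n_genotyped < min_bin_n] = np.nan
    return f


def bin_samples(
    samples: Sequence,
    bin_width_years: float = 1000.0,
    bin_step_years: float = 250.0,
) -> list:
    """Sliding time bins over the ancient samples.

    Bin centres sit at multiples of the step; a sample of age ``a`` belongs
    to the bin centred at ``c`` when ``c - w/2 <= a < c + w/2`` (half-open,
    so a sample on the upper edge belongs to the next bin only).  Modern
    samples (age 0) are never binned here; they form their own panel.
    """
    ages = np.array([s.age_bp for s in samples])
    ancient = np.flatnonzero(ages > 0)
    if ancient.size == 0:
        return []
    half = bin_width_years / 2.0
    lo, hi = ages[ancient].min(), ages[ancient].max()
    first = max(1, int(np.floor((lo - half) / bin_step_years)) + 1)
    last = int(np.ceil((hi + half) / bin_step_years))
    bins = []
    for k in range(first, last + 1):
        c = k * bin_step_years
        members = ancient[(ages[ancient] >= c - half) & (ages[ancient] < c + half)]
        if members.size:
            bins.append(TimeBin(center_bp=float(c), member_indices=tuple(int(i) for i in members)))
    return bins


def classify_trajectory(
    f_hats: Sequence[float],
    fixed_threshold: float = 0.99,
    absent_threshold: float = 0.01,
) -> str:
    """Classify a trajectory from its available per-bin estimates."""
    f = np.asarray(f_hats, dtype=float)
    f = f[~np.isnan(f)]
    if f.size == 0:
        return CLASS_UNCLASSIFIED
    if np.all(f >= fixed_threshold):
        return CLASS_FIXED
    if np.all(f < absent_threshold):
        return CLASS_ABSENT
    return CLASS_DYNAMIC


def trajectory_table(
    acm: AlleleCountMatrix,
    config: Optional[Config] = None,
    transversions_only: bool = False,
    phylop_threshold: Optional[float] = None,
    include_modern: bool = True,
) -> pd.DataFrame:
    """Site x bin matrix of ML frequencies plus the trajectory class.

    Rows are the deleterious (constrained, assigned-allele) sites; columns
    ``f_<center>`` hold per-bin estimates (NaN where fewer than
    ``min_bin_n`` individuals were genotyped), ``f_modern`` the pooled
    modern-panel estimate.  ``transversions_only`` drops transition sites,
    the standard guard against post-mortem damage artefacts;
    ``phylop_threshold`` optionally restricts to more constrained sites.
    """
    cfg = config or Config()
    thr = cfg.phylop_threshold if phylop_threshold is None else phylop_threshold
    keep = np.array(
        [
            s.constrained
            and s.deleterious_allele is not None
            and s.phylop >= thr
            and (not transversions_only or s.mutation_class == "transversion")
            for s in acm.sites
        ]
    )
    sub = acm.subset_sites(keep)
    bins = bin_samples(sub.samples, cfg.bin_width_years, cfg.bin_step_years)
    data = {
        "chrom": [s.chrom for s in sub.sites],
        "pos": [s.pos for s in sub.sites],
        "phylop": [s.phylop for s in sub.sites],
        "mutation_class": [s.mutation_class for s in sub.sites],
    }
    fcols = []
    for b in bins:
        col = f"f_{int(b.center_bp)}"
        data[col] = ml_frequency_matrix(sub, b.member_indices, cfg.min_bin_n)
        fcols.append(col)
    if include_modern:
        modern = [i for i, s in enumerate(sub.samples) if not s.is_ancient]
        data["f_modern"] = ml_frequency_matrix(sub, modern, cfg.min_bin_n)
        fcols.append("f_modern")
    df = pd.DataFrame(data)
    fmat = df[fcols].to_numpy() if fcols else np.empty((len(df), 0))
    df["trajectory_class"] = [
        classify_trajectory(row, cfg.fixed_threshold, cfg.absent_threshold)
        for row in fmat
    ]
    return df


def delta_series(
    table: pd.DataFrame,
    centers: Sequence[float] = DELTA_CENTERS,
) -> pd.DataFrame:
    """Frequency shifts between consecutive non-overlapping bins.

    For each pair of adjacent centres (old -> young) the change is
    reported at the *younger* centre: ``delta = |f_young - f_old|`` with
    the signed value retained for the increase/decrease tally.  Missing
    when either bin estimate is missing.
    """
    def colname(center: float) -> str:
        return "f_modern" if center == 0 else f"f_{int(center)}"

    ordered = sorted(centers, reverse=True)  # old -> young
    rows = []
    for older, younger in zip(ordered[:-1], ordered[1:]):
        col_o, col_y = colname(older), colname(younger)
        if col_o not in table.columns or col_y not in table.columns:
            continue
        signed = table[col_y] - table[col_o]
        rows.append(
            pd.DataFrame(
                {
                    "chrom": table["chrom"],
                    "pos": table["pos"],
                    "center_bp": float(younger),
                    "delta": signed.abs(),
                    "signed_delta": signed,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["chrom", "pos", "center_bp", "delta", "signed_delta"]
        )
    return pd.concat(rows, ignore_index=True)


def pooled_comparison(
    acm: AlleleCountMatrix,
    config: Optional[Config] = None,
    transversions_only: bool = False,
) -> pd.DataFrame:
    """Mean deleterious-allele frequency in the pooled ancient vs pooled
    modern panels, stratified by mutation class.

    Returns one row per stratum with the two pooled means and their
    difference (modern - ancient).  ``transversions_only`` removes the
    transition stratum entirely.
    """
    cfg = config or Config()
    keep = np.array(
        [
            s.constrained and s.deleterious_allele is not None and s.mutation_class is not None
            for s in acm.sites
        ]
    )
    sub = acm.subset_sites(keep)
    ancient = [i for i, s in enumerate(sub.samples) if s.is_ancient]
    modern = [i for i, s in enumerate(sub.samples) if not s.is_ancient]
    if not ancient or not modern:
        raise ValueError("both an ancient and a modern pool are required")
    f_anc = ml_frequency_matrix(sub, ancient)
    f_mod = ml_frequency_matrix(sub, modern)
    classes = np.array([s.mutation_class for s in sub.sites])
    strata = ["transversion"] if transversions_only else ["transition", "transversion"]
    rows = []
    for stratum in strata:
        m = (classes == stratum) & ~np.isnan(f_anc) & ~np.isnan(f_mod)
        if m.sum() == 0:
            rows.append(
                {"mutation_class": stratum, "n_sites": 0, "f_ancient": np.nan,
                 "f_modern": np.nan, "difference": np.nan}
            )
            continue
        fa, fm = float(f_anc[m].mean()), float(f_mod[m].mean())
        rows.append(
            {
                "mutation_class": stratum,
                "n_sites": int(m.sum()),
                "f_ancient": fa,
                "f_modern": fm,
                "difference": fm - fa,
            }
        )
    return pd.DataFrame(rows)
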