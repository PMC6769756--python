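"""End-to-end analysis workflows combining the pipeline stages.

These functions run the whole chain on in-memory objects — simulate (or
accept) a dataset, call genotypes, ascertain the deleterious variants
segregating in the modern panel, and compute the summary quantities the
study design targets: pooled ancient-vs-modern frequency differences,
per-interval frequency-shift medians, the increase/decrease tally over
the most recent interval, mutational loads and their correlation with
estimated inbreeding.  They back both the command-line ``report`` stage
and the reproducibility script.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from . import genotyping, inbreeding, io as pio, loadstats, trajectories
from .datamodel import AlleleCountMatrix, Config
from .simdata import ScenarioParams, SimulatedDataset, simulate_dataset


def ascertain_modern_segregating(
    acm: AlleleCountMatrix, error_rate: float
) -> np.ndarray:
    """Mask of deleterious sites segregating in the modern panel.

    Mirrors the study design: the tracked variants are the deleterious
    alleles observed (as het or hom carriers, by maximum-likelihood
    genotype) in at least one modern genome.
    """
    geno, _, _ = genotyping.call_matrix(acm, error_rate=error_rate, strict=False)
    modern = np.array([not s.is_ancient for s in acm.samples])
    carrier = (
        (geno[modern] == genotyping.GENO_HET)
        | (geno[modern] == genotyping.GENO_HOM_DEL)
    ).any(axis=0)
    deleterious = np.array(
        [s.constrained and s.deleterious_allele is not None for s in acm.sites]
    )
    return deleterious & carrier


def trajectory_metrics(
    acm: AlleleCountMatrix,
    config: Optional[Config] = None,
    error_rate: float = 1e-3,
) -> dict:
    """Trajectory-level summary of a dataset.

    Returns the pooled modern-minus-ancient frequency difference per
    mutation class (in percent), trajectory-class percentages, the median
    |delta| per non-overlapping interval, the one-sided rank-sum p-value
    for the most recent interval exceeding the older ones, and the
    fraction of dynamic variants that increased over the most recent
    interval.
    """
    cfg = config or Config()
    keep = ascertain_modern_segregating(acm, error_rate)
    sub = acm.subset_sites(keep)
    table = trajectories.trajectory_table(sub, cfg)
    class_pct = (
        100.0 * table["trajectory_class"].value_counts(normalize=True)
    ).to_dict()

    deltas = trajectories.delta_series(table)
    dynamic_keys = set(
        map(
            tuple,
            table.loc[table["trajectory_class"] == "dynamic", ["chrom", "pos"]].values,
        )
    )
    deltas = deltas[
        [
            (c, p) in dynamic_keys
            for c, p in zip(deltas["chrom"], deltas["pos"])
        ]
    ].dropna(subset=["delta"])
    medians = deltas.groupby("center_bp")["delta"].median().to_dict()
    recent = deltas.loc[deltas["center_bp"] == 0.0, "delta"]
    older = deltas.loc[deltas["center_bp"] > 0.0, "delta"]
    if len(recent) and len(older):
        _, p_recent = mannwhitneyu(recent, older, alternative="greater")
    else:
        p_recent = np.nan
    signed = deltas.loc[deltas["center_bp"] == 0.0, "signed_delta"]
    frac_up = float((signed > 0).mean()) if len(signed) else np.nan

    pooled = trajectories.pooled_comparison(sub, cfg)
    diff_pct = {
        row["mutation_class"]: 100.0 * row["difference"]
        for _, row in pooled.iterrows()
    }
    return {
        "n_sites_tracked": int(keep.sum()),
        "class_percent": class_pct,
        "pooled_diff_percent": diff_pct,
        "delta_medians": medians,
        "p_recent_vs_older": float(p_recent),
        "frac_increase_recent": frac_up,
        "n_dynamic_recent": int(len(signed)),
    }


def load_table(
    acm: AlleleCountMatrix,
    config: Optional[Config] = None,
    error_rate: float = 1e-3,
) -> pd.Series:
    """Genome-wide load per sample under the strict calling protocol."""
    cfg = config or Config()
    geno, _, _ = genotyping.call_matrix(
        acm, error_rate=error_rate, call_threshold=cfg.call_threshold
    )
    frame = pio.sites_to_frame(acm.sites)
    loads = loadstats.compute_loads(
        geno, frame, acm.samples, phylop_threshold=cfg.phylop_threshold,
        per_region=False,
    )
    gw = loads[loads["region_class"] == loadstats.GENOME_WIDE]
    return gw.set_index("sample_id")["load"]


def inbreeding_metrics(
    ds: SimulatedDataset,
    config: Optional[Config] = None,
    error_rate: float = 1e-3,
    n_hmm_samples: int = 40,
    max_iter: int = 30,
) -> dict:
    """Inbreeding estimates for a modern subset and the load correlation.

    Fits the IBD HMM to the first ``n_hmm_samples`` modern genomes (on
    LD-pruned polymorphic sites called from their read counts) and
    correlates the estimated F with the genome-wide load; also reports the
    correlation against the generator's true F over all moderns.
    """
    cfg = config or Config()
    acm = ds.acm
    modern_idx = np.array([i for i, s in enumerate(acm.samples) if not s.is_ancient])
    geno, _, _ = genotyping.call_matrix(acm, error_rate=error_rate, strict=False)
    gm = geno[modern_idx]
    positions = np.array([s.pos for s in acm.sites])
    chroms = np.array([s.chrom for s in acm.sites])
    called = gm >= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(
            called.sum(0) > 0,
            np.where(called, gm, 0).sum(0) / np.maximum(2 * called.sum(0), 1),
            0.0,
        )
    poly = (freqs > 0.05) & (freqs < 0.95) & inbreeding.missingness_filter(
        np.where(called, gm, -1)
    )
    idx = np.flatnonzero(poly)
    pairs = inbreeding.ld_r2_pairs(
        gm[:, idx].astype(float), positions[idx], chroms[idx], cfg.ld_max_dist_bp
    )
    _, reps = inbreeding.cluster_ld_blocks(pairs, positions[idx], cfg.ld_r2_threshold)
    pruned = idx[reps]

    subset = modern_idx[:n_hmm_samples]
    f_est = np.empty(len(subset))
    for k, i in enumerate(subset):
        ok = geno[i, pruned] >= 0
        pp = pruned[ok]
        res = inbreeding.fit_ibd_hmm(
            (geno[i, pp] == genotyping.GENO_HET).astype(np.int8),
            positions[pp],
            chroms[pp],
            np.clip(freqs[pp], 1e-3, 1.0 - 1e-3),
            em_epsilon=cfg.em_epsilon,
            max_iter=max_iter,
            sample_id=acm.samples[i].sample_id,
        )
        f_est[k] = res.f

    gw = load_table(acm, cfg, error_rate)
    subset_ids = [acm.samples[i].sample_id for i in subset]
    rho_est, p_est = inbreeding.correlate_load_inbreeding(
        gw[subset_ids].to_numpy(), f_est
    )
    modern_ids = [acm.samples[i].sample_id for i in modern_idx]
    rho_true, p_true = inbreeding.correlate_load_inbreeding(
        gw[modern_ids].to_numpy(), ds.truth.f_true[modern_idx]
    )
    ancient_ids = [s.sample_id for s in acm.samples if s.is_ancient]
    return {
        "n_pruned_sites": int(len(pruned)),
        "f_estimates": f_est,
        "f_true_subset": ds.truth.f_true[subset],
        "rho_load_f_estimated": float(rho_est),
        "p_load_f_estimated": float(p_est),
        "rho_load_f_true": float(rho_true),
        "p_load_f_true": float(p_true),
        "mean_load_modern": float(gw[modern_ids].mean()),
        "mean_load_ancient": float(gw[ancient_ids].mean()),
    }


def run_direction_checks(
    seed: int,
    purging_strength: float = 0.5,
    n_hmm_samples: int = 40,
    params: Optional[ScenarioParams] = None,
) -> dict:
    """Full end-to-end run of the default scenario, with and without
    purging, returning every direction-check quantity."""
    base = params or ScenarioParams(seed=seed)
    base.seed = seed
    base.purging_strength = 0.0
    ds = simulate_dataset(base)
    cfg = Config(seed=seed)
    traj = trajectory_metrics(ds.acm, cfg, base.error_rate)
    inb = inbreeding_metrics(ds, cfg, base.error_rate, n_hmm_samples)

    import dataclasses

    purged_params = dataclasses.replace(base, purging_strength=purging_strength)
    ds_purged = simulate_dataset(purged_params)
    inb_purged = inbreeding_metrics(ds_purged, cfg, base.error_rate, n_hmm_samples)
    return {
        "trajectories": traj,
        "inbreeding": inb,
        "inbreeding_purged": inb_purged,
    }
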