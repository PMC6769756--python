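"""The load statistic against a per-site brute-force oracle, plus group tests."""
import itertools

import numpy as np
import pandas as pd
import pytest

from paleoload import genotyping as gt
from paleoload import loadstats as ls
from paleoload.datamodel import REGION_CLASSES, SampleMeta


def _samples(n):
    return [SampleMeta(f"s{i}", f"breed{i % 3}", "other", 0.0, 10.0) for i in range(n)]


def _sites_frame(rng, n):
    regions = rng.choice(list(REGION_CLASSES), size=n)
    phylop = rng.uniform(-1, 4, size=n).round(3)
    del_allele = rng.choice(["G", None], size=n, p=[0.8, 0.2])
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, n + 1),
            "region_class": regions,
            "phylop": phylop,
            "deleterious_allele": del_allele,
            "constrained": phylop >= 1.5,
            "mutation_class": "transversion",
            "major_allele": "A",
        }
    )


def load_oracle(genotypes, sites, sample_idx, region_set, threshold):
    """Per-site loop implementing the load definition directly."""
    num = 0.0
    n_hom = 0
    for j in range(len(sites)):
        if sites["region_class"].iloc[j] not in region_set:
            continue
        g = genotypes[sample_idx, j]
        if g not in (gt.GENO_HOM_MAJOR, gt.GENO_HOM_DEL):
            continue
        n_hom += 1
        if (
            g == gt.GENO_HOM_DEL
            and sites["deleterious_allele"].iloc[j] is not None
            and sites["phylop"].iloc[j] >= threshold
        ):
            num += sites["phylop"].iloc[j]
    return (num / n_hom) if n_hom else np.nan, n_hom


class TestComputeLoads:
    def test_worked_example(self):
        # three deleterious homozygotes at phyloP 2.0/1.6/3.0 among 1000
        # called homozygous sites -> load 6.6e-3
        n = 1000
        sites = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(1, n + 1),
                "region_class": "coding",
                "phylop": 2.0,
                "deleterious_allele": "G",
                "constrained": True,
                "mutation_class": "transversion",
                "major_allele": "A",
            }
        )
        sites.loc[1, "phylop"] = 1.6
        sites.loc[2, "phylop"] = 3.0
        geno = np.full((1, n), gt.GENO_HOM_MAJOR, dtype=np.int8)
        geno[0, :3] = gt.GENO_HOM_DEL
        loads = ls.compute_loads(geno, sites, _samples(1), per_region=False)
        gw = loads[loads["region_class"] == ls.GENOME_WIDE].iloc[0]
        assert gw["load"] == pytest.approx(6.6e-3)
        assert gw["n_hom_total"] == n and gw["n_hom_deleterious"] == 3

    def test_subthreshold_site_counts_in_denominator_only(self):
        sites = pd.DataFrame(
            {
                "chrom": "chr1", "pos": [1, 2], "region_class": "coding",
                "phylop": [1.49, 2.0], "deleterious_allele": "G",
                "constrained": [False, True], "mutation_class": "transversion",
                "major_allele": "A",
            }
        )
        geno = np.array([[gt.GENO_HOM_DEL, gt.GENO_HOM_MAJOR]], dtype=np.int8)
        loads = ls.compute_loads(geno, sites, _samples(1), per_region=False)
        gw = loads[loads["region_class"] == ls.GENOME_WIDE].iloc[0]
        assert gw["n_hom_total"] == 2 and gw["load"] == 0.0

    def test_no_called_homozygotes_is_missing_not_zero(self):
        sites = _sites_frame(np.random.default_rng(0), 5)
        geno = np.full((1, 5), gt.GENO_MASKED, dtype=np.int8)
        loads = ls.compute_loads(geno, sites, _samples(1), per_region=False)
        assert np.isnan(loads["load"]).all()

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_sites, n_samples = 120, 4
        sites = _sites_frame(rng, n_sites)
        geno = rng.choice(
            [gt.GENO_MASKED, gt.GENO_HOM_MAJOR, gt.GENO_HET, gt.GENO_HOM_DEL],
            size=(n_samples, n_sites),
        ).astype(np.int8)
        loads = ls.compute_loads(geno, sites, _samples(n_samples))
        for i in range(n_samples):
            for rc in list(REGION_CLASSES) + [ls.GENOME_WIDE]:
                region_set = set(REGION_CLASSES) if rc == ls.GENOME_WIDE else {rc}
                want, n_hom = load_oracle(geno, sites, i, region_set, 1.5)
                row = loads[
                    (loads["sample_id"] == f"s{i}") & (loads["region_class"] == rc)
                ].iloc[0]
                assert row["n_hom_total"] == n_hom
                if n_hom:
                    assert row["load"] == pytest.approx(want, abs=1e-12)
                else:
                    assert np.isnan(row["load"])

    def test_linearity_in_phylop(self):
        rng = np.random.default_rng(3)
        sites = _sites_frame(rng, 200)
        geno = rng.choice([0, 1, 2, -1], size=(3, 200)).astype(np.int8)
        base = ls.compute_loads(geno, sites, _samples(3), per_region=False)
        doubled_sites = sites.copy()
        doubled_sites["phylop"] = 2 * doubled_sites["phylop"]
        doubled = ls.compute_loads(
            geno, doubled_sites, _samples(3), per_region=False, phylop_threshold=3.0
        )
        np.testing.assert_allclose(2 * base["load"], doubled["load"])

    def test_region_numerators_partition_genome_wide(self):
        rng = np.random.default_rng(4)
        sites = _sites_frame(rng, 300)
        geno = rng.choice([0, 1, 2, -1], size=(2, 300)).astype(np.int8)
        loads = ls.compute_loads(geno, sites, _samples(2))
        for sid in ("s0", "s1"):
            sub = loads[loads["sample_id"] == sid]
            gw = sub[sub["region_class"] == ls.GENOME_WIDE].iloc[0]
            parts = sub[sub["region_class"] != ls.GENOME_WIDE]
            assert parts["sum_phylop"].sum() == pytest.approx(gw["sum_phylop"])
            assert parts["n_hom_total"].sum() == gw["n_hom_total"]

    def test_invariant_to_site_and_sample_order(self):
        rng = np.random.default_rng(5)
        sites = _sites_frame(rng, 80)
        geno = rng.choice([0, 1, 2, -1], size=(3, 80)).astype(np.int8)
        base = ls.compute_loads(geno, sites, _samples(3), per_region=False)
        perm = rng.permutation(80)
        shuffled = ls.compute_loads(
            geno[:, perm], sites.iloc[perm].reset_index(drop=True), _samples(3),
            per_region=False,
        )
        merged = base.merge(shuffled, on=["sample_id", "region_class"])
        np.testing.assert_allclose(merged["load_x"], merged["load_y"])


def rank_sum_oracle(a, b):
    """Exact two-sided p by enumerating every labelling of the pooled data."""
    pooled = np.concatenate([a, b])
    n_a = len(a)

    def u_stat(x_idx):
        x = pooled[list(x_idx)]
        y = np.delete(pooled, list(x_idx))
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)

    observed = u_stat(range(n_a))
    mean_u = n_a * (len(pooled) - n_a) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        if abs(u_stat(idx) - mean_u) >= abs(observed - mean_u) - 1e-12:
            count += 1
    return count / total


class TestGroupCompare:
    def test_disjoint_groups_exact_p(self):
        u, p = ls.group_compare([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_groups(self):
        u, p = ls.group_compare([1.0, 1.0], [1.0, 1.0])
        assert u == 2.0 and p == 1.0

    def test_tied_pairs_statistic(self):
        u, p = ls.group_compare([1, 2], [1, 2])
        assert u == 2.0 and p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=4)
        b = rng.normal(size=4)
        _, p = ls.group_compare(a, b)
        assert p == pytest.approx(rank_sum_oracle(a, b), abs=1e-12)

    def test_rejects_singleton_groups(self):
        with pytest.raises(ValueError):
            ls.group_compare([1.0], [2.0, 3.0])


class TestCorrelations:
    def test_spearman_examples(self):
        assert ls.spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 100])[0] == pytest.approx(1.0)
        assert ls.spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])[0] == pytest.approx(-1.0)
        rho, _ = ls.spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert rho == pytest.approx(0.8)  # 1 - 6*4/120, by the rank formula

    def test_constant_vector_is_missing(self):
        rho, p = ls.spearman([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])
        assert np.isnan(rho)

    def test_region_correlation_table(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(8):
            base = rng.uniform(1, 2)
            for rc in REGION_CLASSES:
                rows.append(
                    {"sample_id": f"s{i}", "region_class": rc, "load": base + rng.normal(0, 0.1)}
                )
        out = ls.region_correlation(pd.DataFrame(rows))
        assert len(out) == 10  # C(5,2) region pairs
        assert (out["n"] == 8).all()


class TestBreedSummary:
    def test_single_and_double_samples(self):
        samples = [
            SampleMeta("a", "x", "other", 0.0, 10.0),
            SampleMeta("b", "y", "other", 0.0, 10.0),
            SampleMeta("c", "y", "other", 0.0, 10.0),
        ]
        loads = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c"],
                "region_class": ls.GENOME_WIDE,
                "load": [4.0e-3, 4.0e-3, 4.2e-3],
            }
        )
        out = ls.breed_summary(loads, samples)
        x = out[out["breed"] == "x"].iloc[0]
        y = out[out["breed"] == "y"].iloc[0]
        assert x["mean"] == 4.0e-3 and bool(x["low_confidence"])
        assert y["mean"] == pytest.approx(4.1e-3)
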