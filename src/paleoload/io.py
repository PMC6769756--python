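"""Readers and writers for the plain-text formats used by the pipeline.

Formats (all tab-separated, 1-based inclusive coordinates):

* site table:  ``chrom pos region_class phylop column_counts`` with the
  alignment-column tally encoded as ``"A:44,G:2"``;
* counts:      ``sample chrom pos del_allele r d`` (long format);
* metadata:    ``sample_id breed group age_bp mean_depth``;
* genotypes:   a minimal VCF 4.2 subset (GT field), read through cyvcf2;
* trees:       Newick via dendropy; config: YAML.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    AlleleCountMatrix,
    Config,
    SampleMeta,
    SiteAnnotation,
)


class ParseError(ValueError):
    """Malformed input row; message carries the file and line number."""


def _err(path, lineno, msg) -> ParseError:
    return ParseError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------------
# column-count tally encoding

def format_column_counts(counts) -> str:
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ",".join(f"{a}:{c}" for a, c in items)


def parse_column_counts(text: str) -> dict:
    out = {}
    for part in text.split(","):
        allele, _, num = part.partition(":")
        out[allele.strip()] = int(num)
    return out


# ---------------------------------------------------------------------------
# site table

SITE_COLUMNS = ("chrom", "pos", "region_class", "phylop", "column_counts")


def load_site_table(
    path,
    phylop_threshold: float = 1.5,
    sample_alleles: Optional[dict] = None,
) -> list:
    """Read a site-annotation TSV into a list of :class:`SiteAnnotation`.

    ``sample_alleles`` optionally maps ``(chrom, pos)`` to the allele set
    observed in the study samples, which participates in the deleterious-
    allele assignment at monomorphic alignment columns.
    """
    sites = []
    last = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != SITE_COLUMNS:
            raise _err(path, 1, f"expected header {SITE_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise _err(path, lineno, f"expected 5 columns, got {len(fields)}")
            chrom, pos_s, region, phylop_s, cc_s = fields
            try:
                pos = int(pos_s)
                phylop = float(phylop_s)
                cc = parse_column_counts(cc_s)
            except ValueError as exc:
                raise _err(path, lineno, str(exc)) from exc
            if chrom in last and pos <= last[chrom]:
                raise _err(path, lineno, f"positions not strictly increasing on {chrom}")
            last[chrom] = pos
            alleles = ()
            if sample_alleles is not None:
                alleles = tuple(sample_alleles.get((chrom, pos), ()))
            try:
                sites.append(
                    SiteAnnotation.from_fields(
                        chrom, pos, region, phylop, cc, alleles, phylop_threshold
                    )
                )
            except ValueError as exc:
                raise _err(path, lineno, str(exc)) from exc
    return sites


def write_site_table(path, sites: Sequence[SiteAnnotation]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SITE_COLUMNS) + "\n")
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.region_class}\t{s.phylop!r}\t"
                f"{format_column_counts(s.column_counts)}\n"
            )


def sites_to_frame(sites: Sequence[SiteAnnotation]) -> pd.DataFrame:
    """Tabular view of a site list for the statistics modules."""
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "region_class": [s.region_class for s in sites],
            "phylop": [s.phylop for s in sites],
            "deleterious_allele": [s.deleterious_allele for s in sites],
            "constrained": [s.constrained for s in sites],
            "mutation_class": [s.mutation_class for s in sites],
            "major_allele": [s.major_allele for s in sites],
        }
    )


# ---------------------------------------------------------------------------
# metadata

META_COLUMNS = ("sample_id", "breed", "group", "age_bp", "mean_depth")


def load_metadata(path) -> list:
    samples = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != META_COLUMNS:
            raise _err(path, 1, f"expected header {META_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise _err(path, lineno, f"expected 5 columns, got {len(fields)}")
            try:
                samples.append(
                    SampleMeta(
                        sample_id=fields[0],
                        breed=fields[1],
                        group=fields[2],
                        age_bp=float(fields[3]),
                        mean_depth=float(fields[4]),
                    )
                )
            except ValueError as exc:
                raise _err(path, lineno, str(exc)) from exc
    return samples


def write_metadata(path, samples: Sequence[SampleMeta]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(META_COLUMNS) + "\n")
        for s in samples:
            fh.write(
                f"{s.sample_id}\t{s.breed}\t{s.group}\t{s.age_bp!r}\t{s.mean_depth!r}\n"
            )


# ---------------------------------------------------------------------------
# read counts

COUNT_COLUMNS = ("sample", "chrom", "pos", "del_allele", "r", "d")


def load_counts(path, samples: Sequence[SampleMeta], sites: Sequence[SiteAnnotation]) -> AlleleCountMatrix:
    """Read a pileup-like counts TSV into an :class:`AlleleCountMatrix`.

    Rows absent from the file are treated as missing (depth 0).  Rows
    referring to unknown samples or sites, or violating ``0 <= r <= d``,
    raise :class:`ParseError` with the offending line number.
    """
    sample_idx = {s.sample_id: i for i, s in enumerate(samples)}
    site_idx = {(s.chrom, s.pos): j for j, s in enumerate(sites)}
    r = np.zeros((len(samples), len(sites)), dtype=np.int32)
    d = np.zeros_like(r)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != COUNT_COLUMNS:
            raise _err(path, 1, f"expected header {COUNT_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 6:
                raise _err(path, lineno, f"expected 6 columns, got {len(fields)}")
            sample, chrom, pos_s, _allele, r_s, d_s = fields
            try:
                pos, rv, dv = int(pos_s), int(r_s), int(d_s)
            except ValueError as exc:
                raise _err(path, lineno, str(exc)) from exc
            if sample not in sample_idx:
                raise _err(path, lineno, f"unknown sample {sample!r}")
            if (chrom, pos) not in site_idx:
                raise _err(path, lineno, f"unknown site {chrom}:{pos}")
            if not (0 <= rv <= dv):
                raise _err(path, lineno, f"invalid counts r={rv}, d={dv}")
            r[sample_idx[sample], site_idx[(chrom, pos)]] = rv
            d[sample_idx[sample], site_idx[(chrom, pos)]] = dv
    return AlleleCountMatrix(samples=list(samples), sites=list(sites), r=r, d=d)


def write_counts(path, acm: AlleleCountMatrix) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(COUNT_COLUMNS) + "\n")
        for i, sample in enumerate(acm.samples):
            for j, site in enumerate(acm.sites):
                if acm.d[i, j] == 0:
                    continue  # depth 0 encodes missing; omit the row
                allele = site.deleterious_allele or "."
                fh.write(
                    f"{sample.sample_id}\t{site.chrom}\t{site.pos}\t{allele}\t"
                    f"{acm.r[i, j]}\t{acm.d[i, j]}\n"
                )


# ---------------------------------------------------------------------------
# VCF (GT-only subset)

def write_vcf(path, samples: Sequence[str], sites: Sequence[SiteAnnotation], dosage) -> None:
    """Write a GT-only VCF.  ``dosage[i, j]`` counts deleterious-allele
    copies (0/1/2) for sample ``i`` at site ``j``; -1 encodes missing."""
    dosage = np.asarray(dosage)
    gt_strings = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = []
        for s in sites:
            if s.chrom not in chroms:
                chroms.append(s.chrom)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for j, site in enumerate(sites):
            ref = site.major_allele
            alt = site.deleterious_allele or "."
            gts = "\t".join(gt_strings[int(g)] for g in dosage[:, j])
            fh.write(f"{site.chrom}\t{site.pos}\t.\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}\n")


def load_vcf(path):
    """Read a GT-only VCF.

    Returns ``(sample_ids, records, dosage)`` where ``records`` is a
    DataFrame with chrom/pos/ref/alt and ``dosage`` is an
    (n_samples, n_sites) int array of ALT-allele copies, -1 for missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    chroms, poss, refs, alts, cols = [], [], [], [], []
    for var in vcf:
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
        gts = var.genotypes  # [[a0, a1, phased], ...]
        col = np.array(
            [a0 + a1 if a0 >= 0 and a1 >= 0 else -1 for a0, a1, *_ in gts],
            dtype=np.int8,
        )
        cols.append(col)
    vcf.close()
    records = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    dosage = (
        np.stack(cols, axis=1) if cols else np.zeros((len(sample_ids), 0), dtype=np.int8)
    )
    return sample_ids, records, dosage


# ---------------------------------------------------------------------------
# trees, config, generic tables

def write_newick(tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def load_config(path) -> Config:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(Config)}
    unknown = set(data) - known
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    return Config(**data)


def save_config(config: Config, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
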