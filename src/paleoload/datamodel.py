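"""Core domain types and site-level classification rules.

The analysis revolves around per-position annotations: a conservation
(phyloP) score summarising evolutionary constraint across a multi-species
alignment, the allele tally observed in that alignment column, and the
"deleterious" allele — the allele that is rarer than, or absent from, the
alignment column. Sites with a phyloP score at or above a configurable
threshold (default 1.5, which discriminates fourfold- from zerofold-
degenerate coding sites) are treated as evolutionarily constrained, so a
derived allele there is considered harmful.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")

#: Region classes recognised in site annotations, in precedence order used
#: when an input assigns a position to more than one class.
REGION_CLASSES = ("coding", "upstream2kb", "downstream2kb", "intron", "intergenic")

GROUPS = ("working", "hotblood", "warmblood", "przewalski", "hybrid", "ancient", "other")

TRANSITION = "transition"
TRANSVERSION = "transversion"

_TRANSITION_PAIRS = (frozenset("AG"), frozenset("CT"))


def classify_constraint(phylop: float, threshold: float = 1.5) -> bool:
    """True iff the site is evolutionarily constrained (phyloP >= threshold)."""
    if not math.isfinite(phylop):
        raise ValueError(f"phyloP score must be finite, got {phylop!r}")
    return phylop >= threshold


def classify_mutation(a1: str, a2: str) -> str:
    """Classify an allele pair as ``"transition"`` or ``"transversion"``.

    Transitions are the purine<->purine / pyrimidine<->pyrimidine pairs
    {A,G} and {C,T}; the other four unordered pairs are transversions.
    Symmetric in its arguments.
    """
    if a1 not in NUCLEOTIDES or a2 not in NUCLEOTIDES:
        raise ValueError(f"non-nucleotide alleles: {a1!r}, {a2!r}")
    if a1 == a2:
        raise ValueError(f"equal alleles {a1!r}: not a mutation")
    return TRANSITION if frozenset((a1, a2)) in _TRANSITION_PAIRS else TRANSVERSION


def assign_deleterious_allele(
    column_counts: Mapping[str, int],
    sample_alleles: Sequence[str] = (),
) -> Optional[str]:
    """Pick the putatively deleterious allele at a site.

    The deleterious allele is the less frequent allele in the alignment
    column, or — when the column is monomorphic — a sample allele absent
    from the column.  The assignment is only made when at most two distinct
    variants segregate across the column plus the observed sample alleles;
    ties between the two column alleles are unresolvable and return None.

    Returns None (undefined) when the site is rejected.
    """
    if not column_counts:
        raise ValueError("empty alignment-column tally")
    bad = [a for a in list(column_counts) + list(sample_alleles) if a not in NUCLEOTIDES]
    if bad:
        logger.warning("rejecting site with non-nucleotide symbols %s", sorted(set(bad)))
        return None
    observed = {a for a, c in column_counts.items() if c > 0}
    variants = observed | set(sample_alleles)
    if len(variants) > 2:
        return None
    if len(observed) == 2:
        (a1, c1), (a2, c2) = sorted(column_counts.items())
        if c1 == c2:
            return None  # tie: no minor allele
        return a1 if c1 < c2 else a2
    # monomorphic column: deleterious allele is a sample allele absent from it
    extra = variants - observed
    if extra:
        return extra.pop()
    return None


@dataclass(frozen=True)
class SiteAnnotation:
    """One genomic position with its conservation and allele annotation."""

    chrom: str
    pos: int  # 1-based
    region_class: str
    phylop: float
    column_counts: Mapping[str, int]
    deleterious_allele: Optional[str] = None
    constrained: bool = False
    mutation_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not math.isfinite(self.phylop):
            raise ValueError("phyloP score must be finite")
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")
        if self.deleterious_allele is not None:
            variants = {a for a, c in self.column_counts.items() if c > 0}
            variants.add(self.deleterious_allele)
            if len(variants) > 2:
                raise ValueError(
                    "deleterious allele defined at a site with >2 segregating variants"
                )

    @property
    def major_allele(self) -> str:
        """Most frequent allele in the alignment column (ties by base order)."""
        return max(sorted(self.column_counts), key=lambda a: self.column_counts[a])

    @classmethod
    def from_fields(
        cls,
        chrom: str,
        pos: int,
        region_class: str,
        phylop: float,
        column_counts: Mapping[str, int],
        sample_alleles: Sequence[str] = (),
        phylop_threshold: float = 1.5,
    ) -> "SiteAnnotation":
        """Build a fully annotated site, deriving the classification fields."""
        delet = assign_deleterious_allele(column_counts, sample_alleles)
        mut = None
        if delet is not None:
            major = max(sorted(column_counts), key=lambda a: column_counts[a])
            if major != delet:
                mut = classify_mutation(major, delet)
        return cls(
            chrom=chrom,
            pos=pos,
            region_class=region_class,
            phylop=phylop,
            column_counts=dict(column_counts),
            deleterious_allele=delet,
            constrained=classify_constraint(phylop, phylop_threshold),
            mutation_class=mut,
        )


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    breed: str
    group: str
    age_bp: float  # years before present; 0 for modern samples
    mean_depth: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.age_bp < 0:
            raise ValueError("age_bp must be >= 0")
        if self.group == "ancient" and self.age_bp <= 0:
            raise ValueError("ancient samples must have age_bp > 0")

    @property
    def is_ancient(self) -> bool:
        return self.age_bp > 0


@dataclass
class AlleleCountMatrix:
    """Per-(sample, site) deleterious-allele read counts and total depths.

    ``r[i, j]`` counts reads supporting the deleterious allele of site ``j``
    in sample ``i``; ``d[i, j]`` is the total read depth there.  ``d == 0``
    encodes missing data.
    """

    samples: list  # list[SampleMeta]
    sites: list  # list[SiteAnnotation]
    r: "np.ndarray"
    d: "np.ndarray"

    def __post_init__(self) -> None:
        import numpy as np

        self.r = np.asarray(self.r)
        self.d = np.asarray(self.d)
        shape = (len(self.samples), len(self.sites))
        if self.r.shape != shape or self.d.shape != shape:
            raise ValueError(
                f"count arrays must have shape {shape}, got {self.r.shape}/{self.d.shape}"
            )
        if (self.r < 0).any() or (self.r > self.d).any():
            raise ValueError("invariant violated: need 0 <= r <= d elementwise")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset_samples(self, mask) -> "AlleleCountMatrix":
        import numpy as np

        idx = np.flatnonzero(np.asarray(mask))
        return AlleleCountMatrix(
            samples=[self.samples[i] for i in idx],
            sites=self.sites,
            r=self.r[idx],
            d=self.d[idx],
        )

    def subset_sites(self, mask) -> "AlleleCountMatrix":
        import numpy as np

        idx = np.flatnonzero(np.asarray(mask))
        return AlleleCountMatrix(
            samples=self.samples,
            sites=[self.sites[j] for j in idx],
            r=self.r[:, idx],
            d=self.d[:, idx],
        )


@dataclass
class Config:
    """Analysis-wide thresholds and window parameters."""

    phylop_threshold: float = 1.5
    call_threshold: float = 0.99
    fixed_threshold: float = 0.99
    absent_threshold: float = 0.01
    bin_width_years: float = 1000.0
    bin_step_years: float = 250.0
    min_bin_n: int = 10
    ld_max_dist_bp: int = 50_000
    ld_r2_threshold: float = 0.2
    em_epsilon: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.absent_threshold < self.fixed_threshold <= 1):
            raise ValueError("need 0 < absent_threshold < fixed_threshold <= 1")
        if self.bin_step_years > self.bin_width_years:
            raise ValueError("bin step must not exceed bin width")
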