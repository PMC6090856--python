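"""Core record types shared across the pipeline.

Every external table row is parsed into one of these frozen-ish dataclasses,
which enforce their invariants at construction time. Coordinates are 1-based
inclusive throughout (MAF/SEG convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "VariantClass",
    "SampleInfo",
    "MutationRecord",
    "CopyNumberSegment",
    "ExpressionRecord",
    "CCFPosterior",
    "PeptideCandidate",
    "BindingCall",
    "InvariantError",
    "HLA_ALLELE_RE",
]


class InvariantError(ValueError):
    """A record violated one of its documented invariants."""


class VariantClass(str, Enum):
    """The seven somatic variant classes tracked by the pipeline."""

    MISSENSE = "missense"
    SILENT = "silent"
    NONSENSE = "nonsense"
    SPLICE_SITE = "splice_site"
    NONSTOP_READTHROUGH = "nonstop_readthrough"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: allele names look like "DRB1*01:01" (gene, field1:field2)
HLA_ALLELE_RE = re.compile(r"^[A-Z0-9]+\*\d{2}:\d{2,3}$")

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class SampleInfo:
    """One tumor sample: purity/ploidy estimates plus HLA typing.

    ``purity`` is the cancer-cell fraction of the bulk sample, in (0, 1];
    ``ploidy`` the average tumor genome copy number.
    """

    patient_id: str
    purity: float
    ploidy: float
    smoker: Optional[bool] = None
    hla_class2_alleles: Tuple[str, ...] = ()
    hla_class1_alleles: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.hla_class2_alleles = tuple(self.hla_class2_alleles)
        self.hla_class1_alleles = tuple(self.hla_class1_alleles)
        if not (0.0 < self.purity <= 1.0):
            raise InvariantError(
                f"sample {self.patient_id!r}: purity {self.purity} outside (0, 1]"
            )
        if not self.ploidy > 0:
            raise InvariantError(
                f"sample {self.patient_id!r}: ploidy {self.ploidy} must be > 0"
            )
        for allele in (*self.hla_class2_alleles, *self.hla_class1_alleles):
            if not HLA_ALLELE_RE.match(allele):
                raise InvariantError(
                    f"sample {self.patient_id!r}: malformed HLA allele {allele!r}"
                )


@dataclass
class MutationRecord:
    """One somatic variant with tumor read counts and annotations."""

    patient_id: str
    gene: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    classification: VariantClass
    alt_count: int
    ref_count: int
    pon_frequency: float = 0.0
    in_dbsnp: bool = False
    in_1000g: bool = False
    transcript_id: str = ""
    protein_change: str = ""

    def __post_init__(self) -> None:
        self.classification = VariantClass(self.classification)
        if self.alt_count < 0 or self.ref_count < 0:
            raise InvariantError(
                f"{self.patient_id}/{self.gene}:{self.pos}: negative read count"
            )
        if not (0.0 <= self.pon_frequency <= 1.0):
            raise InvariantError(
                f"{self.patient_id}/{self.gene}:{self.pos}: "
                f"pon_frequency {self.pon_frequency} outside [0, 1]"
            )
        if self.classification in (
            VariantClass.FRAMESHIFT_INDEL,
            VariantClass.INFRAME_INDEL,
        ) and len(self.ref_allele) == len(self.alt_allele):
            raise InvariantError(
                f"{self.patient_id}/{self.gene}:{self.pos}: indel classification "
                "requires ref/alt alleles of unequal length"
            )

    @property
    def depth(self) -> int:
        """Total tumor read depth at the site (alt + ref)."""
        return self.alt_count + self.ref_count

    @property
    def vaf(self) -> float:
        """Observed variant allele fraction; NaN at zero depth."""
        return self.alt_count / self.depth if self.depth else float("nan")

    def key(self) -> Tuple[str, str, str, int, str, str]:
        """Identity of the mutation within the cohort."""
        return (
            self.patient_id,
            self.gene,
            self.chrom,
            self.pos,
            self.ref_allele,
            self.alt_allele,
        )


@dataclass
class CopyNumberSegment:
    """One total-copy-number segment from a SEG-style table."""

    patient_id: str
    chrom: str
    start: int
    end: int
    total_copy_number: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InvariantError(
                f"segment {self.patient_id}/{self.chrom}: start {self.start} > end {self.end}"
            )
        if self.total_copy_number < 0:
            raise InvariantError(
                f"segment {self.patient_id}/{self.chrom}: negative copy number"
            )

    def covers(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


@dataclass
class ExpressionRecord:
    """RNA-seq read count for one (patient, gene) pair."""

    patient_id: str
    gene: str
    read_count: int

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise InvariantError(
                f"expression {self.patient_id}/{self.gene}: negative read count"
            )


@dataclass
class CCFPosterior:
    """Gridded posterior density of the cancer cell fraction of one mutation.

    ``density`` integrates to 1 over ``grid`` (trapezoid rule). ``ci95`` is the
    central (equal-tail) 95% credible interval.
    """

    grid: np.ndarray
    density: np.ndarray
    mode: float
    mean: float
    ci95: Tuple[float, float]
    is_clonal: bool = False

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.shape != self.density.shape:
            raise InvariantError("CCF grid and density shapes differ")
        if np.any(self.density < 0):
            raise InvariantError("negative CCF density")
        low, high = self.ci95
        if not (0.0 <= low <= high <= 1.0):
            raise InvariantError(f"malformed credible interval {self.ci95}")


@dataclass
class PeptideCandidate:
    """A mutation-overlapping k-mer window of a mutant protein."""

    patient_id: str
    gene: str
    protein_change: str
    sequence: str
    mhc_class: str  # "I" or "II"
    mutant_positions: Tuple[int, ...]  # 1-based indices into sequence
    wt_sequence: Optional[str] = None
    start: int = 0  # 1-based start within the mutant protein (provenance)

    def __post_init__(self) -> None:
        self.mutant_positions = tuple(sorted(self.mutant_positions))
        if self.mhc_class not in ("I", "II"):
            raise InvariantError(f"mhc_class must be 'I' or 'II', got {self.mhc_class!r}")
        if not self.mutant_positions:
            raise InvariantError("peptide candidate without mutant positions")
        if not set(self.sequence) <= _AA20:
            raise InvariantError(f"non-standard residues in peptide {self.sequence!r}")
        n = len(self.sequence)
        if any(not 1 <= i <= n for i in self.mutant_positions):
            raise InvariantError(
                f"mutant position outside peptide of length {n}: {self.mutant_positions}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class BindingCall:
    """Predicted IC50 of one (peptide candidate, HLA allele) pair."""

    candidate: PeptideCandidate
    allele: str
    ic50_nm: float
    category: str  # "strong" | "weak" | "non_binder"
    predictor_name: str = ""

    def __post_init__(self) -> None:
        if self.ic50_nm <= 0:
            raise InvariantError(f"IC50 must be positive, got {self.ic50_nm}")
        expected = (
            "strong" if self.ic50_nm < 50.0 else "weak" if self.ic50_nm < 500.0 else "non_binder"
        )
        if self.category != expected:
            raise InvariantError(
                f"category {self.category!r} inconsistent with IC50 {self.ic50_nm} nM"
            )

    @property
    def is_binder(self) -> bool:
        return self.category in ("strong", "weak")
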