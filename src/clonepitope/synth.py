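"""Synthetic tumor cohorts with known ground truth.

The generator emulates the statistical structure the clonality model
assumes: each patient has a true purity; each mutation a true cancer cell
fraction (1 for clonal, a fixed subclonal value otherwise); read depths are
negative-binomial; alt counts are binomial at the model's expected VAF
given purity and the local total copy number; gene expression is
zero-inflated; and each patient carries HLA-DRB1 alleles from a configured
panel. Proteins are random 100-600-mers with a consistent reverse-translated
CDS, and every mutation carries a valid HGVS-p description for the peptide
stage. One root seed drives everything; per-patient and per-gene generators
are derived from (seed, stream, index) seed sequences so adding patients or
genes never perturbs earlier ones.

Defaults mirror the cohort structure reported for the 147-patient lung
adenocarcinoma study the pipeline is designed around: ~274 mutations per
patient, ~54% clonal, ~4.7% indels, depth ~80X, and the 31-allele DRB1
panel used for class II predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import io_formats
from .clonality import expected_vaf
from .types import (
    CopyNumberSegment,
    ExpressionRecord,
    MutationRecord,
    SampleInfo,
    VariantClass,
)

__all__ = ["SynthConfig", "TruthManifest", "SyntheticCohort", "generate_cohort",
           "kras_fixture", "DEFAULT_DRB1_PANEL", "KRAS_FRAGMENT"]

#: DRB1 allele panel (the 31 alleles of the class II analysis)
DEFAULT_DRB1_PANEL = (
    "DRB1*01:01", "DRB1*01:02", "DRB1*01:03", "DRB1*03:01", "DRB1*04:01",
    "DRB1*04:02", "DRB1*04:03", "DRB1*04:04", "DRB1*04:05", "DRB1*04:07",
    "DRB1*04:08", "DRB1*07:01", "DRB1*08:01", "DRB1*08:03", "DRB1*08:04",
    "DRB1*09:01", "DRB1*10:01", "DRB1*11:01", "DRB1*11:02", "DRB1*11:03",
    "DRB1*11:04", "DRB1*12:01", "DRB1*13:01", "DRB1*13:02", "DRB1*13:03",
    "DRB1*13:05", "DRB1*14:01", "DRB1*15:01", "DRB1*15:02", "DRB1*16:01",
    "DRB1*16:02",
)

_AA = "ACDEFGHIKLMNPQRSTVWY"
#: one fixed codon per residue, for deterministic reverse translation
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

# non-indel class mix, proportional to the seven-class cohort breakdown
_SNV_CLASSES = (
    (VariantClass.MISSENSE, 26296),
    (VariantClass.SILENT, 8965),
    (VariantClass.NONSENSE, 2061),
    (VariantClass.SPLICE_SITE, 911),
    (VariantClass.NONSTOP_READTHROUGH, 98),
)
_CN_CHOICES = np.array([1, 2, 3, 4])
_CN_PROBS = np.array([0.08, 0.72, 0.14, 0.06])


@dataclass
class SynthConfig:
    """Knobs of the synthetic cohort generator (see module docstring)."""

    n_patients: int = 147
    n_genes: int = 300
    mean_mutations_per_patient: float = 274.0
    clonal_fraction: float = 0.54
    subclonal_ccf: float = 0.4
    purity_range: Tuple[float, float] = (0.3, 0.9)
    mean_depth: float = 80.0
    depth_dispersion: float = 10.0
    expression_zero_fraction: float = 0.3
    pon_contamination_rate: float = 0.02
    germline_flag_rate: float = 0.05
    indel_fraction: float = 0.047
    allele_panel: Tuple[str, ...] = DEFAULT_DRB1_PANEL
    planted_enriched_allele: Optional[str] = None
    planted_bias: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "clonal_fraction": self.clonal_fraction,
            "subclonal_ccf": self.subclonal_ccf,
            "expression_zero_fraction": self.expression_zero_fraction,
            "pon_contamination_rate": self.pon_contamination_rate,
            "germline_flag_rate": self.germline_flag_rate,
            "indel_fraction": self.indel_fraction,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.mean_depth < 1:
            raise ValueError("mean_depth must be >= 1")
        if self.mean_mutations_per_patient <= 0:
            raise ValueError(
                "mean_mutations_per_patient must be positive "
                "(a cohort with zero mutations has no clonal structure)"
            )
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"purity_range must satisfy 0 < low <= high <= 1, got {self.purity_range}")
        if self.planted_enriched_allele is not None and (
            self.planted_enriched_allele not in self.allele_panel
        ):
            raise ValueError("planted_enriched_allele must be in allele_panel")


@dataclass
class TruthManifest:
    """Ground truth aligned with the generated tables."""

    purity: Dict[str, float]
    mutation_ccf: List[float]  # aligned with cohort.mutations
    mutation_clonal: List[bool]
    expressed: Dict[str, bool]  # "patient_id|gene" -> read_count >= 3
    planted_enriched_allele: Optional[str]
    planted_bias: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class SyntheticCohort:
    """In-memory bundle of generated inputs plus the truth manifest."""

    mutations: List[MutationRecord]
    samples: List[SampleInfo]
    segments: List[CopyNumberSegment]
    expression: List[ExpressionRecord]
    proteome: Dict[str, str]  # transcript_id -> protein
    cds: Dict[str, str]  # transcript_id -> coding sequence
    truth: TruthManifest
    config: SynthConfig

    def write(self, outdir: Union[str, Path]) -> Dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "mutations": outdir / "mutations.tsv",
            "samples": outdir / "samples.tsv",
            "segments": outdir / "segments.seg",
            "expression": outdir / "expression.tsv",
            "proteome": outdir / "proteome.fasta",
            "cds": outdir / "cds.fasta",
            "truth": outdir / "truth.json",
        }
        io_formats.write_mutations(self.mutations, paths["mutations"])
        io_formats.write_samples(self.samples, paths["samples"])
        io_formats.write_segments(self.segments, paths["segments"])
        io_formats.write_expression(self.expression, paths["expression"])
        io_formats.write_fasta(self.proteome, paths["proteome"])
        io_formats.write_fasta(self.cds, paths["cds"])
        paths["truth"].write_text(self.truth.to_json() + "\n")
        return paths


def _gene_rng(seed: int, gene_idx: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 2, gene_idx]))


def _patient_rng(seed: int, patient_idx: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 1, patient_idx]))


def _make_proteome(config: SynthConfig) -> Tuple[Dict[str, str], Dict[str, str]]:
    proteome: Dict[str, str] = {}
    cds: Dict[str, str] = {}
    for g in range(config.n_genes):
        rng = _gene_rng(config.seed, g)
        length = int(rng.integers(100, 601))
        protein = "".join(rng.choice(list(_AA), size=length))
        tx = f"TX{g:04d}"
        proteome[tx] = protein
        cds[tx] = "".join(_CODON[a] for a in protein) + "TAA"
    return proteome, cds


def _draw_classification(rng: np.random.Generator, indel_fraction: float) -> VariantClass:
    if rng.random() < indel_fraction:
        # frameshift:inframe at the cohort's printed 1735:163 ratio
        return (VariantClass.FRAMESHIFT_INDEL
                if rng.random() < 1735 / (1735 + 163)
                else VariantClass.INFRAME_INDEL)
    total = sum(w for _, w in _SNV_CLASSES)
    u = rng.random() * total
    acc = 0.0
    for cls, w in _SNV_CLASSES:
        acc += w
        if u < acc:
            return cls
    return _SNV_CLASSES[0][0]  # pragma: no cover


_BASES = "ACGT"


def _protein_change(
    rng: np.random.Generator, cls: VariantClass, protein: str
) -> Tuple[str, int, str, str]:
    """Return (hgvs_p, residue_pos, ref_nt, alt_nt) for one mutation."""
    length = len(protein)
    pos = int(rng.integers(2, length))  # interior residue
    ref_aa = protein[pos - 1]
    ref_nt = _BASES[rng.integers(4)]
    alt_nt = _BASES[(rng.integers(3) + _BASES.index(ref_nt) + 1) % 4]
    if cls is VariantClass.MISSENSE:
        alt_aa = _AA[int(rng.integers(len(_AA)))]
        while alt_aa == ref_aa:
            alt_aa = _AA[int(rng.integers(len(_AA)))]
        return f"p.{ref_aa}{pos}{alt_aa}", pos, ref_nt, alt_nt
    if cls is VariantClass.SILENT:
        return f"p.{ref_aa}{pos}{ref_aa}", pos, ref_nt, alt_nt
    if cls is VariantClass.NONSENSE:
        return f"p.{ref_aa}{pos}*", pos, ref_nt, alt_nt
    if cls is VariantClass.FRAMESHIFT_INDEL:
        return f"p.{ref_aa}{pos}fs", pos, ref_nt + alt_nt, ref_nt
    if cls is VariantClass.INFRAME_INDEL:
        return f"p.{ref_aa}{pos}del", pos, ref_nt + "".join(
            _BASES[i] for i in rng.integers(0, 4, size=3)
        ), ref_nt
    # splice site / nonstop: no defined protein-level product in this model
    return "", pos, ref_nt, alt_nt


def generate_cohort(config: SynthConfig) -> SyntheticCohort:
    """Generate a full input bundle plus ground truth (deterministic in seed)."""
    config.validate()
    proteome, cds = _make_proteome(config)
    n_genes = config.n_genes
    gene_names = [f"GENE{g:04d}" for g in range(n_genes)]
    tx_names = [f"TX{g:04d}" for g in range(n_genes)]

    samples: List[SampleInfo] = []
    mutations: List[MutationRecord] = []
    segments: List[CopyNumberSegment] = []
    expression: List[ExpressionRecord] = []
    truth_purity: Dict[str, float] = {}
    truth_ccf: List[float] = []
    truth_clonal: List[bool] = []
    truth_expressed: Dict[str, bool] = {}

    disp = config.depth_dispersion
    p_nb = disp / (disp + config.mean_depth)

    for pi in range(config.n_patients):
        rng = _patient_rng(config.seed, pi)
        pid = f"PT{pi:04d}"
        lo, hi = config.purity_range
        purity = float(np.round(rng.uniform(lo, hi), 4))
        ploidy = float(np.round(np.clip(rng.normal(2.5, 0.5), 1.5, 5.5), 3))
        smoker = bool(rng.random() < 0.5)
        n_hla = 1 if rng.random() < 0.1 else 2
        alleles = tuple(sorted(rng.choice(config.allele_panel, size=n_hla, replace=False)))
        samples.append(SampleInfo(
            patient_id=pid, purity=purity, ploidy=ploidy, smoker=smoker,
            hla_class2_alleles=alleles,
        ))
        truth_purity[pid] = purity

        # one whole-chromosome copy-number segment per patient and chromosome
        chrom_cn = {
            str(c + 1): int(rng.choice(_CN_CHOICES, p=_CN_PROBS)) for c in range(22)
        }
        for chrom in sorted(chrom_cn, key=int):
            segments.append(CopyNumberSegment(
                patient_id=pid, chrom=chrom, start=1, end=260_000_000,
                total_copy_number=chrom_cn[chrom],
            ))

        # expression: zero-inflated negative binomial per (patient, gene)
        zero = rng.random(n_genes) < config.expression_zero_fraction
        nb = rng.negative_binomial(5, 5 / 55.0, size=n_genes)
        for g in range(n_genes):
            count = 0 if zero[g] else int(nb[g])
            expression.append(ExpressionRecord(pid, gene_names[g], count))
            truth_expressed[f"{pid}|{gene_names[g]}"] = count >= 3

        n_mut = int(rng.poisson(config.mean_mutations_per_patient))
        for _ in range(n_mut):
            g = int(rng.integers(n_genes))
            gene = gene_names[g]
            chrom = str(g % 22 + 1)
            cn = chrom_cn[chrom]
            cls = _draw_classification(rng, config.indel_fraction)
            hgvs, res_pos, ref_nt, alt_nt = _protein_change(rng, cls, proteome[tx_names[g]])
            clonal = bool(rng.random() < config.clonal_fraction)
            ccf = 1.0 if clonal else config.subclonal_ccf
            depth = max(1, int(rng.negative_binomial(disp, p_nb)))
            ev = expected_vaf(ccf, purity, max(cn, 1))
            alt = int(rng.binomial(depth, ev))
            pon = (float(np.round(rng.uniform(0.02, 0.2), 4))
                   if rng.random() < config.pon_contamination_rate else 0.0)
            mutations.append(MutationRecord(
                patient_id=pid, gene=gene, chrom=chrom,
                pos=(g + 1) * 1_000_000 + res_pos * 3,
                ref_allele=ref_nt, alt_allele=alt_nt, classification=cls,
                alt_count=alt, ref_count=depth - alt, pon_frequency=pon,
                in_dbsnp=bool(rng.random() < config.germline_flag_rate / 2),
                in_1000g=bool(rng.random() < config.germline_flag_rate / 2),
                transcript_id=tx_names[g], protein_change=hgvs,
            ))
            truth_ccf.append(ccf)
            truth_clonal.append(clonal)

    truth = TruthManifest(
        purity=truth_purity,
        mutation_ccf=truth_ccf,
        mutation_clonal=truth_clonal,
        expressed=truth_expressed,
        planted_enriched_allele=config.planted_enriched_allele,
        planted_bias=config.planted_bias,
    )
    return SyntheticCohort(
        mutations=mutations, samples=samples, segments=segments,
        expression=expression, proteome=proteome, cds=cds,
        truth=truth, config=config,
    )


#: Human KRAS (UniProt P01116) residues 1-31 — the G12 hotspot context
KRAS_FRAGMENT = "MTEYKLVVVGAGGVGKSALTIQLIQNHFVDE"

_KRAS_G12 = (("C", "25245350", "C", "A"), ("V", "25245351", "C", "A"),
             ("A", "25245351", "C", "G"), ("D", "25245350", "C", "T"),
             ("R", "25245351", "C", "G"), ("S", "25245351", "C", "T"))


def kras_fixture() -> Tuple[str, str]:
    """KRAS G12 hotspot fixture: (protein FASTA text, mutation TSV text).

    The protein is the N-terminal 31-residue KRAS fragment; the table holds
    one missense record per G12 substitution (C, V, A, D, R, S), each for a
    distinct synthetic patient. Both round-trip through the standard
    readers.
    """
    fasta = f">TX_KRAS\n{KRAS_FRAGMENT}\n"
    header = ("patient_id\tgene\tchrom\tpos\tref_allele\talt_allele\tclassification"
              "\talt_count\tref_count\tpon_frequency\tin_dbsnp\tin_1000g"
              "\ttranscript_id\tprotein_change")
    rows = [header]
    for i, (alt_aa, pos, ref_nt, alt_nt) in enumerate(_KRAS_G12, start=1):
        rows.append("\t".join([
            f"KRAS{i:02d}", "KRAS", "12", pos, ref_nt, alt_nt, "missense",
            "40", "60", "0.0", "false", "false", "TX_KRAS", f"p.G12{alt_aa}",
        ]))
    return fasta, "\n".join(rows) + "\n"
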