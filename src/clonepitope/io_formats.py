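"""Readers and writers for the pipeline's external tables.

All tables are plain TSV; FASTA goes through Biopython. Lines starting with
``#`` are treated as comments (run metadata headers). Readers validate every
row and raise :class:`SchemaError` / :class:`RecordError` rather than
silently coercing out-of-range values.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    CopyNumberSegment,
    ExpressionRecord,
    InvariantError,
    MutationRecord,
    SampleInfo,
    VariantClass,
)

__all__ = [
    "SchemaError",
    "RecordError",
    "CLASSIFICATION_ALIASES",
    "read_mutations",
    "write_mutations",
    "read_samples",
    "write_samples",
    "read_segments",
    "write_segments",
    "read_expression",
    "write_expression",
    "read_fasta",
    "write_fasta",
    "qc_samples",
    "dedupe_samples",
]


class SchemaError(ValueError):
    """The file is missing a required column or is otherwise malformed."""


class RecordError(ValueError):
    """A single row could not be parsed; carries the 1-based row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


#: Standard MAF Variant_Classification vocabulary -> internal seven classes.
#: Anything not listed here (and not already an internal name) errors loudly.
CLASSIFICATION_ALIASES: Dict[str, VariantClass] = {
    "Missense_Mutation": VariantClass.MISSENSE,
    "Silent": VariantClass.SILENT,
    "Nonsense_Mutation": VariantClass.NONSENSE,
    "Splice_Site": VariantClass.SPLICE_SITE,
    "Splice_Region": VariantClass.SPLICE_SITE,
    "Nonstop_Mutation": VariantClass.NONSTOP_READTHROUGH,
    "Read_Through": VariantClass.NONSTOP_READTHROUGH,
    "Frame_Shift_Ins": VariantClass.FRAMESHIFT_INDEL,
    "Frame_Shift_Del": VariantClass.FRAMESHIFT_INDEL,
    "In_Frame_Ins": VariantClass.INFRAME_INDEL,
    "In_Frame_Del": VariantClass.INFRAME_INDEL,
}

_MAF_COLUMNS = {
    "Tumor_Sample_Barcode": "patient_id",
    "Hugo_Symbol": "gene",
    "Chromosome": "chrom",
    "Start_Position": "pos",
    "Reference_Allele": "ref_allele",
    "Tumor_Seq_Allele2": "alt_allele",
    "Variant_Classification": "classification",
    "t_alt_count": "alt_count",
    "t_ref_count": "ref_count",
    "HGVSp_Short": "protein_change",
    "Transcript_ID": "transcript_id",
}

_CANONICAL_COLUMNS = [
    "patient_id",
    "gene",
    "chrom",
    "pos",
    "ref_allele",
    "alt_allele",
    "classification",
    "alt_count",
    "ref_count",
    "pon_frequency",
    "in_dbsnp",
    "in_1000g",
    "transcript_id",
    "protein_change",
]

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False, "t": True, "f": False, "": False,
}


def _read_tsv(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    return df


def _parse_bool(value: str, row: int, column: str) -> bool:
    key = str(value).strip().lower()
    if key not in _BOOL_MAP:
        raise RecordError(row, f"cannot parse boolean {column}={value!r}")
    return _BOOL_MAP[key]


def _parse_classification(value: str, row: int) -> VariantClass:
    value = value.strip()
    if value in CLASSIFICATION_ALIASES:
        return CLASSIFICATION_ALIASES[value]
    try:
        return VariantClass(value)
    except ValueError:
        raise RecordError(row, f"unmappable variant classification {value!r}") from None


def read_mutations(path: Union[str, Path], dialect: str = "tsv") -> List[MutationRecord]:
    """Read a somatic mutation table.

    ``dialect="maf_min"`` accepts TCGA-style MAF column names
    (Tumor_Sample_Barcode, Hugo_Symbol, ...); ``dialect="tsv"`` is the
    package's canonical column set (see :func:`write_mutations`).
    """
    if dialect not in ("maf_min", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _read_tsv(path)
    if dialect == "maf_min":
        missing = [c for c in _MAF_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = df.rename(columns=_MAF_COLUMNS)
    else:
        required = [c for c in _CANONICAL_COLUMNS
                    if c not in ("pon_frequency", "in_dbsnp", "in_1000g")]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records: List[MutationRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        row = row._asdict()
        try:
            records.append(
                MutationRecord(
                    patient_id=row["patient_id"],
                    gene=row["gene"],
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    ref_allele=row["ref_allele"],
                    alt_allele=row["alt_allele"],
                    classification=_parse_classification(row["classification"], i),
                    alt_count=int(row["alt_count"]),
                    ref_count=int(row["ref_count"]),
                    pon_frequency=float(row.get("pon_frequency", 0.0) or 0.0),
                    in_dbsnp=_parse_bool(row.get("in_dbsnp", "false"), i, "in_dbsnp"),
                    in_1000g=_parse_bool(row.get("in_1000g", "false"), i, "in_1000g"),
                    transcript_id=row.get("transcript_id", ""),
                    protein_change=row.get("protein_change", ""),
                )
            )
        except RecordError:
            raise
        except (InvariantError, ValueError) as exc:
            raise RecordError(i, str(exc)) from exc
    return records


def _fmt_float(x: float) -> str:
    return repr(float(x))


def write_mutations(records: Sequence[MutationRecord], path: Union[str, Path],
                    header_comment: Optional[str] = None) -> None:
    """Write mutations in the canonical TSV dialect (round-trip safe)."""
    lines = []
    if header_comment:
        lines.append(f"# {header_comment}")
    lines.append("\t".join(_CANONICAL_COLUMNS))
    for r in records:
        lines.append("\t".join([
            r.patient_id, r.gene, r.chrom, str(r.pos), r.ref_allele, r.alt_allele,
            r.classification.value, str(r.alt_count), str(r.ref_count),
            _fmt_float(r.pon_frequency), str(r.in_dbsnp).lower(),
            str(r.in_1000g).lower(), r.transcript_id, r.protein_change,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def _split_alleles(raw: str) -> Tuple[str, ...]:
    raw = raw.strip()
    if not raw:
        return ()
    return tuple(a.strip() for a in raw.replace(";", ",").split(",") if a.strip())


def read_samples(path: Union[str, Path]) -> List[SampleInfo]:
    """Read the per-sample purity/ploidy/HLA table."""
    df = _read_tsv(path)
    missing = [c for c in ("patient_id", "purity", "ploidy") if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    out: List[SampleInfo] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            smoker_raw = str(row.get("smoker", "")).strip()
            out.append(SampleInfo(
                patient_id=row["patient_id"],
                purity=float(row["purity"]),
                ploidy=float(row["ploidy"]),
                smoker=None if smoker_raw in ("", "NA") else _parse_bool(smoker_raw, i, "smoker"),
                hla_class2_alleles=_split_alleles(str(row.get("hla_class2_alleles", ""))),
                hla_class1_alleles=_split_alleles(str(row.get("hla_class1_alleles", ""))),
            ))
        except RecordError:
            raise
        except (InvariantError, ValueError) as exc:
            raise RecordError(i, str(exc)) from exc
    return out


def write_samples(samples: Sequence[SampleInfo], path: Union[str, Path],
                  header_comment: Optional[str] = None) -> None:
    lines = []
    if header_comment:
        lines.append(f"# {header_comment}")
    lines.append("patient_id\tpurity\tploidy\tsmoker\thla_class2_alleles\thla_class1_alleles")
    for s in samples:
        smoker = "" if s.smoker is None else str(s.smoker).lower()
        lines.append("\t".join([
            s.patient_id, _fmt_float(s.purity), _fmt_float(s.ploidy), smoker,
            ",".join(s.hla_class2_alleles), ",".join(s.hla_class1_alleles),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_segments(path: Union[str, Path]) -> List[CopyNumberSegment]:
    """Read a SEG-style total copy number table (1-based inclusive)."""
    df = _read_tsv(path)
    missing = [c for c in ("patient_id", "chrom", "start", "end", "total_cn")
               if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    out: List[CopyNumberSegment] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            out.append(CopyNumberSegment(
                patient_id=row["patient_id"], chrom=str(row["chrom"]),
                start=int(row["start"]), end=int(row["end"]),
                total_copy_number=int(row["total_cn"]),
            ))
        except (InvariantError, ValueError) as exc:
            raise RecordError(i, str(exc)) from exc
    _check_non_overlap(out)
    return out


def _check_non_overlap(segments: Sequence[CopyNumberSegment]) -> None:
    by_key: Dict[Tuple[str, str], List[CopyNumberSegment]] = {}
    for seg in segments:
        by_key.setdefault((seg.patient_id, seg.chrom), []).append(seg)
    for (pid, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise InvariantError(
                    f"overlapping segments for {pid}/{chrom}: "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )


def write_segments(segments: Sequence[CopyNumberSegment], path: Union[str, Path],
                   header_comment: Optional[str] = None) -> None:
    lines = []
    if header_comment:
        lines.append(f"# {header_comment}")
    lines.append("patient_id\tchrom\tstart\tend\ttotal_cn")
    for s in segments:
        lines.append(f"{s.patient_id}\t{s.chrom}\t{s.start}\t{s.end}\t{s.total_copy_number}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression(path: Union[str, Path]) -> List[ExpressionRecord]:
    df = _read_tsv(path)
    missing = [c for c in ("patient_id", "gene", "read_count") if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    out: List[ExpressionRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            out.append(ExpressionRecord(
                patient_id=row["patient_id"], gene=row["gene"],
                read_count=int(row["read_count"]),
            ))
        except (InvariantError, ValueError) as exc:
            raise RecordError(i, str(exc)) from exc
    return out


def write_expression(records: Sequence[ExpressionRecord], path: Union[str, Path],
                     header_comment: Optional[str] = None) -> None:
    lines = []
    if header_comment:
        lines.append(f"# {header_comment}")
    lines.append("patient_id\tgene\tread_count")
    for r in records:
        lines.append(f"{r.patient_id}\t{r.gene}\t{r.read_count}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path: Union[str, Path]) -> Dict[str, str]:
    """Read a FASTA file into an id -> sequence map (ids must be unique)."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise SchemaError(f"duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(sequences: Dict[str, str], path: Union[str, Path]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def qc_samples(
    samples: Sequence[SampleInfo],
    min_purity: float = 0.20,
    max_ploidy: float = 6.0,
) -> Tuple[List[SampleInfo], List[Tuple[SampleInfo, str]]]:
    """Apply the sample-level purity/ploidy gates.

    A sample is dropped iff purity < ``min_purity`` (strictly below 20% by
    default) or ploidy > ``max_ploidy`` (strictly above 6). Returns
    ``(kept, dropped)`` where each dropped entry carries a machine-readable
    reason, ``"purity"`` or ``"ploidy"``.
    """
    kept: List[SampleInfo] = []
    dropped: List[Tuple[SampleInfo, str]] = []
    for s in samples:
        if s.purity < min_purity:
            dropped.append((s, "purity"))
        elif s.ploidy > max_ploidy:
            dropped.append((s, "ploidy"))
        else:
            kept.append(s)
    return kept, dropped


def dedupe_samples(samples: Sequence[SampleInfo]) -> List[SampleInfo]:
    """Enforce one tumor sample per patient: keep the first, warn on the rest."""
    seen: Dict[str, SampleInfo] = {}
    for s in samples:
        if s.patient_id in seen:
            warnings.warn(
                f"duplicate sample for patient {s.patient_id!r}: keeping first occurrence",
                stacklevel=2,
            )
        else:
            seen[s.patient_id] = s
    return list(seen.values())
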