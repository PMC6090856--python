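"""End-to-end orchestration: QC -> filters -> clonality -> expression gate ->
peptide windows -> binding -> cohort statistics.

Every stage writes its intermediate TSV into the output directory, each
file carrying a ``# config_hash=... seed=...`` comment header, and the run
ends with a JSON summary of the stage funnel (counts are non-increasing
through the mutation gates by construction).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import yaml

from . import io_formats
from .binding import ToyPSSMPredictor, score_candidates
from .clonality import ClonalityModel
from .filters import filter_mutations
from .peptides import (
    CLASS_I_LENGTHS,
    CLASS_II_LENGTHS,
    apply_protein_change,
    enumerate_windows,
    expression_index,
    is_expressed,
)
from .stats import allele_enrichment, neo_peptide_counts, per_gene_frequency, per_patient_burden
from .synth import DEFAULT_DRB1_PANEL
from .types import BindingCall, MutationRecord, PeptideCandidate, VariantClass

__all__ = ["RunConfig", "StageError", "run_all"]

logger = logging.getLogger("clonepitope")

_PEPTIDE_CLASSES = (
    VariantClass.MISSENSE,
    VariantClass.FRAMESHIFT_INDEL,
    VariantClass.INFRAME_INDEL,
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class RunConfig:
    """Paths and thresholds of one pipeline run."""

    mutations: str = ""
    samples: str = ""
    segments: str = ""
    expression: str = ""
    proteome: str = ""
    cds: str = ""
    outdir: str = "clonepitope_out"
    mutation_dialect: str = "tsv"
    # thresholds (defaults are the analysis' standard gates)
    pon_max: float = 0.01
    min_depth: int = 10
    min_purity: float = 0.20
    max_ploidy: float = 6.0
    min_expr_reads: int = 3
    clonal_ccf_min: float = 0.95
    strong_nm: float = 50.0
    weak_nm: float = 500.0
    mhc_classes: Tuple[str, ...] = ("II",)
    allele_mode: str = "auto"  # typed | panel | auto
    allele_panel: Tuple[str, ...] = DEFAULT_DRB1_PANEL
    predictor: str = "toy"
    predictor_bias_allele: Optional[str] = None
    predictor_bias: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        if isinstance(cfg.allele_panel, list):
            cfg.allele_panel = tuple(cfg.allele_panel)
        if isinstance(cfg.mhc_classes, (list, str)):
            cfg.mhc_classes = tuple(cfg.mhc_classes) if not isinstance(cfg.mhc_classes, str) else (cfg.mhc_classes,)
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header(config: RunConfig) -> str:
    return f"config_hash={config.config_hash()} seed={config.seed}"


def _write_tsv(path: Path, header_cols: Sequence[str], rows: Sequence[Sequence],
               comment: str) -> None:
    lines = [f"# {comment}", "\t".join(header_cols)]
    for row in rows:
        lines.append("\t".join(str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")


def _candidates_for_mutation(
    m: MutationRecord,
    proteome: Dict[str, str],
    cds: Dict[str, str],
    mhc_classes: Sequence[str],
) -> Tuple[List[PeptideCandidate], Optional[str]]:
    """Peptide windows for one mutation, or (None-list, skip reason)."""
    if m.classification not in _PEPTIDE_CLASSES:
        return [], f"class:{m.classification.value}"
    if not m.protein_change:
        return [], "no_protein_change"
    wt = proteome.get(m.transcript_id)
    if wt is None:
        return [], "transcript_missing"
    edit = apply_protein_change(wt, m.protein_change, cds.get(m.transcript_id))
    if edit.no_peptide:
        return [], "no_peptide"
    out: List[PeptideCandidate] = []
    for mhc in mhc_classes:
        lengths = CLASS_II_LENGTHS if mhc == "II" else CLASS_I_LENGTHS
        out.extend(enumerate_windows(
            edit.mutant_protein, edit.mutant_span, lengths,
            mhc_class=mhc, patient_id=m.patient_id, gene=m.gene,
            protein_change=m.protein_change,
            wt_protein=wt if edit.kind == "substitution" else None,
        ))
    # windows identical to wild type carry no novel residue in practice only
    # for silent edits, which never reach this point
    return out, None


def run_all(config: RunConfig) -> Dict:
    """Execute the full pipeline; returns the JSON-serializable run summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    comment = _header(config)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path)
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    summary: Dict = {"config_hash": config.config_hash(), "seed": config.seed,
                     "stages": {}}
    try:
        # ---- load + sample QC -------------------------------------------
        stage = "qc"
        try:
            samples = io_formats.dedupe_samples(io_formats.read_samples(config.samples))
            kept_samples, dropped = io_formats.qc_samples(
                samples, config.min_purity, config.max_ploidy)
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        kept_ids = {s.patient_id for s in kept_samples}
        purity_by_patient = {s.patient_id: s.purity for s in kept_samples}
        summary["stages"]["samples_in"] = len(samples)
        summary["stages"]["samples_qc"] = len(kept_samples)
        _write_tsv(outdir / "samples_qc.tsv",
                   ["patient_id", "purity", "ploidy", "status", "reason"],
                   [[s.patient_id, s.purity, s.ploidy, "kept", ""] for s in kept_samples]
                   + [[s.patient_id, s.purity, s.ploidy, "dropped", r] for s, r in dropped],
                   comment)

        # ---- mutation filters -------------------------------------------
        stage = "filter"
        try:
            muts = io_formats.read_mutations(config.mutations, config.mutation_dialect)
            muts = [m for m in muts if m.patient_id in kept_ids]
            report = filter_mutations(muts, config.pon_max, config.min_depth)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        summary["stages"]["mutations_in"] = report.input_count
        summary["stages"]["mutations_filtered"] = len(report.kept)
        summary["removed_by_filter"] = dict(report.removed_by)
        summary["per_category_counts"] = {
            k.value: v for k, v in report.per_category_counts.items()}
        io_formats.write_mutations(report.kept, outdir / "mutations_filtered.tsv",
                                   header_comment=comment)
        (outdir / "filter_summary.json").write_text(report.summary_json() + "\n")

        # ---- clonality ---------------------------------------------------
        stage = "clonality"
        try:
            segments = io_formats.read_segments(config.segments) if config.segments else []
            model = ClonalityModel(clonal_ccf_min=config.clonal_ccf_min)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # uncovered-segment warnings go to the log
                model.fit(report.kept, purity_by_patient=purity_by_patient,
                          segments=segments)
            clonal_mask = model.predict()
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        clonal_muts = [m for m, c in zip(report.kept, clonal_mask) if c]
        summary["stages"]["mutations_clonal"] = len(clonal_muts)
        rows = []
        for m, post, cn in zip(report.kept, model.posteriors_, model.local_cn_):
            rows.append([m.patient_id, m.gene, m.protein_change, m.alt_count,
                         m.ref_count, purity_by_patient[m.patient_id], cn,
                         round(post.mode, 4), round(post.mean, 4),
                         round(post.ci95[0], 4), round(post.ci95[1], 4),
                         str(post.is_clonal).lower()])
        _write_tsv(outdir / "clonality.tsv",
                   ["patient_id", "gene", "protein_change", "alt", "ref", "purity",
                    "local_cn", "ccf_mode", "ccf_mean", "ci_low", "ci_high", "is_clonal"],
                   rows, comment)

        # ---- expression gate --------------------------------------------
        stage = "expression"
        try:
            if not config.expression or not Path(config.expression).exists():
                raise FileNotFoundError(
                    f"expression table not found: {config.expression!r}")
            expr_idx = expression_index(io_formats.read_expression(config.expression))
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        expressed = [m for m in clonal_muts
                     if is_expressed(m.gene, m.patient_id, expr_idx, config.min_expr_reads)]
        summary["stages"]["mutations_expressed_clonal"] = len(expressed)

        # ---- peptide windows --------------------------------------------
        stage = "peptides"
        try:
            proteome = io_formats.read_fasta(config.proteome) if config.proteome else {}
            cds = io_formats.read_fasta(config.cds) if config.cds else {}
            candidates: List[PeptideCandidate] = []
            skip_reasons: Dict[str, int] = {}
            n_with_candidates = 0
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for m in expressed:
                    cands, reason = _candidates_for_mutation(
                        m, proteome, cds, config.mhc_classes)
                    if reason is not None:
                        skip_reasons[reason] = skip_reasons.get(reason, 0) + 1
                    elif cands:
                        n_with_candidates += 1
                        candidates.extend(cands)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        summary["stages"]["mutations_with_candidates"] = n_with_candidates
        summary["peptide_candidates"] = len(candidates)
        summary["peptide_skip_reasons"] = skip_reasons
        _write_tsv(outdir / "candidates.tsv",
                   ["patient_id", "gene", "protein_change", "mhc_class", "length",
                    "sequence", "mutant_positions", "wt_sequence"],
                   [[c.patient_id, c.gene, c.protein_change, c.mhc_class, c.length,
                     c.sequence, ",".join(map(str, c.mutant_positions)),
                     c.wt_sequence or ""] for c in candidates],
                   comment)

        # ---- binding -----------------------------------------------------
        stage = "binding"
        try:
            if config.predictor != "toy":
                raise ValueError(
                    f"predictor {config.predictor!r} requires an external adapter; "
                    "use the library API for adapter-driven scoring")
            predictor = ToyPSSMPredictor(
                bias_allele=config.predictor_bias_allele, bias=config.predictor_bias)
            alleles_by_patient = {s.patient_id: s.hla_class2_alleles for s in kept_samples}
            calls = score_candidates(
                candidates, predictor, config.allele_panel, alleles_by_patient,
                mode=config.allele_mode, strong_nm=config.strong_nm,
                weak_nm=config.weak_nm)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        n_strong, n_weak = neo_peptide_counts(calls)
        summary["neo_peptides"] = {"strong": n_strong, "weak": n_weak,
                                   "total": n_strong + n_weak}
        summary["allele_mode"] = config.allele_mode
        summary["predictor"] = predictor.name
        _write_tsv(outdir / "binding.tsv",
                   ["patient_id", "gene", "protein_change", "allele", "peptide",
                    "ic50_nm", "category", "predictor_name"],
                   [[b.candidate.patient_id, b.candidate.gene,
                     b.candidate.protein_change, b.allele, b.candidate.sequence,
                     round(b.ic50_nm, 2), b.category, b.predictor_name]
                    for b in calls if b.is_binder],
                   comment)

        # ---- cohort statistics ------------------------------------------
        stage = "stats"
        try:
            binder_calls = [b for b in calls if b.is_binder]
            burden = per_patient_burden(binder_calls, expressed, kept_samples)
            genes = per_gene_frequency(binder_calls, expressed, len(kept_samples))
            enrich = allele_enrichment(
                binder_calls, [s.patient_id for s in kept_samples],
                list(config.allele_panel))
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        for name, df in (("per_patient.tsv", burden), ("per_gene.tsv", genes),
                         ("per_allele.tsv", enrich)):
            path = outdir / name
            path.write_text(f"# {comment}\n" + df.to_csv(sep="\t", index=False))
        summary["n_neoantigen_mutations"] = int(
            (burden["n_strong"] + burden["n_weak"]).sum())
        top = enrich.iloc[0]
        summary["top_allele"] = {"allele": top["allele"],
                                 "p_value": float(top["p_value"]),
                                 "q_value": float(top["q_value"])}
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")
        logger.info("run complete: %s", json.dumps(summary["stages"]))
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()
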