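"""Binding-affinity scoring of (peptide, HLA allele) pairs.

The scoring backend is pluggable. The built-in :class:`ToyPSSMPredictor` is
a deterministic position-specific weight matrix scorer that exists so the
whole pipeline and its statistics are runnable and testable with no external
binaries; it makes no claim of immunological accuracy and its name is
recorded on every call it produces. Real predictions are obtained through
:class:`ExternalPredictorAdapter`, a wrapper contract around an external
affinity-prediction executable.

IC50 categories follow the standard convention: strong binder below 50 nM,
weak binder below 500 nM, non-binder otherwise (both thresholds strict).
"""

from __future__ import annotations

import hashlib
import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.base import BaseEstimator

from .types import BindingCall, PeptideCandidate

__all__ = [
    "STRONG_NM",
    "WEAK_NM",
    "IC50_MAX_NM",
    "categorize",
    "ToyPSSMPredictor",
    "ExternalPredictorAdapter",
    "PredictorNotConfiguredError",
    "PredictorOutputError",
    "parse_predictor_output",
    "score_candidates",
]

STRONG_NM = 50.0
WEAK_NM = 500.0
#: raw score 0 maps to this IC50; raw score 1 maps to 1 nM
IC50_MAX_NM = 50000.0

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}


def categorize(ic50_nm: float, strong_nm: float = STRONG_NM, weak_nm: float = WEAK_NM) -> str:
    """Map an IC50 in nM to 'strong' / 'weak' / 'non_binder'."""
    if ic50_nm <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nm}")
    if ic50_nm < strong_nm:
        return "strong"
    if ic50_nm < weak_nm:
        return "weak"
    return "non_binder"


class PredictorNotConfiguredError(RuntimeError):
    """The external predictor executable is absent or misconfigured."""


class PredictorOutputError(ValueError):
    """The external predictor produced unparseable output."""

    def __init__(self, line_no: int, message: str):
        self.line_no = line_no
        super().__init__(f"line {line_no}: {message}")


class ToyPSSMPredictor(BaseEstimator):
    """Deterministic position-specific-weight-matrix affinity scorer.

    For each allele a 9 x 20 weight matrix with entries in [0, 1] is drawn
    from a generator seeded by SHA-256 of ``"{seed_namespace}|{allele}"``,
    so the same (peptide, allele) pair always scores identically. The raw
    score s of a peptide is the minimum over its 9-mer cores of the mean
    per-position weight (peptides of length 8 use the single 8-mer core
    against the first 8 matrix columns), and

        IC50 = 50000 ** (1 - s)   [nM]

    so s = 1 maps to 1 nM and s = 0 to 50000 nM. ``bias_allele`` multiplies
    that allele's raw scores by ``bias`` (capped at 1), which the synthetic
    cohorts use to plant a known enrichment effect.
    """

    name = "toy-pssm"
    supported_lengths = frozenset(range(8, 26))
    supported_alleles = "open"

    def __init__(self, seed_namespace: str = "clonepitope-v1",
                 bias_allele: Optional[str] = None, bias: float = 1.0):
        self.seed_namespace = seed_namespace
        self.bias_allele = bias_allele
        self.bias = bias
        self._matrices: Dict[str, np.ndarray] = {}

    def _matrix(self, allele: str) -> np.ndarray:
        if allele not in self._matrices:
            digest = hashlib.sha256(
                f"{self.seed_namespace}|{allele}".encode()
            ).digest()
            seed = int.from_bytes(digest[:4], "big")
            rng = np.random.default_rng(seed)
            self._matrices[allele] = rng.uniform(0.0, 1.0, size=(9, len(_AA)))
        return self._matrices[allele]

    @staticmethod
    def _encode(peptide: str) -> np.ndarray:
        try:
            return np.array([_AA_INDEX[a] for a in peptide], dtype=np.intp)
        except KeyError as exc:
            raise ValueError(f"non-standard residue {exc.args[0]!r} in {peptide!r}") from None

    def raw_score(self, peptide: str, allele: str) -> float:
        """Raw score s in [0, 1]; higher = stronger predicted binding."""
        return float(self.raw_score_batch([peptide], allele)[0])

    def raw_score_batch(self, peptides: Sequence[str], allele: str) -> np.ndarray:
        if not peptides:
            return np.empty(0)
        w = self._matrix(allele)
        scores = np.empty(len(peptides))
        by_len: Dict[int, List[int]] = {}
        for i, p in enumerate(peptides):
            if len(p) not in self.supported_lengths:
                raise ValueError(
                    f"peptide length {len(p)} unsupported by {self.name}: {p!r}"
                )
            by_len.setdefault(len(p), []).append(i)
        for L, idx in by_len.items():
            enc = np.stack([self._encode(peptides[i]) for i in idx])  # (n, L)
            core = min(9, L)
            n_cores = L - core + 1
            core_means = np.empty((len(idx), n_cores))
            for c in range(n_cores):
                cols = np.arange(core)
                core_means[:, c] = w[cols, enc[:, c : c + core]].mean(axis=1)
            scores[idx] = core_means.min(axis=1)
        if allele == self.bias_allele and self.bias != 1.0:
            scores = np.minimum(1.0, scores * self.bias)
        return scores

    @staticmethod
    def ic50_from_raw(s: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
        """Strictly decreasing map from raw score to IC50 in nM."""
        return IC50_MAX_NM ** (1.0 - np.asarray(s, dtype=float))

    def score(self, peptide: str, allele: str) -> float:
        """Predicted IC50 in nM for one (peptide, allele) pair."""
        return float(self.ic50_from_raw(self.raw_score(peptide, allele)))

    def score_batch(self, peptides: Sequence[str], allele: str) -> np.ndarray:
        return np.asarray(self.ic50_from_raw(self.raw_score_batch(peptides, allele)))


def score_candidates(
    candidates: Sequence[PeptideCandidate],
    predictor,
    allele_panel: Sequence[str],
    alleles_by_patient: Optional[Mapping[str, Sequence[str]]] = None,
    mode: str = "auto",
    strong_nm: float = STRONG_NM,
    weak_nm: float = WEAK_NM,
) -> List[BindingCall]:
    """Score every candidate against its allele set.

    ``mode="typed"`` scores each candidate against its patient's typed
    alleles, ``mode="panel"`` against the full panel for every patient
    (the all-alleles assumption used when typing is unavailable), and
    ``mode="auto"`` uses typed alleles when present, else the panel.
    """
    if mode not in ("auto", "typed", "panel"):
        raise ValueError(f"unknown allele mode {mode!r}")
    calls: List[BindingCall] = []
    # batch per allele so vectorized predictors stay fast
    groups: Dict[str, List[int]] = {}
    for i, cand in enumerate(candidates):
        if mode == "panel":
            alleles = tuple(allele_panel)
        else:
            typed = ()
            if alleles_by_patient is not None:
                typed = tuple(alleles_by_patient.get(cand.patient_id, ()))
            if mode == "typed":
                alleles = typed
            else:
                alleles = typed if typed else tuple(allele_panel)
        for allele in alleles:
            groups.setdefault(allele, []).append(i)
    for allele in sorted(groups):
        idx = groups[allele]
        if hasattr(predictor, "score_batch"):
            ic50s = predictor.score_batch([candidates[i].sequence for i in idx], allele)
        else:
            ic50s = [predictor.score(candidates[i].sequence, allele) for i in idx]
        for i, ic50 in zip(idx, ic50s):
            ic50 = float(ic50)
            calls.append(
                BindingCall(
                    candidate=candidates[i],
                    allele=allele,
                    ic50_nm=ic50,
                    category=categorize(ic50, strong_nm, weak_nm),
                    predictor_name=getattr(predictor, "name", type(predictor).__name__),
                )
            )
    return calls


def parse_predictor_output(
    lines: Iterable[str],
    candidates_by_peptide: Mapping[str, PeptideCandidate],
) -> List[BindingCall]:
    """Parse the adapter's tabular output contract into binding calls.

    Expected format: a header line ``peptide<TAB>allele<TAB>ic50_nm``
    followed by one TSV row per scored pair. Unknown peptides and
    non-numeric affinities raise :class:`PredictorOutputError` with the
    offending line number.
    """
    calls: List[BindingCall] = []
    it = iter(enumerate(lines, start=1))
    try:
        _, header = next(it)
    except StopIteration:
        raise PredictorOutputError(1, "empty predictor output") from None
    if [c.strip() for c in header.rstrip("\n").split("\t")] != ["peptide", "allele", "ic50_nm"]:
        raise PredictorOutputError(1, f"unexpected header {header.rstrip()!r}")
    for no, line in it:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise PredictorOutputError(no, f"expected 3 columns, got {len(parts)}")
        peptide, allele, raw = parts
        try:
            ic50 = float(raw)
        except ValueError:
            raise PredictorOutputError(no, f"non-numeric affinity {raw!r}") from None
        if peptide not in candidates_by_peptide:
            raise PredictorOutputError(no, f"unknown peptide {peptide!r}")
        calls.append(
            BindingCall(
                candidate=candidates_by_peptide[peptide],
                allele=allele,
                ic50_nm=ic50,
                category=categorize(ic50),
                predictor_name="external",
            )
        )
    return calls


@dataclass
class ExternalPredictorAdapter:
    """Wrapper contract for an external affinity-prediction executable.

    ``config`` keys: ``executable`` (path), optional ``allele_map``
    (pipeline allele name -> tool name), optional ``lengths``. The adapter
    writes a peptide list, invokes the tool, and parses its TSV output via
    :func:`parse_predictor_output`. It never falls back silently: a missing
    executable raises :class:`PredictorNotConfiguredError`.
    """

    config: Dict

    name = "external"

    def run(
        self,
        candidates: Sequence[PeptideCandidate],
        alleles: Sequence[str],
        workdir: Union[str, Path],
    ) -> List[BindingCall]:
        exe = self.config.get("executable")
        if not exe or (shutil.which(exe) is None and not Path(exe).exists()):
            raise PredictorNotConfiguredError(
                f"external predictor not installed (executable {exe!r} not found)"
            )
        workdir = Path(workdir)
        workdir.mkdir(parents=True, exist_ok=True)
        peptide_file = workdir / "peptides.txt"
        peptides = sorted({c.sequence for c in candidates})
        peptide_file.write_text("\n".join(peptides) + "\n")
        allele_map = self.config.get("allele_map", {})
        mapped = [allele_map.get(a, a) for a in alleles]
        result = subprocess.run(
            [str(exe), str(peptide_file), ",".join(mapped)],
            capture_output=True, text=True,
        )
        if result.returncode != 0:
            raise PredictorNotConfiguredError(
                f"external predictor exited with {result.returncode}: {result.stderr[:500]}"
            )
        by_peptide = {c.sequence: c for c in candidates}
        return parse_predictor_output(result.stdout.splitlines(), by_peptide)
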