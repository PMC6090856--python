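"""Expression gating, mutant protein construction, and peptide windows.

Mutant proteins are built from HGVS-p descriptions applied to a wild-type
protein (plus its CDS for frameshifts), and candidate epitope windows are
every k-mer that (a) lies inside the 29-residue context around the mutated
residues (14 flanking positions on each side, truncated at the termini) and
(b) contains at least one mutant position — windows without a mutant residue
are wild-type self peptides and are never emitted. Class II uses 15-mers,
class I 8-11-mers.

HGVS-p dialects supported (whitespace inside the description is ignored):
``p.G12C`` (substitution; ``*`` as the alternate residue is a stop gain),
``p.V73fs`` (frameshift), ``p.ELREA746del`` (deletion of the named
residues starting at the position), ``p.773_774insH`` (insertion between
two residues), ``p.709_710ET>D`` (deletion-insertion over a range).
Anything else raises :class:`HgvsError`.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

from Bio.Seq import Seq

from .types import ExpressionRecord, PeptideCandidate

__all__ = [
    "HgvsError",
    "ProteinChangeError",
    "ProteinEdit",
    "parse_hgvs_p",
    "apply_protein_change",
    "enumerate_windows",
    "is_expressed",
    "expression_index",
    "CLASS_II_LENGTHS",
    "CLASS_I_LENGTHS",
    "CONTEXT_FLANK",
]

CLASS_II_LENGTHS = (15,)
CLASS_I_LENGTHS = (8, 9, 10, 11)
#: 14 residues each side of the mutation = the 29-mer scanning context
CONTEXT_FLANK = 14


class HgvsError(ValueError):
    """The HGVS-p description could not be parsed."""


class ProteinChangeError(ValueError):
    """The description is inconsistent with the given protein/CDS."""


@dataclass
class ProteinEdit:
    """Result of applying a protein change.

    ``mutant_span`` is the 1-based inclusive interval of mutant-protein
    positions considered novel (empty == ``no_peptide``: the change produces
    no novel residues, e.g. an immediate stop).
    """

    mutant_protein: str
    mutant_span: Optional[Tuple[int, int]]
    kind: str

    @property
    def no_peptide(self) -> bool:
        return self.mutant_span is None

    def __iter__(self):  # allow (protein, span) unpacking
        yield self.mutant_protein
        yield self.mutant_span


_SUB_RE = re.compile(r"^p\.([A-Y])(\d+)([A-Y*])$")
_FS_RE = re.compile(r"^p\.([A-Y])(\d+)fs$")
_DEL_RE = re.compile(r"^p\.([A-Y]+)(\d+)del$")
_INS_RE = re.compile(r"^p\.(\d+)_(\d+)ins([A-Y]+)$")
_DELINS_RE = re.compile(r"^p\.(\d+)_(\d+)([A-Y]+)>([A-Y]+)$")


@dataclass
class ParsedChange:
    kind: str  # substitution | stop_gain | frameshift | deletion | insertion | delins
    pos: int
    ref: str = ""
    alt: str = ""
    end: int = 0


def parse_hgvs_p(change: str) -> ParsedChange:
    """Parse the supported HGVS-p dialects into a structured change."""
    norm = re.sub(r"\s+", "", change)
    m = _SUB_RE.match(norm)
    if m:
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        kind = "stop_gain" if alt == "*" else "substitution"
        return ParsedChange(kind=kind, pos=pos, ref=ref, alt=alt)
    m = _FS_RE.match(norm)
    if m:
        return ParsedChange(kind="frameshift", pos=int(m.group(2)), ref=m.group(1))
    m = _DEL_RE.match(norm)
    if m:
        seq, pos = m.group(1), int(m.group(2))
        return ParsedChange(kind="deletion", pos=pos, ref=seq, end=pos + len(seq) - 1)
    m = _INS_RE.match(norm)
    if m:
        a, b, ins = int(m.group(1)), int(m.group(2)), m.group(3)
        if b != a + 1:
            raise HgvsError(f"insertion positions must be adjacent: {change!r}")
        return ParsedChange(kind="insertion", pos=a, end=b, alt=ins)
    m = _DELINS_RE.match(norm)
    if m:
        a, b, ref, alt = int(m.group(1)), int(m.group(2)), m.group(3), m.group(4)
        if b - a + 1 != len(ref):
            raise HgvsError(
                f"range {a}_{b} does not match reference residues {ref!r}: {change!r}"
            )
        return ParsedChange(kind="delins", pos=a, end=b, ref=ref, alt=alt)
    raise HgvsError(f"unsupported HGVS-p description {change!r}")


def _check_ref(wt: str, pos: int, expected: str, change: str) -> None:
    if pos < 1 or pos + len(expected) - 1 > len(wt):
        raise ProteinChangeError(
            f"{change}: position {pos} outside protein of length {len(wt)}"
        )
    found = wt[pos - 1 : pos - 1 + len(expected)]
    if found != expected:
        raise ProteinChangeError(
            f"{change}: reference residue(s) {expected!r} at position {pos} "
            f"do not match protein ({found!r})"
        )


def _translate_to_stop(cds: str) -> str:
    usable = cds[: len(cds) - len(cds) % 3]
    prot = str(Seq(usable).translate())
    stop = prot.find("*")
    return prot if stop < 0 else prot[:stop]


def apply_protein_change(
    wt_protein: str,
    change: str,
    cds: Optional[str] = None,
) -> ProteinEdit:
    """Apply an HGVS-p change to a wild-type protein.

    Frameshifts require the in-frame CDS of the protein and are modeled as a
    single-base deletion at the first base of the stated codon, translating
    the shifted frame from that codon to the first stop; the novel span runs
    from the first altered residue to the new C-terminus. A change whose
    first shifted codon is already a stop yields no novel residues
    (``no_peptide``), as does a stop gain at the stated position.
    """
    parsed = parse_hgvs_p(change)
    wt = wt_protein.rstrip("*")

    if parsed.kind == "substitution":
        _check_ref(wt, parsed.pos, parsed.ref, change)
        mutant = wt[: parsed.pos - 1] + parsed.alt + wt[parsed.pos :]
        return ProteinEdit(mutant, (parsed.pos, parsed.pos), "substitution")

    if parsed.kind == "stop_gain":
        _check_ref(wt, parsed.pos, parsed.ref, change)
        return ProteinEdit(wt[: parsed.pos - 1], None, "stop_gain")

    if parsed.kind == "deletion":
        _check_ref(wt, parsed.pos, parsed.ref, change)
        mutant = wt[: parsed.pos - 1] + wt[parsed.end :]
        if not mutant:
            return ProteinEdit("", None, "deletion")
        # novel junction: the residues flanking the deleted block
        lo = max(1, parsed.pos - 1)
        hi = min(len(mutant), parsed.pos)
        return ProteinEdit(mutant, (lo, hi), "deletion")

    if parsed.kind == "insertion":
        if parsed.pos < 1 or parsed.end > len(wt):
            raise ProteinChangeError(
                f"{change}: insertion site outside protein of length {len(wt)}"
            )
        mutant = wt[: parsed.pos] + parsed.alt + wt[parsed.pos :]
        return ProteinEdit(
            mutant, (parsed.pos + 1, parsed.pos + len(parsed.alt)), "insertion"
        )

    if parsed.kind == "delins":
        _check_ref(wt, parsed.pos, parsed.ref, change)
        mutant = wt[: parsed.pos - 1] + parsed.alt + wt[parsed.end :]
        return ProteinEdit(
            mutant, (parsed.pos, parsed.pos + len(parsed.alt) - 1), "delins"
        )

    if parsed.kind == "frameshift":
        if cds is None:
            raise ProteinChangeError(f"{change}: frameshift requires the CDS")
        translated = _translate_to_stop(cds)
        if not translated.startswith(wt) and not wt.startswith(translated):
            raise ProteinChangeError(
                f"{change}: CDS is not in frame with the wild-type protein"
            )
        _check_ref(wt, parsed.pos, parsed.ref, change)
        base = 3 * (parsed.pos - 1)  # first base of the stated codon
        shifted = cds[:base] + cds[base + 1 :]
        mutant = _translate_to_stop(shifted)
        # first residue that actually differs from wild type
        first_novel = None
        for i in range(parsed.pos - 1, len(mutant)):
            if i >= len(wt) or mutant[i] != wt[i]:
                first_novel = i + 1
                break
        if first_novel is None or first_novel > len(mutant):
            return ProteinEdit(mutant, None, "frameshift")
        return ProteinEdit(mutant, (first_novel, len(mutant)), "frameshift")

    raise HgvsError(f"unsupported change kind {parsed.kind!r}")  # pragma: no cover


def _infer_mhc_class(lengths: Iterable[int]) -> str:
    lengths = set(lengths)
    if lengths <= {15}:
        return "II"
    if lengths <= set(CLASS_I_LENGTHS):
        return "I"
    raise ValueError(
        f"cannot infer MHC class from lengths {sorted(lengths)}; pass mhc_class"
    )


def enumerate_windows(
    mutant_protein: str,
    mutant_span: Tuple[int, int],
    lengths: Iterable[int],
    context_flank: int = CONTEXT_FLANK,
    mhc_class: Optional[str] = None,
    patient_id: str = "",
    gene: str = "",
    protein_change: str = "",
    wt_protein: Optional[str] = None,
) -> List[PeptideCandidate]:
    """Enumerate mutation-overlapping k-mer windows of a mutant protein.

    For each requested length L, emits every L-mer that fits inside the
    context interval (mutant span padded by ``context_flank`` on each side,
    truncated at the termini) and overlaps the mutant span. Windows are
    deduplicated by (sequence, length), keeping the smallest start; output
    is ordered by (length, start). Returns an empty list (with a warning)
    when the protein is shorter than the smallest requested length.
    """
    lengths = sorted(set(int(l) for l in lengths))
    if not lengths:
        return []
    if mhc_class is None:
        mhc_class = _infer_mhc_class(lengths)
    n = len(mutant_protein)
    span_lo, span_hi = mutant_span
    if not (1 <= span_lo <= span_hi <= n):
        raise ValueError(f"mutant span {mutant_span} outside protein of length {n}")
    if n < min(lengths):
        warnings.warn(
            f"protein of length {n} shorter than smallest window ({min(lengths)})",
            stacklevel=2,
        )
    ctx_lo = max(1, span_lo - context_flank)
    ctx_hi = min(n, span_hi + context_flank)
    out: List[PeptideCandidate] = []
    seen: Set[Tuple[str, int]] = set()
    for L in lengths:
        start_min = max(ctx_lo, span_lo - L + 1)
        start_max = min(ctx_hi - L + 1, span_hi)
        for s in range(start_min, start_max + 1):
            seq = mutant_protein[s - 1 : s - 1 + L]
            key = (seq, L)
            if key in seen:
                continue
            seen.add(key)
            mut_pos = tuple(
                p - s + 1 for p in range(max(s, span_lo), min(s + L - 1, span_hi) + 1)
            )
            wt_window = None
            if wt_protein is not None and span_lo == span_hi and len(wt_protein) >= s + L - 1:
                wt_window = wt_protein[s - 1 : s - 1 + L]
            out.append(
                PeptideCandidate(
                    patient_id=patient_id,
                    gene=gene,
                    protein_change=protein_change,
                    sequence=seq,
                    mhc_class=mhc_class,
                    mutant_positions=mut_pos,
                    wt_sequence=wt_window,
                    start=s,
                )
            )
    return out


def expression_index(expression: Sequence[ExpressionRecord]) -> Dict[Tuple[str, str], int]:
    """Build a (patient_id, gene) -> read_count lookup."""
    return {(r.patient_id, r.gene): r.read_count for r in expression}


def is_expressed(
    gene: str,
    patient_id: str,
    expression: Union[Sequence[ExpressionRecord], Dict[Tuple[str, str], int]],
    min_reads: int = 3,
) -> bool:
    """True iff the (patient, gene) RNA read count reaches ``min_reads``.

    A pair absent from the table counts as 0 reads (not expressed).
    """
    if isinstance(expression, dict):
        count = expression.get((patient_id, gene), 0)
    else:
        count = 0
        for r in expression:
            if r.patient_id == patient_id and r.gene == gene:
                count = r.read_count
                break
    return count >= min_reads
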