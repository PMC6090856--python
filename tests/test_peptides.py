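"""HGVS-p application, frameshift translation, window enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clonepitope.peptides import (
    CLASS_I_LENGTHS,
    HgvsError,
    ProteinChangeError,
    apply_protein_change,
    enumerate_windows,
    expression_index,
    is_expressed,
    parse_hgvs_p,
)
from clonepitope.synth import KRAS_FRAGMENT
from clonepitope.types import ExpressionRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------- expression

@pytest.mark.parametrize("count,expressed", [(3, True), (2, False), (0, False)])
def test_expression_threshold(count, expressed):
    table = [ExpressionRecord("P1", "KRAS", count)]
    assert is_expressed("KRAS", "P1", table) is expressed
    assert is_expressed("KRAS", "P1", expression_index(table)) is expressed


def test_absent_gene_counts_as_zero():
    assert is_expressed("TP53", "P1", [ExpressionRecord("P1", "KRAS", 100)]) is False


# ------------------------------------------------------------------- HGVS-p

@pytest.mark.parametrize(
    "text,kind",
    [
        ("p.G12C", "substitution"),
        ("p.G12 V", "substitution"),      # tolerate stray whitespace
        ("p.R175*", "stop_gain"),
        ("p.V73 fs", "frameshift"),
        ("p.ELREA746del", "deletion"),
        ("p.773_774insH", "insertion"),
        ("p.709_710ET>D", "delins"),
    ],
)
def test_parse_dialects(text, kind):
    assert parse_hgvs_p(text).kind == kind


@pytest.mark.parametrize("text", ["p.12G>C", "c.35G>T", "p.G12", "p.700_800ins"])
def test_parse_rejects_unknown_dialects(text):
    with pytest.raises(HgvsError):
        parse_hgvs_p(text)


def test_missense_application(kras_protein):
    edit = apply_protein_change(kras_protein, "p.G12C")
    assert edit.mutant_protein[11] == "C"
    assert edit.mutant_span == (12, 12)
    assert edit.mutant_protein[:11] == kras_protein[:11]


def test_reference_mismatch_names_position(kras_protein):
    with pytest.raises(ProteinChangeError, match="12"):
        apply_protein_change(kras_protein, "p.A12C")


def test_inframe_deletion_and_delins():
    prot = "MKELREATSPKA"
    edit = apply_protein_change(prot, "p.ELREA3del")
    assert edit.mutant_protein == "MKTSPKA"
    assert edit.mutant_span == (2, 3)  # junction residues
    edit = apply_protein_change("MAETKL", "p.3_4ET>D", None)
    assert edit.mutant_protein == "MADKL"
    assert edit.mutant_span == (3, 3)


def test_insertion():
    edit = apply_protein_change("MAKL", "p.2_3insWW")
    assert edit.mutant_protein == "MAWWKL"
    assert edit.mutant_span == (3, 4)


def test_frameshift_hand_translated():
    # wild type MKRW from ATG AAA CGT TGG TAA; deleting the first base of
    # codon 2 shifts to ATG AAC GTT GGT AA -> M N V G
    edit = apply_protein_change("MKRW", "p.K2fs", cds="ATGAAACGTTGGTAA")
    assert edit.mutant_protein == "MNVG"
    assert edit.mutant_span == (2, 4)
    assert not edit.no_peptide


def test_frameshift_immediate_stop_flags_no_peptide():
    # MVI from ATG GTA ATT TAA; the shifted second codon is TAA
    edit = apply_protein_change("MVI", "p.V2fs", cds="ATGGTAATTTAA")
    assert edit.no_peptide


def test_frameshift_requires_cds(kras_protein):
    with pytest.raises(ProteinChangeError, match="CDS"):
        apply_protein_change(kras_protein, "p.G12fs")


def test_stop_gain_yields_no_peptide():
    edit = apply_protein_change("MKRW", "p.R3*")
    assert edit.no_peptide and edit.mutant_protein == "MK"


# ------------------------------------------------------------------ windows

def naive_windows(protein, span, lengths, flank=14):
    """Independent double-loop enumerator used as the oracle."""
    lo, hi = span
    ctx_lo, ctx_hi = max(1, lo - flank), min(len(protein), hi + flank)
    seen = set()
    out = []
    for L in sorted(set(lengths)):
        for s in range(1, len(protein) - L + 2):
            e = s + L - 1
            if s < ctx_lo or e > ctx_hi:
                continue
            if e < lo or s > hi:
                continue
            key = (protein[s - 1:e], L)
            if key in seen:
                continue
            seen.add(key)
            out.append((s, protein[s - 1:e]))
    return out


def test_interior_missense_window_counts():
    protein = "".join(AA[i % 20] for i in range(80))
    prot = protein[:40] + "W" + protein[41:]
    cands = enumerate_windows(prot, (41, 41), [15])
    assert len(cands) == 15
    assert all("W" in c.sequence for c in cands)
    assert all(c.sequence[c.mutant_positions[0] - 1] == "W" for c in cands)
    class1 = enumerate_windows(prot, (41, 41), CLASS_I_LENGTHS)
    assert len(class1) == 8 + 9 + 10 + 11


def test_kras_g12c_windows(kras_protein):
    edit = apply_protein_change(kras_protein, "p.G12C")
    cands = enumerate_windows(
        edit.mutant_protein, edit.mutant_span, [15], wt_protein=kras_protein
    )
    assert len(cands) == 12  # N-terminal truncation
    assert "VGACGVGKSALTIQL" in {c.sequence for c in cands}
    # every emitted 15-mer differs from wild type at the mutant position
    assert all(c.sequence != c.wt_sequence for c in cands)


TABLE3_KRAS = {
    "p.G12C": "VGACGVGKSALTIQL",
    "p.G12V": "VVGAVGVGKSALTIQ",
    "p.G12A": "KLVVVGAAGVGKSAL",
    "p.G12D": "KLVVVGADGVGKSAL",
    "p.G12R": "VVVGARGVGKSALTI",
    "p.G12S": "KLVVVGASGVGKSAL",
}


@pytest.mark.parametrize("change,peptide", sorted(TABLE3_KRAS.items()))
def test_kras_g12_hotspot_peptides(kras_protein, change, peptide):
    """Each G12 variant's reported binder peptide is among its 15-mers."""
    edit = apply_protein_change(kras_protein, change)
    cands = enumerate_windows(edit.mutant_protein, edit.mutant_span, [15])
    assert peptide in {c.sequence for c in cands}


def test_windows_match_naive_enumerator_randomized():
    rng = np.random.default_rng(99)
    for _ in range(200):
        n = int(rng.integers(8, 120))
        protein = "".join(rng.choice(list(AA), size=n))
        lo = int(rng.integers(1, n + 1))
        hi = min(n, lo + int(rng.integers(0, 6)))
        lengths = rng.choice([8, 9, 10, 11, 15], size=int(rng.integers(1, 4)),
                             replace=False)
        lengths = [int(x) for x in lengths]
        got = enumerate_windows(protein, (lo, hi), lengths, mhc_class="II")
        expect = naive_windows(protein, (lo, hi), lengths)
        assert [(c.start, c.sequence) for c in got] == expect


@given(st.integers(1, 60), st.integers(0, 5), st.integers(0, 2**16))
@settings(derandomize=True, max_examples=60)
def test_windows_never_cross_termini(lo, width, seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(16, 100))
    protein = "".join(rng.choice(list(AA), size=n))
    lo = min(lo, n)
    hi = min(n, lo + width)
    for c in enumerate_windows(protein, (lo, hi), [9, 15], mhc_class="II"):
        assert 1 <= c.start and c.start + c.length - 1 <= n
        assert protein[c.start - 1 : c.start - 1 + c.length] == c.sequence


def test_short_protein_warns_and_returns_empty():
    with pytest.warns(UserWarning, match="shorter"):
        assert enumerate_windows("MKRW", (2, 2), [15]) == []
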