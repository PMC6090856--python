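"""Cohort-level summaries and allele enrichment statistics.

Counting units: a *neo-antigen mutation* is a mutation with at least one
binding window (counted once per patient, at the strongest category it
achieves); a *neo-peptide* is one distinct (patient, mutation, peptide
sequence, allele) binding call below the weak threshold. Per-patient
burdens are mutation-level (waterfall-style ordering); per-allele totals
are neo-peptide-level.

The allele enrichment test contrasts, for each allele ``a``, the per-patient
counts of neo-antigens presented by ``a`` against the per-(patient, other
allele) counts pooled over all remaining alleles, with a one-sided
Mann-Whitney U test (``a`` stochastically greater) and Benjamini-Hochberg
adjustment across alleles.
"""

from __future__ import annotations

import itertools
from math import comb, sqrt
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .types import BindingCall, MutationRecord, SampleInfo

__all__ = [
    "mann_whitney_one_sided",
    "bh_adjust",
    "per_patient_burden",
    "per_gene_frequency",
    "allele_enrichment",
    "neo_peptide_counts",
]

_EXACT_MAX_N = 12


def mann_whitney_one_sided(
    x: Sequence[float], y: Sequence[float], alternative: str = "greater"
) -> Tuple[float, float]:
    """One-sided Mann-Whitney U test (is ``x`` stochastically greater?).

    U is computed from midrank sums. When the pooled sample has at most 12
    observations and no ties, the p-value is exact (enumeration over all
    rank assignments); otherwise a normal approximation with tie correction
    and a 0.5 continuity correction is used.
    """
    if alternative != "greater":
        raise ValueError("only the 'greater' alternative is implemented")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks
    u = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    nn = n + m
    has_ties = len(np.unique(pooled)) < nn

    if nn <= _EXACT_MAX_N and not has_ties:
        # P(U >= u) over all C(n+m, n) equally likely rank assignments
        base = n * (n + 1) / 2.0
        count = 0
        total = comb(nn, n)
        for combo in itertools.combinations(range(1, nn + 1), n):
            if sum(combo) - base >= u - 1e-9:
                count += 1
        return u, count / total

    mu = n * m / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = n * m / 12.0 * ((nn + 1) - tie_term / (nn * (nn - 1)))
    if sigma2 <= 0:  # all observations identical
        return u, 0.5
    z = (u - mu - 0.5) / sqrt(sigma2)
    return u, float(min(max(norm.sf(z), 0.0), 1.0))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, returned in the input
    order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _mutation_key(call: BindingCall) -> Tuple[str, str, str]:
    c = call.candidate
    return (c.patient_id, c.gene, c.protein_change)


def _best_category_by_mutation(calls: Sequence[BindingCall]) -> Dict[Tuple[str, str, str], str]:
    rank = {"strong": 0, "weak": 1, "non_binder": 2}
    best: Dict[Tuple[str, str, str], str] = {}
    for call in calls:
        key = _mutation_key(call)
        if key not in best or rank[call.category] < rank[best[key]]:
            best[key] = call.category
    return best


def per_patient_burden(
    calls: Sequence[BindingCall],
    muts: Sequence[MutationRecord],
    samples: Optional[Sequence[SampleInfo]] = None,
) -> pd.DataFrame:
    """Per-patient neo-antigen mutation burden, descending by total burden.

    A mutation counts once per patient at the strongest binding category any
    of its windows/alleles achieves; ``n_other_mutations`` counts the
    patient's remaining mutations. Patients with zero binders still get a
    row.
    """
    best = _best_category_by_mutation(calls)
    patients = sorted({m.patient_id for m in muts} | {k[0] for k in best})
    strong: Dict[str, int] = {p: 0 for p in patients}
    weak: Dict[str, int] = {p: 0 for p in patients}
    for (pid, _, _), cat in best.items():
        if cat == "strong":
            strong[pid] += 1
        elif cat == "weak":
            weak[pid] += 1
    n_muts: Dict[str, int] = {p: 0 for p in patients}
    for m in muts:
        n_muts[m.patient_id] += 1
    smoker = {s.patient_id: s.smoker for s in samples} if samples else {}
    rows = []
    for pid in patients:
        n_binding = strong[pid] + weak[pid]
        rows.append({
            "patient_id": pid,
            "smoker": smoker.get(pid),
            "n_strong": strong[pid],
            "n_weak": weak[pid],
            "n_other_mutations": max(n_muts[pid] - n_binding, 0),
        })
    df = pd.DataFrame(
        rows, columns=["patient_id", "smoker", "n_strong", "n_weak", "n_other_mutations"]
    )
    df["_burden"] = df["n_strong"] + df["n_weak"]
    df = df.sort_values(["_burden", "patient_id"], ascending=[False, True], kind="stable")
    return df.drop(columns="_burden").reset_index(drop=True)


def neo_peptide_counts(calls: Sequence[BindingCall]) -> Tuple[int, int]:
    """Cohort (n_strong, n_weak) at the neo-peptide counting unit."""
    seen: Dict[Tuple, str] = {}
    for call in calls:
        if not call.is_binder:
            continue
        key = (*_mutation_key(call), call.candidate.sequence, call.allele)
        prev = seen.get(key)
        if prev is None or (call.category == "strong" and prev == "weak"):
            seen[key] = call.category
    n_strong = sum(1 for v in seen.values() if v == "strong")
    n_weak = sum(1 for v in seen.values() if v == "weak")
    return n_strong, n_weak


def per_gene_frequency(
    calls: Sequence[BindingCall],
    muts: Sequence[MutationRecord],
    n_patients: int,
) -> pd.DataFrame:
    """Per-gene neo-peptide counts and patient frequency.

    ``n_strong``/``n_weak`` count distinct binder neo-peptides in the gene,
    ``n_other`` its mutations with no binder, and ``freq_of_patients`` the
    fraction of the cohort carrying at least one predicted neo-antigen in
    the gene.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    genes = sorted({m.gene for m in muts} | {c.candidate.gene for c in calls})
    seen_peptides: Dict[Tuple, str] = {}
    binder_mutations: Dict[str, set] = {g: set() for g in genes}
    binder_patients: Dict[str, set] = {g: set() for g in genes}
    for call in calls:
        if not call.is_binder:
            continue
        g = call.candidate.gene
        key = (*_mutation_key(call), call.candidate.sequence, call.allele)
        prev = seen_peptides.get(key)
        if prev is None or (call.category == "strong" and prev == "weak"):
            seen_peptides[key] = call.category
        binder_mutations[g].add(_mutation_key(call))
        binder_patients[g].add(call.candidate.patient_id)
    strong = {g: 0 for g in genes}
    weak = {g: 0 for g in genes}
    for key, cat in seen_peptides.items():
        g = key[1]
        if cat == "strong":
            strong[g] += 1
        else:
            weak[g] += 1
    rows = []
    for g in genes:
        gene_mut_keys = {(m.patient_id, m.gene, m.protein_change)
                         for m in muts if m.gene == g}
        gene_mut_keys |= binder_mutations[g]
        n_other = len(gene_mut_keys - binder_mutations[g])
        rows.append({
            "gene": g,
            "n_strong": strong[g],
            "n_weak": weak[g],
            "n_other": n_other,
            "total": strong[g] + weak[g] + n_other,
            "freq_of_patients": len(binder_patients[g]) / n_patients,
        })
    df = pd.DataFrame(
        rows, columns=["gene", "n_strong", "n_weak", "n_other", "total", "freq_of_patients"]
    )
    return df.sort_values(
        ["freq_of_patients", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def allele_enrichment(
    calls: Sequence[BindingCall],
    patients: Sequence[str],
    alleles: Sequence[str],
) -> pd.DataFrame:
    """Per-allele neo-antigen enrichment via one-sided Mann-Whitney U.

    For each allele: x = that allele's per-patient neo-peptide counts; y =
    one count per (patient, other allele) pair. Rows carry the U statistic,
    one-sided p-value, and BH q-value, sorted by ascending p.
    """
    alleles = list(dict.fromkeys(alleles))
    if len(alleles) < 2:
        raise ValueError("allele enrichment needs at least 2 alleles")
    patients = list(dict.fromkeys(patients))
    counts: Dict[Tuple[str, str], int] = {}
    strong: Dict[str, int] = {a: 0 for a in alleles}
    weak: Dict[str, int] = {a: 0 for a in alleles}
    seen_peptides: Dict[Tuple, str] = {}
    for call in calls:
        if not call.is_binder or call.allele not in strong:
            continue
        key = (*_mutation_key(call), call.candidate.sequence, call.allele)
        prev = seen_peptides.get(key)
        if prev is None or (call.category == "strong" and prev == "weak"):
            seen_peptides[key] = call.category
    for key, cat in seen_peptides.items():
        pid, allele = key[0], key[-1]
        counts[(pid, allele)] = counts.get((pid, allele), 0) + 1
        if cat == "strong":
            strong[allele] += 1
        else:
            weak[allele] += 1
    rows = []
    for a in alleles:
        x = [counts.get((p, a), 0) for p in patients]
        y = [counts.get((p, b), 0) for p in patients for b in alleles if b != a]
        flagged = False
        if not x or not y:
            u, p_val, flagged = float("nan"), 1.0, True
        else:
            u, p_val = mann_whitney_one_sided(x, y, "greater")
        rows.append({
            "allele": a,
            "n_strong": strong[a],
            "n_weak": weak[a],
            "total": strong[a] + weak[a],
            "u_statistic": u,
            "p_value": p_val,
            "flagged": flagged,
        })
    df = pd.DataFrame(rows)
    df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    return df.sort_values(["p_value", "allele"], kind="stable").reset_index(drop=True)
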