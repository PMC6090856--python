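"""Cancer cell fraction posteriors and clonal/subclonal classification.

Model
-----
A mutation present in a fraction CCF of tumor cells, in a sample of purity
``a`` with local total copy number ``q`` at the site, is expected at variant
allele fraction

    E[VAF] = CCF * a / (2 * (1 - a) + a * q)

assuming one mutated copy per carrying cell (multiplicity 1) and a diploid
normal contaminant. The observed alt/ref read counts give a beta density
over VAF with shape parameters ``alt + 1`` and ``ref + 1``; evaluating that
density at E[VAF](CCF) and renormalizing over CCF in [0, 1] yields the CCF
posterior. A mutation is called clonal when the upper end of its central 95%
credible interval reaches the near-1 region (0.95 by default).

A simplified grid maximum-likelihood purity estimator is provided on the
same beta model: for each candidate purity, each mutation contributes a
mixture likelihood of a point clonal component (CCF = 1, prior weight ``w``)
and a uniform CCF component, and the estimate is the argmax of the summed
log likelihood over a purity grid. It is a desk-scale stand-in for joint
purity/ploidy/segment inference, not a re-implementation of one.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid
from scipy.stats import beta as beta_dist
from sklearn.base import BaseEstimator

from .types import CCFPosterior, CopyNumberSegment, MutationRecord, SampleInfo

__all__ = [
    "expected_vaf",
    "ccf_posterior",
    "classify_clonal",
    "estimate_purity",
    "lookup_local_cn",
    "ClonalityModel",
    "PurityGridMLE",
]


def expected_vaf(
    ccf: Union[float, np.ndarray], purity: float, local_cn: int
) -> Union[float, np.ndarray]:
    """Expected variant allele fraction of a mutation at the given CCF.

    Monotone increasing in ``ccf``. ``local_cn`` must be >= 1: a mutation in
    a fully deleted segment cannot be modeled.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if local_cn < 1:
        raise ValueError(f"local copy number must be >= 1, got {local_cn}")
    ccf = np.asarray(ccf, dtype=float) if not np.isscalar(ccf) else ccf
    return ccf * purity / (2.0 * (1.0 - purity) + purity * local_cn)


def _make_grid(resolution: float) -> np.ndarray:
    n = int(round(1.0 / resolution))
    return np.linspace(0.0, 1.0, n + 1)


def ccf_posterior(
    m: MutationRecord,
    purity: float,
    local_cn: int,
    grid_resolution: float = 0.01,
    clonal_ccf_min: float = 0.95,
) -> CCFPosterior:
    """Posterior density of the cancer cell fraction of one mutation.

    The unnormalized density at each grid point c is
    BetaPDF(expected_vaf(c); alt+1, ref+1); normalization is by trapezoid
    rule over the grid. Mode ties break to the smallest CCF. Raises
    ``ValueError`` when the density vanishes everywhere on the grid.
    """
    if m.depth < 1:
        raise ValueError(f"mutation {m.key()} has zero read depth")
    grid = _make_grid(grid_resolution)
    x = expected_vaf(grid, purity, local_cn)
    # work in log space: large depths underflow the linear-space pdf far
    # from the observed VAF
    logd = beta_dist.logpdf(x, m.alt_count + 1, m.ref_count + 1)
    top = np.max(logd)
    if not np.isfinite(top):
        raise ValueError(
            f"degenerate CCF posterior (all-zero density) for mutation {m.key()}"
        )
    dens = np.exp(logd - top)
    z = trapezoid(dens, grid)
    if z <= 0:
        raise ValueError(
            f"degenerate CCF posterior (zero mass) for mutation {m.key()}"
        )
    dens /= z
    mode = float(grid[int(np.argmax(dens))])  # argmax -> smallest on ties
    mean = float(trapezoid(grid * dens, grid))
    cdf = cumulative_trapezoid(dens, grid, initial=0.0)
    cdf /= cdf[-1]
    low = float(grid[int(np.searchsorted(cdf, 0.025, side="left"))])
    high = float(grid[int(np.searchsorted(cdf, 0.975, side="left"))])
    post = CCFPosterior(grid=grid, density=dens, mode=mode, mean=mean, ci95=(low, high))
    post.is_clonal = classify_clonal(post, clonal_ccf_min)
    return post


def classify_clonal(p: CCFPosterior, clonal_ccf_min: float = 0.95) -> bool:
    """Clonal iff the 95% credible interval reaches the near-1 region."""
    return p.ci95[1] >= clonal_ccf_min


def lookup_local_cn(
    segments: Sequence[CopyNumberSegment],
    patient_id: str,
    chrom: str,
    pos: int,
    default_cn: int = 2,
) -> int:
    """Total copy number of the segment covering a position.

    Falls back to the diploid default (with a warning) when no segment
    covers the site.
    """
    for seg in segments:
        if seg.patient_id == patient_id and seg.covers(chrom, pos):
            return seg.total_copy_number
    warnings.warn(
        f"no copy-number segment covers {patient_id}/{chrom}:{pos}; "
        f"assuming local_cn={default_cn}",
        stacklevel=2,
    )
    return default_cn


def estimate_purity(
    muts: Sequence[MutationRecord],
    local_cn: Union[int, Sequence[int]] = 2,
    purity_grid: Optional[np.ndarray] = None,
    clonal_prior_weight: float = 0.8,
    grid_resolution: float = 0.01,
) -> Tuple[float, np.ndarray]:
    """Grid maximum-likelihood purity estimate under the beta CCF model.

    Objective: purity_hat = argmax_a sum_m log L_m(a) with

        L_m(a) = w * BetaPDF(ev(1, a, q_m); alt+1, ref+1)
                 + (1 - w) * integral_0^1 BetaPDF(ev(c, a, q_m); ...) dc

    i.e. each mutation is clonal with prior weight ``w`` and otherwise has a
    uniform CCF. Returns ``(purity_hat, curve)`` where ``curve`` is an
    (n_grid, 2) array of (purity, log_likelihood) pairs. Warns below 10
    mutations.
    """
    if len(muts) == 0:
        raise ValueError("cannot estimate purity from an empty mutation list")
    if len(muts) < 10:
        warnings.warn(
            f"purity estimate from only {len(muts)} mutation(s) is low-confidence",
            stacklevel=2,
        )
    if purity_grid is None:
        purity_grid = np.round(np.arange(0.05, 1.0 + 1e-9, 0.01), 2)
    cn = np.broadcast_to(np.asarray(local_cn, dtype=float), (len(muts),)).copy()
    if np.any(cn < 1):
        raise ValueError("local copy number must be >= 1 for every mutation")
    alt = np.array([m.alt_count for m in muts], dtype=float)
    ref = np.array([m.ref_count for m in muts], dtype=float)
    ccf_grid = _make_grid(grid_resolution)
    w = clonal_prior_weight
    lls = np.empty(len(purity_grid))
    for i, a in enumerate(purity_grid):
        denom = 2.0 * (1.0 - a) + a * cn  # per mutation
        ev = ccf_grid[None, :] * (a / denom)[:, None]  # (n_mut, n_ccf)
        pdf = beta_dist.pdf(ev, (alt + 1)[:, None], (ref + 1)[:, None])
        clonal_term = pdf[:, -1]  # ev at CCF = 1
        uniform_term = trapezoid(pdf, ccf_grid, axis=1)
        lik = w * clonal_term + (1.0 - w) * uniform_term
        lls[i] = np.sum(np.log(np.clip(lik, 1e-300, None)))
    best = int(np.argmax(lls))
    curve = np.column_stack([purity_grid, lls])
    return float(purity_grid[best]), curve


class ClonalityModel(BaseEstimator):
    """Per-mutation CCF posteriors and clonal calls for a cohort.

    Parameters follow sklearn conventions; ``fit`` computes one
    :class:`~clonepitope.types.CCFPosterior` per mutation (``posteriors_``)
    and ``predict`` returns the boolean clonal labels.
    """

    def __init__(self, grid_resolution: float = 0.01, clonal_ccf_min: float = 0.95,
                 default_cn: int = 2):
        self.grid_resolution = grid_resolution
        self.clonal_ccf_min = clonal_ccf_min
        self.default_cn = default_cn

    def fit(
        self,
        X: Sequence[MutationRecord],
        y=None,
        *,
        purity_by_patient: Dict[str, float],
        segments: Sequence[CopyNumberSegment] = (),
    ) -> "ClonalityModel":
        seg_index: Dict[Tuple[str, str], List[CopyNumberSegment]] = {}
        for seg in segments:
            seg_index.setdefault((seg.patient_id, seg.chrom), []).append(seg)
        posteriors: List[CCFPosterior] = []
        local_cns: List[int] = []
        for m in X:
            covering = [s for s in seg_index.get((m.patient_id, m.chrom), ())
                        if s.covers(m.chrom, m.pos)]
            if covering:
                cn = covering[0].total_copy_number
            else:
                cn = self.default_cn
                warnings.warn(
                    f"no copy-number segment covers {m.patient_id}/{m.chrom}:{m.pos}; "
                    f"assuming local_cn={cn}",
                    stacklevel=2,
                )
            local_cns.append(cn)
            posteriors.append(
                ccf_posterior(
                    m,
                    purity=purity_by_patient[m.patient_id],
                    local_cn=cn,
                    grid_resolution=self.grid_resolution,
                    clonal_ccf_min=self.clonal_ccf_min,
                )
            )
        self.posteriors_ = posteriors
        self.local_cn_ = np.array(local_cns)
        return self

    def predict(self, X: Sequence[MutationRecord] = None) -> np.ndarray:
        """Boolean clonal labels for the mutations passed to ``fit``."""
        return np.array([p.is_clonal for p in self.posteriors_], dtype=bool)


class PurityGridMLE(BaseEstimator):
    """Sklearn-style wrapper around :func:`estimate_purity`.

    After ``fit``, ``purity_`` holds the estimate and ``loglik_curve_`` the
    (purity, log-likelihood) grid.
    """

    def __init__(self, clonal_prior_weight: float = 0.8, grid_resolution: float = 0.01):
        self.clonal_prior_weight = clonal_prior_weight
        self.grid_resolution = grid_resolution

    def fit(self, X: Sequence[MutationRecord], y=None,
            *, local_cn: Union[int, Sequence[int]] = 2) -> "PurityGridMLE":
        self.purity_, self.loglik_curve_ = estimate_purity(
            X, local_cn=local_cn,
            clonal_prior_weight=self.clonal_prior_weight,
            grid_resolution=self.grid_resolution,
        )
        return self
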