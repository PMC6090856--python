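"""Beta-model CCF posteriors, clonal classification, purity recovery."""

import math

import numpy as np
import pytest

from clonepitope.clonality import (
    ClonalityModel,
    PurityGridMLE,
    ccf_posterior,
    classify_clonal,
    estimate_purity,
    expected_vaf,
)
from clonepitope.types import CopyNumberSegment

from conftest import make_mut


def longhand_posterior(alt, ref, purity, cn, resolution=0.01):
    """Independent brute-force evaluation of the normalized CCF density.

    The beta density is written out from its closed form (gamma functions),
    evaluated at the expected VAF of each grid point, and normalized by the
    trapezoid rule.
    """
    grid = np.linspace(0.0, 1.0, int(round(1 / resolution)) + 1)
    a, b = alt + 1, ref + 1
    log_beta = math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)
    dens = np.empty_like(grid)
    for i, c in enumerate(grid):
        x = c * purity / (2 * (1 - purity) + purity * cn)
        if x <= 0.0:
            dens[i] = math.exp(-log_beta) if a == 1 else 0.0
        elif x >= 1.0:
            dens[i] = math.exp(-log_beta) if b == 1 else 0.0
        else:
            dens[i] = math.exp(
                (a - 1) * math.log(x) + (b - 1) * math.log(1 - x) - log_beta
            )
    z = np.trapezoid(dens, grid)
    return grid, dens / z


@pytest.mark.parametrize(
    "ccf,purity,cn,expected",
    [
        (1.0, 1.0, 2, 0.5),
        (1.0, 0.5, 2, 0.25),
        (0.0, 0.3, 3, 0.0),
        (0.5, 1.0, 2, 0.25),
    ],
)
def test_expected_vaf_values(ccf, purity, cn, expected):
    assert expected_vaf(ccf, purity, cn) == pytest.approx(expected)


def test_expected_vaf_rejects_deleted_segment():
    with pytest.raises(ValueError, match="copy number"):
        expected_vaf(0.5, 0.5, 0)


def test_expected_vaf_monotone_in_ccf():
    grid = np.linspace(0, 1, 50)
    v = expected_vaf(grid, 0.7, 3)
    assert np.all(np.diff(v) > 0)


def test_posterior_matches_longhand_oracle():
    rng = np.random.default_rng(2024)
    for _ in range(100):
        alt = int(rng.integers(0, 150))
        ref = int(rng.integers(0, 150))
        if alt + ref == 0:
            alt = 1
        purity = float(rng.uniform(0.1, 1.0))
        cn = int(rng.integers(1, 5))
        m = make_mut(alt_count=alt, ref_count=ref)
        post = ccf_posterior(m, purity, cn)
        grid, expect = longhand_posterior(alt, ref, purity, cn)
        assert np.max(np.abs(post.density - expect)) < 1e-8


def test_posterior_mode_examples():
    # VAF 0.5 at purity 1, cn 2 maps to CCF 1
    assert ccf_posterior(make_mut(alt_count=50, ref_count=50), 1.0, 2).mode == 1.0
    # VAF 0.25 maps to CCF 0.5
    assert ccf_posterior(make_mut(alt_count=10, ref_count=30), 1.0, 2).mode == pytest.approx(0.5, abs=0.02)


def test_posterior_normalization():
    post = ccf_posterior(make_mut(alt_count=7, ref_count=13), 0.6, 3)
    assert np.trapezoid(post.density, post.grid) == pytest.approx(1.0, abs=1e-6)


def test_posterior_mode_shifts_down_with_purity():
    m = make_mut(alt_count=20, ref_count=60)
    modes = [ccf_posterior(m, a, 2).mode for a in (0.4, 0.6, 0.8, 1.0)]
    assert all(b <= a for a, b in zip(modes, modes[1:]))


@pytest.mark.parametrize(
    "alt,ref,clonal",
    [
        (200, 200, True),   # posterior concentrated at CCF 1
        (30, 170, False),   # concentrated near 0.3
        (1, 1, True),       # wide posterior reaches the near-1 region
    ],
)
def test_classify_clonal_examples(alt, ref, clonal):
    post = ccf_posterior(make_mut(alt_count=alt, ref_count=ref), 1.0, 2)
    assert classify_clonal(post) is clonal
    assert post.is_clonal is clonal


def test_degenerate_posterior_raises():
    with pytest.raises(ValueError, match="depth"):
        ccf_posterior(make_mut(alt_count=0, ref_count=0), 1.0, 2)


def _simulate_clonal(rng, purity, n, depth_mean=80, cn=2):
    muts = []
    for _ in range(n):
        depth = max(1, int(rng.negative_binomial(10, 10 / (10 + depth_mean))))
        alt = int(rng.binomial(depth, expected_vaf(1.0, purity, cn)))
        muts.append(make_mut(alt_count=alt, ref_count=depth - alt))
    return muts


def test_purity_recovery_at_060():
    rng = np.random.default_rng(5)
    muts = _simulate_clonal(rng, 0.6, 200)
    hat, curve = estimate_purity(muts, local_cn=2)
    assert abs(hat - 0.6) <= 0.05
    assert curve.shape[1] == 2 and np.isfinite(curve[:, 1]).all()


def test_purity_recovery_at_boundary():
    rng = np.random.default_rng(6)
    hat, _ = estimate_purity(_simulate_clonal(rng, 1.0, 200), local_cn=2)
    assert hat >= 0.95


def test_single_mutation_warns_but_returns():
    with pytest.warns(UserWarning, match="low-confidence"):
        hat, curve = estimate_purity([make_mut(alt_count=20, ref_count=20)], local_cn=2)
    assert 0.05 <= hat <= 1.0


def test_empty_input_raises():
    with pytest.raises(ValueError, match="empty"):
        estimate_purity([])


def test_purity_estimator_class():
    rng = np.random.default_rng(7)
    est = PurityGridMLE().fit(_simulate_clonal(rng, 0.5, 150), local_cn=2)
    assert abs(est.purity_ - 0.5) <= 0.05


def test_clonality_model_uses_segments_and_default_cn():
    muts = [
        make_mut(patient_id="P1", chrom="1", pos=500, alt_count=45, ref_count=55),
        make_mut(patient_id="P1", chrom="2", pos=500, alt_count=45, ref_count=55),
    ]
    segs = [CopyNumberSegment("P1", "1", 1, 1000, 4)]
    model = ClonalityModel()
    with pytest.warns(UserWarning, match="no copy-number segment"):
        model.fit(muts, purity_by_patient={"P1": 0.9}, segments=segs)
    assert list(model.local_cn_) == [4, 2]
    assert model.predict().dtype == bool
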