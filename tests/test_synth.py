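"""Synthetic cohort generator: determinism, truth bookkeeping, realism."""

import numpy as np
import pytest

from clonepitope import io_formats
from clonepitope.clonality import expected_vaf
from clonepitope.peptides import apply_protein_change
from clonepitope.synth import (
    DEFAULT_DRB1_PANEL,
    KRAS_FRAGMENT,
    SynthConfig,
    generate_cohort,
    kras_fixture,
)
from clonepitope.types import VariantClass


def test_same_seed_gives_byte_identical_files(tmp_path):
    config = SynthConfig(n_patients=4, n_genes=25, mean_mutations_per_patient=15, seed=42)
    d1 = generate_cohort(config).write(tmp_path / "a")
    d2 = generate_cohort(config).write(tmp_path / "b")
    for name, p1 in d1.items():
        assert p1.read_bytes() == d2[name].read_bytes(), name


def test_adding_patients_preserves_earlier_ones():
    small = generate_cohort(SynthConfig(n_patients=3, n_genes=25,
                                        mean_mutations_per_patient=15, seed=9))
    big = generate_cohort(SynthConfig(n_patients=6, n_genes=25,
                                      mean_mutations_per_patient=15, seed=9))
    assert big.samples[:3] == small.samples
    assert [m for m in big.mutations if m.patient_id in {"PT0000", "PT0001", "PT0002"}] \
        == small.mutations


def test_clonal_fraction_bookkeeping():
    cohort = generate_cohort(SynthConfig(
        n_patients=10, n_genes=40, mean_mutations_per_patient=100,
        clonal_fraction=0.7, seed=3))
    labels = np.array(cohort.truth.mutation_clonal)
    assert len(labels) == len(cohort.mutations)
    assert abs(labels.mean() - 0.7) < 0.05  # binomial sampling around 0.7
    assert {c for l, c in zip(labels, cohort.truth.mutation_ccf) if not l} == {0.4}


def test_infeasible_config_rejected():
    with pytest.raises(ValueError, match="mean_mutations_per_patient"):
        SynthConfig(mean_mutations_per_patient=0).validate()
    with pytest.raises(ValueError, match="purity_range"):
        SynthConfig(purity_range=(0.0, 0.5)).validate()
    with pytest.raises(ValueError, match="allele_panel"):
        SynthConfig(planted_enriched_allele="DRB1*99:99").validate()


def test_outputs_roundtrip_through_readers(cohort_dir):
    muts = io_formats.read_mutations(cohort_dir["mutations"], dialect="tsv")
    samples = io_formats.read_samples(cohort_dir["samples"])
    segs = io_formats.read_segments(cohort_dir["segments"])
    expr = io_formats.read_expression(cohort_dir["expression"])
    prot = io_formats.read_fasta(cohort_dir["proteome"])
    assert muts and samples and segs and expr and prot


def test_every_generated_hgvs_parses_against_proteome(small_cohort):
    checked = 0
    for m in small_cohort.mutations:
        if not m.protein_change:
            assert m.classification in (VariantClass.SPLICE_SITE,
                                        VariantClass.NONSTOP_READTHROUGH)
            continue
        edit = apply_protein_change(
            small_cohort.proteome[m.transcript_id], m.protein_change,
            small_cohort.cds.get(m.transcript_id))
        assert edit.mutant_protein is not None
        checked += 1
    assert checked > 50


def test_simulated_vaf_concentrates_at_model_expectation():
    """Clonal mutations at purity a, cn 2 have mean VAF ~ a/2."""
    purity = 0.8
    cohort = generate_cohort(SynthConfig(
        n_patients=6, n_genes=40, mean_mutations_per_patient=200,
        clonal_fraction=1.0, purity_range=(purity, purity),
        mean_depth=100, seed=21))
    seg_cn = {(s.patient_id, s.chrom): s.total_copy_number for s in cohort.segments}
    tot_alt = tot_expect = 0.0
    for m, ccf in zip(cohort.mutations, cohort.truth.mutation_ccf):
        cn = seg_cn[(m.patient_id, m.chrom)]
        tot_alt += m.alt_count
        tot_expect += m.depth * expected_vaf(ccf, purity, cn)
    # total alt reads concentrate around their expectation; 2 SE band
    assert abs(tot_alt - tot_expect) < 2 * np.sqrt(tot_expect)


def test_kras_fixture_contents(tmp_path):
    fasta, table = kras_fixture()
    (tmp_path / "kras.fasta").write_text(fasta)
    (tmp_path / "kras.tsv").write_text(table)
    prot = io_formats.read_fasta(tmp_path / "kras.fasta")
    muts = io_formats.read_mutations(tmp_path / "kras.tsv", dialect="tsv")
    assert prot["TX_KRAS"] == KRAS_FRAGMENT
    assert len(muts) == 6
    assert {m.protein_change for m in muts} == {
        "p.G12C", "p.G12V", "p.G12A", "p.G12D", "p.G12R", "p.G12S"}
    # the G12C mutant fragment reads the reported binder at residues 9-23
    edit = apply_protein_change(prot["TX_KRAS"], "p.G12C")
    assert edit.mutant_protein[8:23] == "VGACGVGKSALTIQL"


def test_default_panel_is_valid():
    assert len(DEFAULT_DRB1_PANEL) == 31
    assert all(a.startswith("DRB1*") for a in DEFAULT_DRB1_PANEL)
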