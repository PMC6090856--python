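import numpy as np
import pytest

from clonepitope.types import MutationRecord, PeptideCandidate, BindingCall, VariantClass
from clonepitope.synth import KRAS_FRAGMENT, SynthConfig, generate_cohort


def make_mut(
    patient_id="PT0000",
    gene="GENE0001",
    chrom="1",
    pos=1000,
    ref="A",
    alt="C",
    classification=VariantClass.MISSENSE,
    alt_count=30,
    ref_count=70,
    **kwargs,
):
    return MutationRecord(
        patient_id=patient_id, gene=gene, chrom=chrom, pos=pos,
        ref_allele=ref, alt_allele=alt, classification=classification,
        alt_count=alt_count, ref_count=ref_count, **kwargs,
    )


def make_call(patient_id, allele, ic50, gene="GENE0001", protein_change="p.A2C",
              sequence="ACDEFGHIKLMNPQR"):
    cand = PeptideCandidate(
        patient_id=patient_id, gene=gene, protein_change=protein_change,
        sequence=sequence, mhc_class="II", mutant_positions=(8,),
    )
    category = "strong" if ic50 < 50 else "weak" if ic50 < 500 else "non_binder"
    return BindingCall(candidate=cand, allele=allele, ic50_nm=ic50,
                       category=category, predictor_name="toy-pssm")


@pytest.fixture(scope="session")
def kras_protein():
    return KRAS_FRAGMENT


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic synthetic cohort shared across tests."""
    config = SynthConfig(
        n_patients=8, n_genes=40, mean_mutations_per_patient=25,
        allele_panel=tuple(f"DRB1*{i:02d}:01" for i in range(1, 7)),
        seed=11,
    )
    return generate_cohort(config)


@pytest.fixture()
def cohort_dir(small_cohort, tmp_path):
    return small_cohort.write(tmp_path / "bundle")
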