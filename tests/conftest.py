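import numpy as np
import pytest

from adalink.germline import GermlineAllele, GermlineReference, parse_allele_name
from adalink.simulate import SimulationConfig, simulate_study


def make_allele(name: str, seq: str) -> GermlineAllele:
    return GermlineAllele(parse_allele_name(name), seq)


@pytest.fixture(scope="session")
def toy_reference() -> GermlineReference:
    """Hand-built reference: 2 heavy V genes (one with 2 alleles), J genes,
    and a kappa/lambda light side."""
    return GermlineReference(
        [
            make_allele("IGHV1-1*01", "QVQLVQSGAEVKKPGASVKVSCKASGYTFT"),
            make_allele("IGHV1-1*02", "QVQLVQSGAEVKKPGASVRVSCKASGYAFT"),
            make_allele("IGHV2-1*01", "EVQLVESGGGLVQPGGSLRLSCAASGFTFS"),
            make_allele("IGHJ1*01", "WGQGTLVTVSS"),
            make_allele("IGHJ2*01", "WGRGTLVAVSS"),
            make_allele("IGKV1-1*01", "DIQMTQSPSSLSASVGDRVTITCRASQSIS"),
            make_allele("IGLV1-1*01", "QSVLTQPPSVSGAPGQRVTISCTGSSSNIG"),
            make_allele("IGKJ1*01", "FGQGTKVEIK"),
            make_allele("IGLJ1*01", "FGGGTKLTVL"),
        ]
    )


@pytest.fixture(scope="session")
def small_study():
    """A small but complete simulated study shared across tests."""
    config = SimulationConfig(seed=11, n_subjects=30, reads_per_subject=2500)
    return simulate_study(config)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
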