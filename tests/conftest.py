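import numpy as np
import pandas as pd
import pytest

import eqtlcross as ec


@pytest.fixture(scope="session")
def paper_pedigree():
    """The study-scale cross: 4x16 F0, 56 F1, 44 litters x 4 F2."""
    return ec.simulate_pedigree(4, 16, 56, 44, 4, seed=11)


@pytest.fixture(scope="session")
def small_map():
    """5 chromosomes x 6 markers, 20 cM spacing."""
    return ec.LinkageMap.uniform(5, 6, 20.0)


@pytest.fixture(scope="session")
def paper_genotypes(paper_pedigree, small_map):
    return ec.simulate_genotypes(paper_pedigree, small_map,
                                 informativeness=1.0, seed=12)


@pytest.fixture(scope="session")
def paper_inference(paper_pedigree, paper_genotypes, small_map):
    return ec.infer_marker_origins(paper_pedigree, paper_genotypes, small_map)


@pytest.fixture(scope="session")
def marker_grid(small_map):
    return ec.build_scan_grid(small_map, k_intermediate=0)


@pytest.fixture(scope="session")
def paper_ca(paper_inference, marker_grid):
    return ec.compute_ca_matrix(paper_inference, marker_grid)


@pytest.fixture(scope="session")
def null_study(paper_pedigree, paper_genotypes, small_map):
    """An expression study with no eQTL anywhere."""
    truth = ec.make_truth(small_map, 40, frac_eqtl=0.0, seed=13)
    study, truth, channel_map = ec.simulate_expression_study(
        paper_pedigree, paper_genotypes, truth, seed=14)
    return study, truth, channel_map


@pytest.fixture(scope="session")
def eqtl_study(paper_pedigree, paper_genotypes, small_map):
    """An expression study where half the probes carry a strong eQTL."""
    truth = ec.make_truth(small_map, 40, frac_eqtl=0.5, effect_size=0.8,
                          seed=15)
    study, truth, channel_map = ec.simulate_expression_study(
        paper_pedigree, paper_genotypes, truth, seed=16)
    return study, truth, channel_map
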