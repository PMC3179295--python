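import numpy as np
import pytest

from hipshape.model import fit_shape_model, score_subjects
from hipshape.procrustes import generalized_procrustes
from hipshape.simulate import make_template, preset, sample_cohort


@pytest.fixture(scope="session")
def template():
    lm, cfg = make_template()
    return lm, cfg


@pytest.fixture(scope="session")
def tiny_cohort():
    return sample_cohort(preset("tiny", seed=7))


@pytest.fixture(scope="session")
def paper_cohort():
    return sample_cohort(preset("paper", seed=3))


@pytest.fixture(scope="session")
def paper_aligned(paper_cohort):
    return generalized_procrustes(paper_cohort.landmarks)


@pytest.fixture(scope="session")
def paper_model(paper_aligned):
    return fit_shape_model(paper_aligned, m=10)


@pytest.fixture(scope="session")
def paper_scores(paper_model, paper_aligned):
    return score_subjects(paper_model, paper_aligned)


@pytest.fixture(scope="session")
def paper_data(paper_cohort, paper_scores):
    """Covariates merged with estimated SD-unit mode scores."""
    return paper_cohort.covariates.merge(paper_scores.frame(), on="subject_id")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
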