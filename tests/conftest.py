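"""Shared fixtures: small hand-built matrices and session-scoped cohorts."""

import numpy as np
import pandas as pd
import pytest

import ntpkit


@pytest.fixture
def tiny_emat():
    """3 genes x 2 samples, hand-checkable."""
    return pd.DataFrame(
        [[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )


@pytest.fixture
def tiny_template():
    return ntpkit.TemplateSet({"A": ["g1", "g2"], "B": ["g3"]})


@pytest.fixture(scope="session")
def default_cohort():
    """A tumor cohort at generator defaults with its planted truth."""
    return ntpkit.simulate_cohort(seed=101)


@pytest.fixture(scope="session")
def default_predictions(default_cohort):
    emat, truth = default_cohort
    preds = ntpkit.ntp_classify(emat, truth.template, seed=5)
    return preds


@pytest.fixture(scope="session")
def trio():
    """The three-dataset study design: tumor cohort with stroma, cell-line
    panel without, and a paired tumor/xenograft contrast, all from the same
    generative process."""
    tumor, truth = ntpkit.simulate_cohort(seed=11)
    cells, _ = ntpkit.simulate_cohort(stromal_present=False, seed=12)
    paired_tumor, paired_xeno, _ = ntpkit.simulate_model_pair(seed=13)
    return {
        "tumor": tumor,
        "truth": truth,
        "cells": cells,
        "paired_tumor": paired_tumor,
        "paired_xeno": paired_xeno,
    }


@pytest.fixture(scope="session")
def derived_template(trio):
    """Template from the full three-filter pipeline on the trio."""
    selector = ntpkit.TemplateSelector(
        cell_lines=trio["cells"],
        paired_tumors=trio["paired_tumor"],
        paired_xenografts=trio["paired_xeno"],
    )
    selector.fit(trio["tumor"].T, trio["truth"].labels.loc[trio["tumor"].columns])
    return selector
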