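import dataclasses

import numpy as np
import pytest

from orogut import (AbundanceTable, filter_low_abundance, generate_cohort,
                    to_relative)
from orogut.synthetic_cohort import preset


def make_table(values, site="gut", mode="counts", samples=None, taxa=None,
               taxonomy=None):
    values = np.asarray(values, dtype=float)
    n, t = values.shape
    samples = samples or [f"S{i+1}" for i in range(n)]
    taxa = taxa or [f"T{j+1}" for j in range(t)]
    return AbundanceTable(tuple(samples), tuple(taxa), values, site=site,
                          mode=mode, taxonomy=taxonomy)


@pytest.fixture(scope="session")
def study_cohort():
    """One paired cohort at the full study design (n=83, depth 66,902)."""
    spec = dataclasses.replace(preset("study"), seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def gut_filtered(study_cohort):
    cohort, _ = study_cohort
    return filter_low_abundance(to_relative(cohort.gut))


def cohort_at(seed, name="study", **overrides):
    spec = dataclasses.replace(preset(name), seed=seed, **overrides)
    return generate_cohort(spec)
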