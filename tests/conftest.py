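import numpy as np
import pytest

from mlof.model import MlofModel
from mlof.synthetic import CohortSpec, make_cohort, make_toy_structure


def brute_force_edc(model, variants, plddt_min=70.0):
    """Independent O(n^2) double-loop EDC oracle; returns the two means and EDC."""
    kept = [r for r in model.residues if r.plddt >= plddt_min]
    disease = variants.positions
    d_dis, d_non = [], []
    for ri in kept:
        best_dis = best_non = None
        for rj in kept:
            if rj is ri:
                continue
            d = sum((a - b) ** 2 for a, b in zip(ri.ca_xyz, rj.ca_xyz)) ** 0.5
            if rj.position in disease:
                if best_dis is None or d < best_dis:
                    best_dis = d
            else:
                if best_non is None or d < best_non:
                    best_non = d
        if best_dis is not None and best_non is not None:
            d_dis.append(best_dis)
            d_non.append(best_non)
    mean_dis = sum(d_dis) / len(d_dis)
    mean_non = sum(d_non) / len(d_non)
    return mean_dis, mean_non, np.log10(mean_dis) / np.log10(mean_non)


@pytest.fixture
def edc_oracle():
    return brute_force_edc


@pytest.fixture(scope="session")
def cohort_df():
    df, _ = make_cohort(CohortSpec(seed=1))
    return df


@pytest.fixture(scope="session")
def fitted_reference(cohort_df):
    return MlofModel.from_dataframe(cohort_df).fit()


@pytest.fixture(scope="session")
def globule80():
    return make_toy_structure(80, "globule", 90.0, seed=11, protein_id="SYN1")
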