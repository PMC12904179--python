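import pandas as pd
import pytest

import dietspan as ds


def make_analysis_cohort(n=4000, seed=11, **overrides):
    """Model-ready cohort straight from the generator (no exclusions), with
    PRS tertiles attached; the latent diet factor serves as the exposure."""
    params = ds.SimulationParams(n_participants=n, seed=seed, **overrides)
    c = ds.generate_cohort(params)
    coh = c.participants.copy()
    coh["prs_tertile"] = ds.prs_tertiles(
        pd.Series(coh["prs_true"], index=coh.index)
    ).to_numpy()
    return coh, params


@pytest.fixture(scope="session")
def analysis_cohort():
    """Mid-size cohort with the default protective diet and PRS effects."""
    return make_analysis_cohort()


@pytest.fixture(scope="session")
def intake_profiles():
    """Averaged intake profiles for ~200 retained participants."""
    params = ds.SimulationParams(
        n_participants=320,
        seed=7,
        implausible_energy_frac=0.0,
        prevalent_disease_frac=0.0,
    )
    c = ds.generate_cohort(params)
    retained, _ = ds.apply_exclusions(c.participants, c.assessments)
    kept = c.assessments[c.assessments["pid"].isin(retained["pid"])]
    return ds.average_assessments(kept).merge(retained[["pid", "sex"]], on="pid")
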