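import numpy as np
import pandas as pd
import pytest

from twinmediate import SimulationConfig, generate_cohort


def single_mediator_config(**overrides) -> SimulationConfig:
    """One-mediator generating setup where the mediator is the factor
    itself (unit loading), convenient for mediation recovery checks."""
    base = dict(
        n_pairs_mz=1000, n_pairs_dz=1000,
        ace_mediators=((0.3, 0.0, 0.7),),
        pleiotropic_mediators=(0.0,),
        factor_loadings=((1.0, 0.0),),
        a_paths=(0.3, 0.0), b_paths=(0.2, 0.0), c_prime=0.15,
        factor_correlation=0.0,
        r_a=0.0, r_c=0.0, r_e=0.0,
        instrumental_path=0.0, pleiotropic_outcome=0.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def mediation_cohort():
    """Unconfounded simple-mediation cohort: a=0.3, b=0.2, c'=0.15."""
    return generate_cohort(single_mediator_config(), seed=42)


@pytest.fixture(scope="session")
def ace_cohort():
    """Equal-thirds ACE exposure, no instrument, 2000+2000 pairs."""
    cfg = single_mediator_config(
        n_pairs_mz=2000, n_pairs_dz=2000,
        ace_exposure=(1 / 3, 1 / 3, 1 / 3))
    return generate_cohort(cfg, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two-pair hand-built cohort with a missing composite."""
    rows = []
    for fam, zyg, pgs in (("F1", "MZ", 0.3), ("F2", "DZss", -0.1)):
        for twin in (1, 2):
            rows.append({
                "family_id": fam, "zygosity": zyg, "twin": twin,
                "pgs": pgs if zyg == "MZ" else pgs + 0.2 * twin,
                "exposure": 0.5 * twin,
                "med_01": np.nan if (fam == "F2" and twin == 1) else 1.0,
                "outcome": -0.2 + 0.1 * twin,
            })
    from twinmediate import TwinCohort
    return TwinCohort(pd.DataFrame(rows))
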