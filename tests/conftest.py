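import numpy as np
import pytest

from enisim import CohortConfig, LadderNetwork, generate_cohort
from enisim.synthetic_cochlea import ElectrodeSite, ListenerParams, VirtualEar


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture
def flat_ear_factory():
    """Hand-built ear with a flat threshold profile (procedure oracles)."""

    def make(value_db=40.0, n=16, dynamic_range_db=12.0, pe_db=0.0):
        sites = [ElectrodeSite(e + 1, 1.0, "ST", 0.8, 0.8) for e in range(n)]
        net = LadderNetwork(np.full(n, 300.0), np.full(n - 1, 120.0))
        listener = ListenerParams(
            psychometric_slope_db=0.5,
            false_alarm_rate=0.0,
            lapse_rate=0.0,
            dynamic_range_mono_db=np.full(n, dynamic_range_db),
            dynamic_range_sqp_db=np.full(n, dynamic_range_db),
        )
        t_mono = np.full(n, value_db)
        t_sqp = np.full(n, value_db)
        t_sqp[0] = t_sqp[-1] = np.nan
        return VirtualEar(
            subject_id="T01",
            array_type="1J",
            duration_of_deafness_years=10.0,
            sites=sites,
            network=net,
            listener=listener,
            t_aca_db=t_mono + pe_db / 2.0,
            t_cac_db=t_mono - pe_db / 2.0,
            t_sqp_db=t_sqp,
            pe_db=np.full(n, float(pe_db)),
        )

    return make


@pytest.fixture
def smooth_config():
    """Low-noise cohort whose threshold profiles are smooth along the array,
    so continuous-sweep reconstruction can be compared to the latent truth."""
    return CohortConfig(
        n_subjects=4,
        survival_noise_sd=0.05,
        sgn_noise_sd=0.05,
        pe_noise_sd_db=0.2,
        mono_noise_sd_db=0.2,
        sqp_noise_sd_db=0.2,
        r_site_sigma_ln=0.1,
        scalar_probs=(1.0, 0.0, 0.0),
        psychometric_slope_db=0.0,
        false_alarm_rate=0.0,
        lapse_rate=0.0,
        seed=11,
    )
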