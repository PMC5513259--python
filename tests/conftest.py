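import numpy as np
import pandas as pd
import pytest

from fluxefp.qc import filter_daytime_measured, par_from_rg
from fluxefp.synthetic import SiteSimConfig, simulate_site_fluxes


@pytest.fixture(scope="session")
def noiseless_config():
    return SiteSimConfig(
        clearness_noise=0.0, noise_scale=0.0, gap_fraction=0.0, seed=7
    )


@pytest.fixture(scope="session")
def noiseless_site(noiseless_config):
    """One noiseless, gapless simulated site-year with its truth."""
    flux, truth = simulate_site_fluxes(noiseless_config)
    return flux, truth


@pytest.fixture(scope="session")
def qc_records(noiseless_site):
    """Daytime, measured records with a PAR column — fit-ready."""
    flux, _ = noiseless_site
    sub = filter_daytime_measured(flux)
    return sub.assign(par=par_from_rg(sub["rg"].to_numpy()))


def make_window(alpha, amax, theta, n=240, q_max=2000.0, noise_scale=0.0, seed=0,
                center="2005-07-01"):
    """A single synthetic 5-day fitting window with known parameters."""
    from fluxefp.lightresponse import nrh_gpp

    rng = np.random.default_rng(seed)
    center = pd.Timestamp(center)
    q = np.linspace(0.0, q_max, n) + rng.uniform(0, q_max / n, n)
    gpp = nrh_gpp(q, alpha, amax, theta)
    if noise_scale > 0:
        gpp = gpp + rng.normal(0.0, 1.0, n) * noise_scale * nrh_gpp(q, alpha, amax, theta)
    ts = center - pd.Timedelta(days=2) + pd.to_timedelta(
        np.linspace(0, 5 * 24 * 60 - 30, n), unit="min"
    )
    return pd.DataFrame({"timestamp": ts, "gpp": gpp, "par": q, "rg": q / 2.11,
                         "measured": True})


@pytest.fixture(scope="session")
def window_factory():
    return make_window
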