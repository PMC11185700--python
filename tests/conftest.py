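import numpy as np
import pytest

import foldswitch_nmr as fn


@pytest.fixture(scope="session")
def tjump_fit():
    """Global fit + bootstrap on the uncatalyzed T-jump design (45+37 peaks, 2% noise)."""
    fixture = fn.kaib_fixture("tjump_20C")
    tcs = fn.gen_tjump(fixture, 45, 37, noise_frac=0.02, seed=1)
    fit = fn.fit_global_rates(tcs)
    boot = fn.bootstrap_rates(tcs, n_iterations=200, seed=1)
    return fit, boot


@pytest.fixture(scope="session")
def cypa_fit():
    """Global fit on the CypA-catalyzed T-jump design."""
    fixture = fn.kaib_fixture("tjump_cypa_20C")
    tcs = fn.gen_tjump(fixture, 45, 37, noise_frac=0.02, seed=2)
    fit = fn.fit_global_rates(tcs)
    boot = fn.bootstrap_rates(tcs, n_iterations=200, seed=2)
    return fit, boot


@pytest.fixture(scope="session")
def methyl_fit():
    """Two-state global CEST fit on six synthetic methyl profiles."""
    fixture = fn.kaib_fixture("methyl_cest_20C")
    profiles = fn.gen_cest(fixture, residues=6, noise_abs=0.01, seed=3)
    # single-B1 CEST cannot resolve the minor state's R2 from kex, so the
    # minor R2 is tied to the observed state's, as in the backbone analysis
    fit = fn.fit_cest_global(
        profiles,
        fixture.model,
        constraints={"tie_r2": [("Enigma", "Ground")]},
        n_starts=1,
        max_nfev=400,
    )
    return fixture, profiles, fit


@pytest.fixture(scope="session")
def chain_fit():
    """Three-state chain CEST fit at the 20 C design (5 residues, R2 tying)."""
    fixture = fn.kaib_fixture("cest15N_20C")
    profiles = fn.gen_cest(fixture, residues=5, noise_abs=0.01, seed=4)
    fit = fn.fit_cest_global(
        profiles,
        fixture.model,
        constraints={"tie_r2": [("Enigma", "Ground")]},
        n_starts=1,
        max_nfev=400,
    )
    return fixture, profiles, fit


@pytest.fixture(scope="session")
def enigma_cpmg_rex():
    """Rex from a simulated Ground-state dispersion under the Enigma fixture."""
    fixture = fn.kaib_fixture("cpmg_enigma_25C")
    spin = next(s for s in fixture.spins if s.residue == "res_dw3")
    profile = fn.simulate_cpmg(fixture.model, spin, 0.060, list(range(3, 61)))
    profile.sigma = np.full_like(profile.r2eff, 0.01)
    return fn.estimate_rex(profile)
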