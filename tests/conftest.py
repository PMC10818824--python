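import numpy as np
import pytest

import quenchfit as qf


@pytest.fixture(scope="session")
def ladder():
    return qf.default_concentration_ladder()


@pytest.fixture()
def sv_series():
    """Noiseless series generated under the modified Stern-Volmer model."""
    cfg = qf.TitrationSimConfig(model="modified_sv", f0=1000.0, fa=0.8,
                                ksv=1500.0, seed=7)
    return qf.simulate_titration_sv(cfg)


@pytest.fixture()
def lb_series():
    """Noiseless series generated under the double-log binding model."""
    cfg = qf.TitrationSimConfig(model="lineweaver_burk", f0=1000.0, ka=150.0,
                                n_sites=0.7, seed=3)
    return qf.simulate_titration_lb(cfg)


@pytest.fixture(scope="session")
def hsa_eem():
    """Noiseless synthetic HSA-like EEM (two peaks + Rayleigh ridge)."""
    return qf.simulate_eem(qf.hsa_eem_config())


def brute_force_peaks(eem, ridge_halfwidth, min_prominence):
    """Exhaustive per-cell local-maxima scan; the independent oracle for
    detect_fluorescence_peaks."""
    z = eem.intensity
    gmax = z.max()
    out = []
    for i in range(z.shape[0]):
        for j in range(z.shape[1]):
            if abs(eem.excitation_grid[i] - eem.emission_grid[j]) <= ridge_halfwidth:
                continue
            if z[i, j] < min_prominence * gmax:
                continue
            is_max = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < z.shape[0] and 0 <= jj < z.shape[1]:
                        if not z[i, j] > z[ii, jj]:
                            is_max = False
            if is_max:
                out.append((float(eem.excitation_grid[i]),
                            float(eem.emission_grid[j]), float(z[i, j])))
    out.sort(key=lambda t: (-t[2], t[0], t[1]))
    return out


def brute_force_ridge_max(eem, ridge_halfwidth):
    """Exhaustive max over in-band cells (first in grid order on ties)."""
    best = None
    for i in range(eem.intensity.shape[0]):
        for j in range(eem.intensity.shape[1]):
            if abs(eem.excitation_grid[i] - eem.emission_grid[j]) > ridge_halfwidth:
                continue
            v = float(eem.intensity[i, j])
            if best is None or v > best[2]:
                best = (float(eem.excitation_grid[i]),
                        float(eem.emission_grid[j]), v)
    return best
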