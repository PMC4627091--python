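import numpy as np
import pytest
from hypothesis import settings

from spinachscan import simulate

# property tests must reproduce exactly across machines and runs
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def reference():
    """The built-in synthetic 87-nt reference and its designed stem pairs."""
    seq, pairs = simulate.synthetic_reference()
    return seq, pairs


@pytest.fixture(scope="session")
def small_truth():
    """Ground truth for a 12-nt toy sequence (36 SPMs + WT + NEG)."""
    seq, _ = simulate.synthetic_reference()
    return seq[:12], simulate.make_truth(seq[:12], seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def melt_grid_oracle(temps_K, signal, n_coarse=200, n_fine=61):
    """Brute-force (Tm x dH_T) least-squares oracle with local refinement.

    The amplitude is profiled out in closed form at every node (the model
    is linear in it).  A coarse scan over the plausible box is refined on
    a +/-3-coarse-step window around its argmin.  Returns
    (tm_best, dh_best, fine_steps) where fine_steps are the refined grid
    resolutions.
    """
    from spinachscan.melting import fraction_folded

    def scan(tm_grid, dh_grid):
        tms, dhs = np.meshgrid(tm_grid, dh_grid, indexing="ij")
        basis = fraction_folded(temps_K[None, None, :], tms[..., None], dhs[..., None])
        amp_hat = (basis * signal).sum(-1) / (basis**2).sum(-1)
        sse = ((amp_hat[..., None] * basis - signal) ** 2).sum(-1)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        return tm_grid[i], dh_grid[j]

    tm_grid = np.linspace(temps_K.min() - 5, temps_K.max() + 5, n_coarse)
    dh_grid = np.linspace(10, 150, n_coarse)
    st, sd = tm_grid[1] - tm_grid[0], dh_grid[1] - dh_grid[0]
    t0, d0 = scan(tm_grid, dh_grid)
    fine_tm = np.linspace(t0 - 3 * st, t0 + 3 * st, n_fine)
    fine_dh = np.linspace(max(d0 - 3 * sd, 1.0), d0 + 3 * sd, n_fine)
    t1, d1 = scan(fine_tm, fine_dh)
    return t1, d1, (fine_tm[1] - fine_tm[0], fine_dh[1] - fine_dh[0])
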