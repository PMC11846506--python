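"""Shared helper: fabricate a PosteriorDraws container with fixed values."""

import numpy as np

from gamvar.inference import PosteriorDraws


def make_plain_draws(a, A, sigma, C, T=40, n_draws=20, b=None):
    a = np.asarray(a, dtype=float)
    n = a.size
    A = np.asarray(A, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    C = np.asarray(C, dtype=float)
    mu = np.tile(a[:, None], (1, T))
    params = {
        "a": np.tile(a, (1, n_draws, 1)),
        "sigma": np.tile(sigma, (1, n_draws, 1)),
        "A": np.tile(A, (1, n_draws, 1, 1)),
        "C": np.tile(C, (1, n_draws, 1, 1)),
        "z": np.zeros((1, n_draws, n, T)),
        "mu": np.tile(mu, (1, n_draws, 1, 1)),
        "X": np.tile(mu, (1, n_draws, 1, 1)),
    }
    if b is not None:
        params["b"] = np.tile(np.asarray(b, dtype=float), (1, n_draws, 1))
    return PosteriorDraws(
        params=params,
        species_ids=[f"s{i}" for i in range(n)],
        variant="GAM-VAR",
    )
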