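"""Shared numerical helpers: parameter transforms, seeded starting points."""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logit
from scipy.stats import qmc


def to_unconstrained(params, kinds):
    """Map parameters to R^k: logit for (0,1)-valued, log for positive."""
    params = np.asarray(params, dtype=float)
    out = np.empty_like(params)
    for j, kind in enumerate(kinds):
        if kind == "unit":
            out[j] = logit(params[j])
        elif kind == "pos":
            out[j] = np.log(params[j])
        else:  # free
            out[j] = params[j]
    return out


def from_unconstrained(theta, kinds):
    theta = np.asarray(theta, dtype=float)
    out = np.empty_like(theta)
    for j, kind in enumerate(kinds):
        if kind == "unit":
            out[j] = expit(theta[j])
        elif kind == "pos":
            out[j] = np.exp(theta[j])
        else:
            out[j] = theta[j]
    return out


def latin_hypercube_starts(n_starts, bounds, seed):
    """Deterministic Latin-hypercube sample of starting points.

    bounds: list of (lo, hi) pairs on the *unconstrained* scale.
    """
    bounds = np.asarray(bounds, dtype=float)
    sampler = qmc.LatinHypercube(d=len(bounds), seed=int(seed))
    u = sampler.random(n=int(n_starts))
    return bounds[:, 0] + u * (bounds[:, 1] - bounds[:, 0])


def derive_seed(*parts):
    """Fold integer parts into a single seed below 2**31 (reproducible)."""
    ss = np.random.SeedSequence([int(p) & 0x7FFFFFFF for p in parts])
    return int(ss.generate_state(1)[0] % (2**31 - 1))
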