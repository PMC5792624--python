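"""Simulation-based calibration of the hierarchical fatality model.

Replicated forward simulation at the study's own scale (33 areal units,
overdispersion SD 0.3) followed by a full posterior fit checks that the
sampler and model are calibrated: equal-tailed 95% intervals should cover
the planted coefficients at close to their nominal rate, and posterior
means should essentially never sit more than three posterior SDs from
truth.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .exposure import build_exposure
from .model import FatalityModel, build_design, model_spec
from .synthetic import gen_study


def coverage_experiment(
    n_replicates: int = 200,
    n_units: int = 33,
    sigma_delta: float = 0.3,
    beta: Mapping[str, float] | None = None,
    model_id: int = 1,
    chains: int = 2,
    warmup: int = 750,
    draws: int = 750,
    seed: int = 0,
) -> dict:
    """Coverage and z-score summary over replicated simulate-then-fit runs.

    Each replicate generates a fresh study (commute tables, covariates,
    Poisson counts) from planted coefficients, fits the hierarchical model,
    and records whether each planted value lies inside the equal-tailed 95%
    interval and within three posterior SDs of the posterior mean. Returns
    per-coefficient rates plus their min/mean across coefficients.
    """
    root = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_replicates)]
    names: Sequence[str] | None = None
    covered: list[list[bool]] = []
    within3: list[list[bool]] = []
    for r, rep_seed in enumerate(rep_seeds):
        frame, tables, truth = gen_study(
            n_units=n_units, seed=rep_seed, beta=beta, sigma_delta=sigma_delta
        )
        exposures = {u: build_exposure(t).distance_km for u, t in tables.items()}
        X, offset, y = build_design(frame, exposures, model_spec(model_id))
        res = FatalityModel(y, X, offset).fit(
            chains=chains, warmup=warmup, draws=draws, seed=rep_seed
        )
        target = {"intercept": truth["beta0"], **truth["beta"]}
        names = res.param_names
        sf = res.summary_frame
        covered.append(
            [bool(sf.loc[p, "q2.5"] <= target[p] <= sf.loc[p, "q97.5"]) for p in names]
        )
        within3.append(
            [
                bool(abs(sf.loc[p, "mean"] - target[p]) <= 3 * sf.loc[p, "sd"])
                for p in names
            ]
        )
    cov = np.asarray(covered, dtype=float).mean(axis=0)
    w3 = np.asarray(within3, dtype=float).mean(axis=0)
    per_coef = {
        name: {"coverage_95": float(c), "frac_within_3sd": float(w)}
        for name, c, w in zip(names, cov, w3)
    }
    return {
        "n_replicates": n_replicates,
        "n_units": n_units,
        "per_coefficient": per_coef,
        "min_coverage_95": float(cov.min()),
        "max_coverage_95": float(cov.max()),
        "mean_coverage_95": float(cov.mean()),
        "min_frac_within_3sd": float(w3.min()),
    }


__all__ = ["coverage_experiment"]
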