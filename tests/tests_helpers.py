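"""Shared helpers: random small studies and feasible random parameters."""

import numpy as np

from mvpgs import CohortSpec, GeneratorTruth, simulate_cohort


def random_study(rng, n_cohorts=None):
    """A small random study: random outcome subsets, twin structure,
    covariate layouts, and missingness rates."""
    n_cohorts = n_cohorts or rng.integers(1, 3)
    study = []
    for c in range(n_cohorts):
        outcomes = tuple(
            np.array(["ADHD", "INT", "SOC"])[
                np.sort(rng.choice(3, rng.integers(1, 4), replace=False))
            ]
        )
        spec = CohortSpec(
            name=f"C{c}",
            outcomes_present=outcomes,
            has_age_covariate=bool(rng.integers(0, 2)),
            n_pcs=int(rng.integers(0, 3)),
            is_twin_cohort=bool(rng.integers(0, 2)),
        )
        truth = GeneratorTruth(
            miss_rate=float(rng.uniform(0, 0.4)),
            Sigma_X=float(rng.uniform(0, 0.5)) * np.eye(3),
        )
        n = int(rng.integers(8, 40))
        study.append(
            simulate_cohort(spec, n, truth, seed=int(rng.integers(2**31)))
        )
    return study


def feasible_theta(space, rng, scale=0.3):
    """Random flat vector kept inside the PD region of every twin block."""
    while True:
        theta = rng.normal(0.0, scale, space.n_params)
        ok = True
        for c, lay in enumerate(space.cohorts):
            if lay.sx_slice is not None:
                eig = np.linalg.eigvalsh(space.pair_cov(theta, c))
                ok = ok and eig.min() > 1e-3 * max(eig.max(), 1e-12)
        if ok:
            return theta
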