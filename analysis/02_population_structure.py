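#!/usr/bin/env python
"""Recover the two hemodynamic subpopulations from (CO, MAP).

Fits the two-component full-covariance Gaussian mixture by EM to the
(cardiac output, mean aortic pressure) plane of the default cohort,
compares the recovered labels with the planted groups, and runs the
group-difference screen (Shapiro–Wilk normality; two-sided
Mann–Whitney U for CO and MAP).  Writes

    results/gmm_fit.json        — component weights/means, agreement
    results/group_tests.csv     — the statistical test table
"""

import json
from pathlib import Path

import numpy as np

from pulseco.population import PopulationConfig, generate_population
from pulseco.structure import (
    fit_two_component_gmm,
    group_difference_tests,
    label_agreement,
    points_from_population,
)

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 0


def main() -> None:
    OUT.mkdir(exist_ok=True)
    pop = generate_population(PopulationConfig(seed=SEED))
    points = points_from_population(pop)
    fit = fit_two_component_gmm(points, rng=SEED)
    groups = np.array([s.params.group for s in pop])
    agreement = label_agreement(fit, groups)
    sizes = np.bincount(fit.labels, minlength=2)
    print(f"GMM component sizes: {sizes[0]} normodynamic-like, "
          f"{sizes[1]} hyperdynamic-like (planted 2620/1198)")
    print(f"label agreement with planted groups: {agreement:.4f}")
    print(f"component means (CO L/min, MAP mmHg):\n{np.round(fit.means, 2)}")

    tests = group_difference_tests(
        {
            "cardiac_output": points[:, 0],
            "mean_aortic_pressure": points[:, 1],
        },
        fit.labels,
    )
    tests.to_csv(OUT / "group_tests.csv", index=False)
    mw = tests[tests["test"] == "mann_whitney_u"]
    print("\nMann-Whitney U between recovered groups:")
    print(mw[["variable", "statistic", "p_value"]].to_string(index=False))

    (OUT / "gmm_fit.json").write_text(json.dumps({
        "seed": SEED,
        "weights": fit.weights.tolist(),
        "means": fit.means.tolist(),
        "sizes": sizes.tolist(),
        "label_agreement": agreement,
        "em_iterations": fit.n_iter,
        "log_likelihood": fit.log_likelihood,
    }, indent=2))


if __name__ == "__main__":
    main()
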