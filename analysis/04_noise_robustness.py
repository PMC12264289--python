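#!/usr/bin/env python
"""Full 12-condition grid with noise injection, at reduced scale.

Runs 3 sites × {calibrated, uncalibrated} × {clean, noisy} on a
600-subject cohort with shortened training, mirroring the full study's
design: noisy conditions corrupt train/validation/test inputs with
Gaussian noise plus 10%-amplitude spikes on 20% of points, reusing the
matched clean condition's hyperparameters.  Writes metric tables and
predictions to ``results/noise/`` and prints the two headline paired
comparisons (clean vs noisy; calibrated vs uncalibrated under noise)
as paired t-tests on Fisher z-transformed r values.
"""

import logging
import sys
from pathlib import Path

from pulseco.agreement import coefficient_of_variation, fisher_z_paired_test
from pulseco.cnn import ModelHyperparameters
from pulseco.experiment import RunConfig, export_report, run_experiment
from pulseco.population import PopulationConfig

OUT = Path(__file__).resolve().parent.parent / "results" / "noise"
SEED = 0


def main() -> None:
    logging.basicConfig(stream=sys.stderr, level=logging.INFO)
    cfg = RunConfig(
        population=PopulationConfig(n_normodynamic=420, n_hyperdynamic=180),
        hyperparameters=ModelHyperparameters(
            batch_size=32, learning_rate=1.5e-3, max_epochs=80,
            early_stopping_patience=15,
        ),
        seed=SEED,
    )
    result = run_experiment(cfg)
    export_report(result, OUT)
    table = result.table
    print(table[["site", "calibration", "noise", "r", "nrmse", "mae"]]
          .round(3).to_string(index=False))

    def rs(calibration, noise):
        sel = table[(table["calibration"] == calibration) & (table["noise"] == noise)]
        return sel.sort_values("site")["r"].to_numpy()

    clean = list(rs("calibrated", "clean")) + list(rs("uncalibrated", "clean"))
    noisy = list(rs("calibrated", "noisy")) + list(rs("uncalibrated", "noisy"))
    t, p = fisher_z_paired_test(clean, noisy)
    print(f"\nclean vs noisy r (pooled, paired t on Fisher z): t={t:.2f}, p={p:.4f}")
    t, p = fisher_z_paired_test(rs("calibrated", "noisy"), rs("uncalibrated", "noisy"))
    print(f"calibrated vs uncalibrated under noise: t={t:.2f}, p={p:.4f}")
    for calibration in ("calibrated", "uncalibrated"):
        cov = coefficient_of_variation(rs(calibration, "noisy"))
        print(f"intersite CoV of noisy {calibration} r: {cov:.1f}%")


if __name__ == "__main__":
    main()
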