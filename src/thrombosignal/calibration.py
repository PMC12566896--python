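"""Simulation-based calibration studies for the signal screen.

Two canned study conditions, used both by the test suite and by the
reproduction script:

* **null calibration** — no drug/event association anywhere (theta = 1);
  the fraction of drugs flagged at alpha measures the screen's type-I
  behaviour.  The flag rule is one-sided in effect (ln ROR > 0 AND p <
  alpha) and Fisher's exact test is conservative on discrete tables, so the
  realized rate sits below alpha; the check is the upper bound.
  The report-count eligibility threshold is set to 1 here so the
  statistical rule itself, not the eligibility filter, is what is
  calibrated.
* **effect recovery** — a single planted reporting-odds multiplier
  theta = 3 on one (drug, term) pair; the mean estimated ROR across seeds
  is compared with the generative model's closed-form expectation.
"""

from __future__ import annotations

import numpy as np

from thrombosignal import io
from thrombosignal.signals import contingency, haldane, ror, signal_scan
from thrombosignal.simulate import (SimTruth, effect_recovery_config,
                                    generate, null_calibration_config)

__all__ = ["null_flagged_rates", "ror_recovery"]


def _pipeline_rows(tables):
    return io.monotherapy_filter(
        io.deduplicate(io.integrate(tables.drug, tables.reac)))


def _seeds(base_seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(base_seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def null_flagged_rates(n_seeds: int = 100, base_seed: int = 0,
                       n_cases: int = 20_000, n_drugs: int = 100,
                       alpha: float = 0.05) -> np.ndarray:
    """Per-seed fraction of drugs flagged under the no-association model."""
    rates = []
    for seed in _seeds(base_seed, n_seeds):
        cfg = null_calibration_config(n_cases=n_cases, n_drugs=n_drugs,
                                      seed=seed)
        tables, _ = generate(cfg)
        rows = _pipeline_rows(tables)
        thrombo = [p.pt for p in cfg.pts if p.scope != "none"]
        res = signal_scan(rows, cohort=[d.name for d in cfg.drugs],
                          terms=thrombo, alpha=alpha, min_drug_reports=1)
        rates.append(float(res["flagged"].mean()))
    return np.asarray(rates)


def ror_recovery(theta: float = 3.0, n_seeds: int = 100, base_seed: int = 0,
                 n_cases: int = 50_000) -> tuple[np.ndarray, float]:
    """Estimated RORs for the planted pair across seeds, plus the truth.

    Returns ``(estimates, expected_ror)`` where ``expected_ror`` is the
    closed-form value implied by the generator configuration.
    """
    target_drug, target_pt = "DRUG000", "DEEP VEIN THROMBOSIS"
    estimates = []
    cfg = None
    for seed in _seeds(base_seed, n_seeds):
        cfg = effect_recovery_config(theta=theta, n_cases=n_cases, seed=seed)
        tables, _ = generate(cfg)
        rows = _pipeline_rows(tables)
        t = haldane(contingency(rows, target_drug, [target_pt]))
        estimates.append(ror(t))
    expected = SimTruth(cfg).expected_ror(target_drug, [target_pt])
    return np.asarray(estimates), float(expected)
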