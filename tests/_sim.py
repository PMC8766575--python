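"""Small direct simulators used as oracles in statistical tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit


def betabinom_draw(rng: np.random.Generator, n: int, mu: float, rho: float) -> int:
    if mu <= 0:
        return 0
    if mu >= 1:
        return n
    if rho < 1e-9:
        return int(rng.binomial(n, mu))
    a = mu * (1 - rho) / rho
    b = (1 - mu) * (1 - rho) / rho
    return int(rng.binomial(n, rng.beta(a, b)))


def paired_observations(
    rng: np.random.Generator,
    n_patients: int,
    trials: int,
    base_logit: float = 0.0,
    condition_effect: float = 0.0,
    patient_sd: float = 0.0,
    rho: float = 0.05,
    unit_id: str = "u1",
) -> pd.DataFrame:
    """Tumor/normal pair per patient with logit-scale patient effects."""
    rows = []
    for p in range(n_patients):
        pid = f"P{p + 1:02d}"
        p_eff = rng.normal(0.0, patient_sd) if patient_sd > 0 else 0.0
        for condition in ("tumor", "normal"):
            eta = base_logit + p_eff + (condition_effect if condition == "tumor" else 0.0)
            mu = float(expit(eta))
            k = betabinom_draw(rng, trials, mu, rho)
            rows.append(
                {
                    "unit_id": unit_id,
                    "sample_id": f"{pid}{condition[0].upper()}",
                    "k": k,
                    "n": trials,
                    "condition": condition,
                    "patient_id": pid,
                }
            )
    return pd.DataFrame(rows)


def paired_level_observations(
    rng: np.random.Generator,
    n_patients: int,
    trials: int,
    level_normal: float,
    level_delta: float = 0.0,
    rho: float = 0.05,
    unit_id: str = "u1",
) -> pd.DataFrame:
    """Tumor/normal pair per patient on the raw level scale."""
    rows = []
    for p in range(n_patients):
        pid = f"P{p + 1:02d}"
        for condition in ("tumor", "normal"):
            mu = float(
                np.clip(level_normal + (level_delta if condition == "tumor" else 0.0), 0, 1)
            )
            k = betabinom_draw(rng, trials, mu, rho)
            rows.append(
                {
                    "unit_id": unit_id,
                    "sample_id": f"{pid}{condition[0].upper()}",
                    "k": k,
                    "n": trials,
                    "condition": condition,
                    "patient_id": pid,
                }
            )
    return pd.DataFrame(rows)
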