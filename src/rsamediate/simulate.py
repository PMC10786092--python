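"""Synthetic cohort generator: EEG epochs, trait questionnaires, behavior.

The generator embeds a known representational geometry and a known mediation
structure so the downstream pipeline can be validated against ground truth:

* condition-mean topographies separate along three orthonormal spatial
  patterns (race / pain / gender), each scaled by a Gaussian temporal
  envelope centered at the dimension's peak latency (race and pain early,
  gender late);
* per-participant race-pattern amplitude is multiplied by a latent "race
  strength" driven by the EG and RI traits with opposite signs;
* punishment decisions (shock intensities in mA) are generated from that
  same latent race strength plus direct trait paths, then clipped to the
  physical shock scale.

Trial noise is spatially correlated across channels (exponential decay in
channel distance) and white over time.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .config import CONDITIONS, DIMENSIONS, SimulationConfig
from .epochs import EpochedEEG
from .errors import ConfigError

__all__ = [
    "dimension_patterns",
    "condition_signs",
    "simulate_participant_eeg",
    "simulate_behavior",
    "simulate_cohort",
]


def condition_signs() -> np.ndarray:
    """(8, 3) array of +/- 1/2 condition codes in canonical order.

    The between-category pattern difference along dimension ``d`` is then
    exactly ``amplitude_d * envelope_d(t) * v_d``.
    """
    signs = np.empty((len(CONDITIONS), len(DIMENSIONS)))
    for i, cond in enumerate(CONDITIONS):
        for j in range(len(DIMENSIONS)):
            # first category of each dimension codes +1/2, second -1/2
            from .config import CATEGORIES

            first = CATEGORIES[DIMENSIONS[j]][0]
            signs[i, j] = 0.5 if cond[j] == first else -0.5
    return signs


def dimension_patterns(config: SimulationConfig) -> np.ndarray:
    """Fixed orthonormal spatial patterns, one per dimension.

    Drawn once from ``config.seed`` so every participant of a cohort shares
    the same representational geometry.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD1]))
    raw = rng.standard_normal((config.n_channels, len(DIMENSIONS)))
    q, r = np.linalg.qr(raw)
    # fix signs for reproducibility across BLAS implementations
    q = q * np.sign(np.diag(r))
    return q.T  # (3, n_channels)


def _noise_cholesky(config: SimulationConfig) -> np.ndarray:
    idx = np.arange(config.n_channels)
    cov = config.noise_variance_uv2 * np.exp(
        -np.abs(idx[:, None] - idx[None, :]) / config.noise_spatial_decay
    )
    if config.noise_variance_uv2 == 0.0:
        return np.zeros_like(cov)
    return np.linalg.cholesky(cov)


def _envelopes(config: SimulationConfig) -> np.ndarray:
    """(3, n_times) Gaussian temporal envelopes, one per dimension."""
    t = config.times_ms
    env = np.empty((len(DIMENSIONS), t.size))
    for j, d in enumerate(DIMENSIONS):
        peak = config.dimension_peak_ms[d]
        env[j] = np.exp(-0.5 * ((t - peak) / config.dimension_width_ms) ** 2)
    return env


def simulate_participant_eeg(
    config: SimulationConfig,
    race_strength: float = 1.0,
    seed: int | None = None,
    participant_id: str = "p000",
) -> EpochedEEG:
    """Generate one participant's epoched EEG.

    ``race_strength`` multiplies the race-dimension amplitude (>= 0); the
    pain and gender amplitudes are taken from the config as is.  With a
    fixed config and seed the output is bit-identical across calls.
    """
    config.validate()
    if race_strength < 0:
        raise ConfigError("race_strength must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xEE, seed or 0]))

    patterns = dimension_patterns(config)  # (3, ch)
    env = _envelopes(config)  # (3, T)
    signs = condition_signs()  # (8, 3)
    amps = np.array([config.dimension_amplitudes[d] for d in DIMENSIONS])
    amps = amps * np.array([race_strength, 1.0, 1.0])

    # condition means: (8, ch, T) = sum_d signs[c,d]*amps[d]*v_d outer env_d
    weighted = signs * amps  # (8, 3)
    means = np.einsum("cd,dk,dt->ckt", weighted, patterns, env)

    n_cond = len(CONDITIONS)
    n_trials = n_cond * config.trials_per_condition
    cond_idx = np.repeat(np.arange(n_cond), config.trials_per_condition)
    rng.shuffle(cond_idx)

    chol = _noise_cholesky(config)
    noise = rng.standard_normal((n_trials, config.n_channels, config.times_ms.size))
    data = means[cond_idx] + np.matmul(chol, noise)

    labels = np.array([CONDITIONS[i] for i in cond_idx], dtype=object)
    return EpochedEEG(
        data=data,
        condition_labels=labels,
        times_ms=config.times_ms,
        channel_ids=config.channel_ids,
        participant_id=participant_id,
    )


def simulate_behavior(
    traits: Mapping[str, float],
    race_indicator: float,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[float, float]:
    """Generate (punishment_high, punishment_low) shock intensities in mA.

    ``traits`` must provide standardized ``EG`` and ``RI`` scores and
    ``race_indicator`` the standardized latent race-representation strength.
    The high-minus-low difference carries the mediation structure
    ``b * race + c'_EG * EG + c'_RI * RI`` on top of the anchored conflict
    gap; both intensities are clipped to the physical shock scale.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xBE, seed or 0]))
    lo, hi, low_anchor, high_anchor = config.shock_scale
    paths = config.mediation_paths

    low = low_anchor + config.low_anchor_noise_sd * rng.standard_normal()
    diff = (
        (high_anchor - low_anchor)
        + paths["b"] * race_indicator
        + paths["c_prime_EG"] * traits["EG"]
        + paths["c_prime_RI"] * traits["RI"]
        + config.behavior_noise_sd * rng.standard_normal()
    )
    high = low + diff
    return float(np.clip(high, lo, hi)), float(np.clip(low, lo, hi))


def _likert_items(
    rng: np.random.Generator, latent: np.ndarray, n_items: int, config: SimulationConfig
) -> np.ndarray:
    """Map a standardized latent trait to integer 1-7 item ratings."""
    n = latent.size
    raw = (
        4.0
        + config.item_loading * latent[:, None]
        + config.item_noise_sd * rng.standard_normal((n, n_items))
    )
    return np.clip(np.round(raw), 1, 7).astype(int)


def simulate_cohort(
    config: SimulationConfig,
    n_participants: int,
    seed: int | None = None,
) -> tuple[list[EpochedEEG], pd.DataFrame]:
    """Generate a full synthetic cohort.

    Returns one :class:`EpochedEEG` per participant plus a cohort table with
    questionnaire item ratings, raw trait composites, punishment decisions,
    and hidden ground-truth columns (prefixed ``true_``) recording the
    latent values the generator used.
    """
    config.validate()
    if n_participants < 1:
        raise ConfigError("n_participants must be >= 1")
    base = np.random.SeedSequence([config.seed, 0xC0, seed or 0])
    rng = np.random.default_rng(base)

    rho = config.trait_correlation
    cov = np.array([[1.0, rho], [rho, 1.0]])
    traits = rng.multivariate_normal([0.0, 0.0], cov, size=n_participants)
    eg, ri = traits[:, 0], traits[:, 1]

    g = config.trait_to_race_slope
    resid_sd = np.sqrt(config._race_strength_residual_var())
    race_z = g["EG"] * eg + g["RI"] * ri + resid_sd * rng.standard_normal(n_participants)
    multiplier = np.maximum(0.0, 1.0 + config.race_modulation_depth * race_z)

    items_eg = _likert_items(rng, eg, config.items_per_factor["EG"], config)
    items_ri = _likert_items(rng, ri, config.items_per_factor["RI"], config)

    participant_seeds = rng.integers(0, 2**31 - 1, size=(n_participants, 2))
    epochs_list: list[EpochedEEG] = []
    rows = []
    for i in range(n_participants):
        pid = f"p{i:03d}"
        epochs_list.append(
            simulate_participant_eeg(
                config,
                race_strength=float(multiplier[i]),
                seed=int(participant_seeds[i, 0]),
                participant_id=pid,
            )
        )
        high, low = simulate_behavior(
            {"EG": eg[i], "RI": ri[i]},
            float(race_z[i]),
            config,
            seed=int(participant_seeds[i, 1]),
        )
        row = {
            "participant_id": pid,
            "EG_raw": items_eg[i].mean(),
            "RI_raw": items_ri[i].mean(),
            "punishment_high": high,
            "punishment_low": low,
            "true_EG": eg[i],
            "true_RI": ri[i],
            "true_race_z": race_z[i],
            "true_race_multiplier": multiplier[i],
        }
        for j in range(items_eg.shape[1]):
            row[f"item_EG_{j + 1}"] = items_eg[i, j]
        for j in range(items_ri.shape[1]):
            row[f"item_RI_{j + 1}"] = items_ri[i, j]
        rows.append(row)

    table = pd.DataFrame(rows)
    lo, hi = config.shock_scale[0], config.shock_scale[1]
    assert table["punishment_high"].between(lo, hi).all()
    assert table["punishment_low"].between(lo, hi).all()
    return epochs_list, table
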