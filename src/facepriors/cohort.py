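"""Synthetic study cohorts: questionnaires, face-task and gaze-task trials.

The generator emulates the study conditions end to end so every analysis
stage can be exercised without participant data:

* **Questionnaire totals.**  PDI and CAPS totals are gamma distributed
  (moment-matched to cohort mean/SD, hence right-skewed), linked by a
  Gaussian copula with a configurable rank coupling, and clipped to the
  instruments' ranges (PDI-21 max 315, CAPS max 480).
* **Generative parameters.**  Each participant's face-detection prior is a
  monotone map of a noisy rank blend of their CAPS score, calibrated so the
  population Spearman correlation equals the configured coupling;
  sensitivity is drawn independently of symptoms.  The per-participant
  direct-gaze advantage (seconds) has a uniform marginal and its own rank
  coupling to CAPS.
* **Face task.**  Detection responses are Bernoulli draws from the Bayesian
  observer's posterior, i.e. the analysis model is also the forward model.
* **Gaze task.**  Breakthrough times are shifted lognormal per trial, with
  the averted-gaze condition centred on the participant's baseline and the
  direct-gaze condition faster by the participant's advantage; times beyond
  the 15 s ceiling and additional random lapses become misses.  A configured
  number of participants receive a high miss rate to exercise the >65%
  exclusion rule.

Rank couplings use a Gaussian copula whose latent correlation inverts the
exact finite-n expectation of Spearman's rho under bivariate normality,
E[r_s] = 6/(pi(n+1)) ((n-2) asin(rho/2) + asin(rho)), so the realized rank
correlation across replicate cohorts is centred on the configured value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .detection import posterior_detection_prob
from .errors import ValidationError

PDI_MAX = 315.0  # 21 items x 3 subscales x max rating 5
CAPS_MAX = 480.0  # 32 items x 3 subscales x max rating 5


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters for one synthetic cohort.

    Defaults reproduce the study conditions: n = 39, PDI 76.95 (42.86),
    CAPS 106.90 (48.81), 40/60 face trials, 12 gaze trials per gaze x side
    cell with a 15 s ceiling, a 0.67 s mean direct-gaze advantage, and rank
    couplings of 0.50 (CAPS vs face prior) and 0.43 (CAPS vs gaze bias).
    """

    n_participants: int = 39
    seed: int = 0
    # questionnaires
    pdi_mean: float = 76.95
    pdi_sd: float = 42.86
    caps_mean: float = 106.90
    caps_sd: float = 48.81
    pdi_caps_rank_coupling: float = 0.6
    # face task
    face_targets: int = 40
    face_noise: int = 60
    prior_caps_rank_coupling: float = 0.50
    prior_range: tuple[float, float] = (0.15, 0.75)
    sensitivity_range: tuple[float, float] = (0.60, 0.90)
    # gaze task
    gaze_trials_per_cell: int = 12
    rt_base_seconds: float = 4.055
    rt_base_sd: float = 1.2
    gaze_advantage_mean: float = 0.67
    gaze_advantage_halfwidth: float = 0.97
    gaze_bias_caps_rank_coupling: float = 0.43
    rt_sigma: float = 1.5
    rt_shift: float = 0.2
    rt_ceiling: float = 15.0
    miss_rate: float = 0.08
    n_high_miss_participants: int = 2
    high_miss_rate: float = 0.9
    mislocalization_rate: float = 0.0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValidationError("n_participants must be >= 1")
        for name in ("pdi_mean", "pdi_sd", "caps_mean", "caps_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("pdi_caps_rank_coupling", "prior_caps_rank_coupling",
                     "gaze_bias_caps_rank_coupling"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must lie in [-1, 1]")
        for lo, hi in (self.prior_range, self.sensitivity_range):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValidationError("probability ranges must be ordered within [0, 1]")
        if not 0.0 <= self.miss_rate <= 1.0 or not 0.0 <= self.high_miss_rate <= 1.0:
            raise ValidationError("miss rates must be probabilities")
        if self.n_high_miss_participants > self.n_participants:
            raise ValidationError("n_high_miss_participants exceeds cohort size")
        if self.rt_ceiling <= self.rt_shift:
            raise ValidationError("rt_ceiling must exceed rt_shift")


@dataclass
class CohortData:
    """All tables for one synthetic cohort, joined by participant_id."""

    psychometrics: pd.DataFrame
    face_trials: pd.DataFrame
    gaze_trials: pd.DataFrame
    ground_truth: pd.DataFrame
    config: CohortConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("psychometrics", "face_trials", "gaze_trials", "ground_truth"):
            p = out / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False, float_format="%.10g")
            paths[name] = p
        return paths


def expected_spearman(rho_latent: float, n: int) -> float:
    """Exact E[Spearman r_s] for an i.i.d. bivariate-normal sample of size n."""
    return (6.0 / (np.pi * (n + 1))) * ((n - 2) * np.arcsin(rho_latent / 2.0)
                                        + np.arcsin(rho_latent))


def latent_correlation(target_spearman: float, n: int) -> float:
    """Latent normal correlation whose finite-n expected Spearman rho equals the target."""
    c = float(target_spearman)
    if not -1.0 <= c <= 1.0:
        raise ValidationError("target rank coupling must lie in [-1, 1]")
    if c == 0.0:
        return 0.0
    if abs(c) == 1.0:
        return float(np.sign(c))
    f = lambda r: expected_spearman(r, n) - abs(c)
    sol = optimize.brentq(f, 0.0, 1.0, xtol=1e-12)
    return float(np.sign(c) * sol)


def _normal_scores(values: np.ndarray) -> np.ndarray:
    """Van der Waerden-style normal scores of the ranks of ``values``."""
    n = values.size
    return stats.norm.ppf((stats.rankdata(values) - 0.5) / n)


def generate_psychometrics(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Gamma-distributed PDI/CAPS totals with a copula rank coupling."""
    config.validate()
    n = config.n_participants
    rho_l = latent_correlation(config.pdi_caps_rank_coupling, max(n, 4))
    z1 = rng.standard_normal(n)
    z2 = rho_l * z1 + np.sqrt(1 - rho_l**2) * rng.standard_normal(n)

    def gamma_from_latent(z, mean, sd, cap):
        shape = (mean / sd) ** 2
        scale = sd**2 / mean
        vals = stats.gamma.ppf(stats.norm.cdf(z), shape, scale=scale)
        return np.clip(vals, 0.0, cap)

    pdi = gamma_from_latent(z1, config.pdi_mean, config.pdi_sd, PDI_MAX)
    caps = gamma_from_latent(z2, config.caps_mean, config.caps_sd, CAPS_MAX)
    ids = [f"P{i+1:03d}" for i in range(n)]
    return pd.DataFrame(dict(participant_id=ids, pdi_total=pdi, caps_total=caps))


def assign_generative_params(psychometrics: pd.DataFrame, config: CohortConfig,
                             rng: np.random.Generator) -> pd.DataFrame:
    """Per-participant ground-truth parameters, rank-coupled to CAPS.

    The face prior and the direct-gaze advantage are monotone maps of noisy
    blends of the CAPS normal scores (couplings per config); sensitivity is
    independent of symptoms; ``n_high_miss_participants`` get a miss rate
    above the exclusion threshold.
    """
    config.validate()
    n = len(psychometrics)
    if n == 0:
        raise ValidationError("psychometrics table is empty")
    caps_z = _normal_scores(psychometrics["caps_total"].to_numpy())

    def coupled_uniform(coupling: float) -> np.ndarray:
        rho_l = latent_correlation(coupling, max(n, 4))
        z = rho_l * caps_z + np.sqrt(1 - rho_l**2) * rng.standard_normal(n)
        return stats.norm.cdf(z)  # uniform marginal, rank-coupled to CAPS

    plo, phi = config.prior_range
    prior = plo + (phi - plo) * coupled_uniform(config.prior_caps_rank_coupling)
    slo, shi = config.sensitivity_range
    sensitivity = rng.uniform(slo, shi, n)
    adv = (config.gaze_advantage_mean
           + config.gaze_advantage_halfwidth
           * (2.0 * coupled_uniform(config.gaze_bias_caps_rank_coupling) - 1.0))
    miss = np.full(n, config.miss_rate)
    high = rng.choice(n, size=config.n_high_miss_participants, replace=False)
    miss[high] = config.high_miss_rate
    return pd.DataFrame(dict(
        participant_id=psychometrics["participant_id"].to_numpy(),
        prior=prior, sensitivity=sensitivity, gaze_advantage=adv,
        miss_rate=miss, high_miss=np.isin(np.arange(n), high)))


def simulate_face_task(params: pd.DataFrame, config: CohortConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Bernoulli detection responses from the Bayesian observer's posterior."""
    config.validate()
    rows = []
    for _, p in params.iterrows():
        present = np.array([True] * config.face_targets + [False] * config.face_noise)
        rng.shuffle(present)
        lik = np.where(present, p["sensitivity"], 1.0 - p["sensitivity"])
        prob = posterior_detection_prob(np.full(present.size, p["prior"]), lik)
        detected = rng.random(present.size) < prob
        rows.append(pd.DataFrame(dict(
            participant_id=p["participant_id"],
            trial_index=np.arange(present.size),
            face_present=present.astype(int),
            detected=detected.astype(int))))
    return pd.concat(rows, ignore_index=True)


def _lognormal_rt(mean_rt: float, config: CohortConfig, size: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Shifted-lognormal trial RTs with the requested mean and trial SD."""
    m = max(mean_rt - config.rt_shift, 0.3)
    s = config.rt_sigma
    sigma2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    return config.rt_shift + rng.lognormal(mu, np.sqrt(sigma2), size)


def simulate_gaze_task(params: pd.DataFrame, config: CohortConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    """bCFS trials: 12 per gaze x side cell, censored at the 15 s ceiling."""
    config.validate()
    rows = []
    quadrants = {"left": (1, 3), "right": (2, 4)}
    for _, p in params.iterrows():
        base = max(float(rng.normal(config.rt_base_seconds, config.rt_base_sd)), 1.0)
        cond_mean = {"averted": base,
                     "direct": max(base - float(p["gaze_advantage"]), 0.5)}
        recs = []
        for gaze in ("direct", "averted"):
            for side in ("left", "right"):
                k = config.gaze_trials_per_cell
                rts = _lognormal_rt(cond_mean[gaze], config, k, rng)
                quads = rng.choice(quadrants[side], size=k)
                lapse = rng.random(k) < p["miss_rate"]
                censored = rts > config.rt_ceiling
                missed = lapse | censored
                misloc = rng.random(k) < config.mislocalization_rate
                for i in range(k):
                    if missed[i]:
                        rep, rt = None, None
                    else:
                        rt = float(rts[i])
                        if misloc[i]:
                            others = [q for q in (1, 2, 3, 4) if q != quads[i]]
                            rep = int(rng.choice(others))
                        else:
                            rep = int(quads[i])
                    recs.append(dict(participant_id=p["participant_id"], gaze=gaze,
                                     true_quadrant=int(quads[i]),
                                     reported_quadrant=rep, rt_seconds=rt))
        order = rng.permutation(len(recs))
        for idx, j in enumerate(order):
            recs[j]["trial_index"] = idx
        recs.sort(key=lambda r: r["trial_index"])
        rows.extend(recs)
    df = pd.DataFrame(rows)
    return df[["participant_id", "trial_index", "gaze", "true_quadrant",
               "reported_quadrant", "rt_seconds"]]


def generate_cohort(config: CohortConfig,
                    rng: Optional[np.random.Generator] = None) -> CohortData:
    """Full deterministic cohort bundle (given config.seed)."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    psych = generate_psychometrics(config, rng)
    params = assign_generative_params(psych, config, rng)
    face = simulate_face_task(params, config, rng)
    gaze = simulate_gaze_task(params, config, rng)
    return CohortData(psychometrics=psych, face_trials=face, gaze_trials=gaze,
                      ground_truth=params, config=config)
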