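"""Generative Bayesian face-detection model and per-participant fitting.

The observer holds a prior probability that a face is present and receives a
binary sensory likelihood whose diagnosticity is governed by a sensitivity
parameter: the likelihood of "face" is ``sensitivity`` when a face is
embedded and ``1 - sensitivity`` otherwise.  The probability of a "face
detected" response on a trial is the Bayesian posterior

    P = prior * L / (prior * L + (1 - prior) * (1 - L)),

and both parameters are estimated per participant by maximising the Bernoulli
log-likelihood of the responses with a bounded Powell search over
[0, 1] x [0, 1].

Because the model is saturated (two parameters, two sufficient statistics:
the hit and false-alarm rates), an algebraic maximum-likelihood solution
exists for interior rates and serves as an independent oracle for the
numeric fit.  Standard signal-detection summaries (d', c, beta, A') are also
provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import BoundaryRateError, FittingError, ValidationError

EPS = 1e-9  # probability clipping before logarithms

_STARTS = [(0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0), (0.5, 0.5)]


@dataclass(frozen=True)
class FaceTrial:
    """One detection trial: ground truth and binary response."""

    face_present: bool
    detected: bool


@dataclass
class FaceTaskData:
    """All face-task trials for one participant."""

    participant_id: str
    trials: list[FaceTrial]

    @classmethod
    def from_arrays(cls, participant_id: str, face_present: Iterable, detected: Iterable) -> "FaceTaskData":
        trials = [FaceTrial(bool(f), bool(d)) for f, d in zip(face_present, detected)]
        return cls(participant_id=str(participant_id), trials=trials)

    @classmethod
    def from_counts(cls, participant_id: str, n_hits: int, n_face: int,
                    n_fa: int, n_noise: int) -> "FaceTaskData":
        """Build data from sufficient statistics (order carries no information)."""
        trials = ([FaceTrial(True, True)] * n_hits
                  + [FaceTrial(True, False)] * (n_face - n_hits)
                  + [FaceTrial(False, True)] * n_fa
                  + [FaceTrial(False, False)] * (n_noise - n_fa))
        return cls(participant_id=str(participant_id), trials=trials)

    def counts(self) -> tuple[int, int, int, int]:
        """(n_hits, n_face, n_fa, n_noise)."""
        nh = sum(t.detected for t in self.trials if t.face_present)
        nf = sum(t.face_present for t in self.trials)
        na = sum(t.detected for t in self.trials if not t.face_present)
        nn = sum(not t.face_present for t in self.trials)
        return nh, nf, na, nn


@dataclass
class FaceFit:
    """Fitted (prior, sensitivity) pair with the maximised log-likelihood."""

    participant_id: str
    prior: float
    sensitivity: float
    log_likelihood: float
    converged: bool
    n_trials: int
    below_chance_sensitivity: bool = False
    boundary_corrected: bool = False


@dataclass
class SDTSummary:
    """Signal-detection summaries of a hit/false-alarm table."""

    hit_rate: float
    fa_rate: float
    d_prime: float
    criterion_c: float
    beta: float
    a_prime: float


def likelihood_of_face(sensitivity: float, face_present: bool) -> float:
    """Sensory likelihood of 'face': sensitivity if present, else 1 - sensitivity."""
    if not 0.0 <= sensitivity <= 1.0:
        raise ValidationError("sensitivity must lie in [0, 1]")
    return sensitivity if face_present else 1.0 - sensitivity


def posterior_detection_prob(prior, likelihood):
    """Two-hypothesis Bayesian posterior; vectorised over numpy inputs.

    Degenerate 0/0 denominators are handled by clipping both numerator and
    denominator away from zero.
    """
    prior = np.asarray(prior, dtype=float)
    likelihood = np.asarray(likelihood, dtype=float)
    if np.any(prior < 0) or np.any(prior > 1) or np.any(likelihood < 0) or np.any(likelihood > 1):
        raise ValidationError("prior and likelihood must lie in [0, 1]")
    num = prior * likelihood
    den = num + (1.0 - prior) * (1.0 - likelihood)
    out = num / np.clip(den, EPS, None)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def _posterior_scalar(prior: float, likelihood: float) -> float:
    """Scalar fast path of the posterior (hot loop of the optimiser)."""
    num = prior * likelihood
    den = num + (1.0 - prior) * (1.0 - likelihood)
    q = num / den if den > EPS else num / EPS
    return min(max(q, EPS), 1.0 - EPS)


def _loglik_from_counts(prior: float, sensitivity: float,
                        nh: int, nf: int, na: int, nn: int) -> float:
    p_face = _posterior_scalar(prior, sensitivity)
    p_noise = _posterior_scalar(prior, 1.0 - sensitivity)
    return (nh * math.log(p_face) + (nf - nh) * math.log(1.0 - p_face)
            + na * math.log(p_noise) + (nn - na) * math.log(1.0 - p_noise))


def log_likelihood(prior: float, sensitivity: float, data: FaceTaskData) -> float:
    """Bernoulli log-likelihood of the responses under the posterior model.

    Probabilities are clipped to [EPS, 1 - EPS] before taking logarithms.
    """
    if not data.trials:
        raise ValidationError("cannot evaluate the likelihood of empty data")
    if not (0.0 <= prior <= 1.0 and 0.0 <= sensitivity <= 1.0):
        raise ValidationError("parameters must lie in [0, 1]")
    return float(_loglik_from_counts(prior, sensitivity, *data.counts()))


def closed_form_mle(hit_rate: float, fa_rate: float) -> tuple[float, float]:
    """Algebraic maximum-likelihood estimate from interior hit/FA rates.

    With odds ``oh = h/(1-h)`` and ``of = f/(1-f)``, the model's predicted
    rates equal the observed ones at prior odds ``sqrt(oh * of)`` and
    sensitivity odds ``sqrt(oh / of)``.
    """
    for r in (hit_rate, fa_rate):
        if not 0.0 < r < 1.0:
            raise BoundaryRateError(
                "hit/FA rate on the boundary of (0, 1); use the bounded numeric fit")
    oh = hit_rate / (1.0 - hit_rate)
    of = fa_rate / (1.0 - fa_rate)
    a = np.sqrt(oh * of)
    b = np.sqrt(oh / of)
    return float(a / (1.0 + a)), float(b / (1.0 + b))


def fit_face_model(data: FaceTaskData, optimizer: str = "powell",
                   n_grid: int = 200) -> FaceFit:
    """Maximise the response log-likelihood over (prior, sensitivity) in [0,1]^2.

    The default optimiser is a bounded Powell search started from the four
    corners and the centre of the parameter square; ties are broken by the
    higher log-likelihood, then by the smaller prior.  ``optimizer='grid'``
    runs an n_grid x n_grid exhaustive evaluation instead (useful as a slow
    but assumption-free cross-check).

    When an observed hit or false-alarm rate is exactly 0 or 1 the saturated
    model's maximum-likelihood estimate does not exist (the likelihood
    supremum is approached at a corner of the parameter square, so any
    numeric "optimum" there is an artifact of probability clipping).  Such
    datasets are fitted after the log-linear correction (0.5 added to each
    response cell, 1 to each denominator) and flagged ``boundary_corrected``;
    the reported log-likelihood is always evaluated on the uncorrected data.
    """
    nh, nf, na, nn = data.counts()
    if nf == 0 or nn == 0:
        missing = "face-present" if nf == 0 else "face-absent"
        raise FittingError(f"cannot fit: no {missing} trials in the data")
    raw = (nh, nf, na, nn)
    corrected = nh in (0, nf) or na in (0, nn)
    if corrected:
        nh, nf, na, nn = nh + 0.5, nf + 1.0, na + 0.5, nn + 1.0

    if optimizer == "grid":
        grid = np.linspace(0.0, 1.0, n_grid)
        pp, ss = np.meshgrid(grid, grid, indexing="ij")
        ll = _loglik_grid(pp, ss, nh, nf, na, nn)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        prior, sens, best_ll, ok = float(grid[i]), float(grid[j]), float(ll[i, j]), True
    elif optimizer == "powell":
        def nll(theta):
            # Powell's line search may probe marginally outside the bounds
            p = min(max(theta[0], 0.0), 1.0)
            s = min(max(theta[1], 0.0), 1.0)
            return -_loglik_from_counts(p, s, nh, nf, na, nn)

        best = None
        for x0 in _STARTS:
            res = optimize.minimize(nll, x0, method="Powell", bounds=[(0, 1), (0, 1)],
                                    options=dict(xtol=1e-8, ftol=1e-12, maxiter=5000))
            if (best is None or res.fun < best.fun - 1e-12
                    or (abs(res.fun - best.fun) <= 1e-12 and res.x[0] < best.x[0])):
                best = res
        prior, sens = (float(np.clip(best.x[0], 0, 1)), float(np.clip(best.x[1], 0, 1)))
        best_ll, ok = -float(best.fun), bool(best.success)
    else:
        raise ValidationError(f"unknown optimizer {optimizer!r}")

    raw_ll = float(_loglik_from_counts(prior, sens, *raw))
    return FaceFit(participant_id=data.participant_id, prior=prior, sensitivity=sens,
                   log_likelihood=raw_ll, converged=ok, n_trials=int(raw[1] + raw[3]),
                   below_chance_sensitivity=sens < 0.5, boundary_corrected=corrected)


def _loglik_grid(prior, sens, nh, nf, na, nn):
    """Vectorised log-likelihood over parameter arrays (grid oracle)."""
    pf = posterior_detection_prob(prior, sens)
    pn = posterior_detection_prob(prior, 1.0 - sens)
    pf = np.clip(pf, EPS, 1 - EPS)
    pn = np.clip(pn, EPS, 1 - EPS)
    return (nh * np.log(pf) + (nf - nh) * np.log1p(-pf)
            + na * np.log(pn) + (nn - na) * np.log1p(-pn))


def sdt_summary(data: FaceTaskData) -> SDTSummary:
    """Hit/FA rates with d', c, beta and A'.

    Perfect (0 or 1) observed rates are corrected with the log-linear rule
    (add 0.5 to each cell count, 1 to each denominator); interior rates are
    used as observed.
    """
    nh, nf, na, nn = data.counts()
    if nf == 0 or nn == 0:
        raise FittingError("both stimulus classes are required for SDT summaries")
    h = nh / nf
    f = na / nn
    if h in (0.0, 1.0) or f in (0.0, 1.0):
        h = (nh + 0.5) / (nf + 1.0)
        f = (na + 0.5) / (nn + 1.0)
    zh, zf = stats.norm.ppf(h), stats.norm.ppf(f)
    d = zh - zf
    c = -(zh + zf) / 2.0
    beta = float(np.exp(c * d))
    if h >= f:
        a_prime = 0.5 + ((h - f) * (1 + h - f)) / (4 * h * (1 - f))
    else:
        a_prime = 0.5 - ((f - h) * (1 + f - h)) / (4 * f * (1 - h))
    return SDTSummary(hit_rate=float(h), fa_rate=float(f), d_prime=float(d),
                      criterion_c=float(c), beta=beta, a_prime=float(a_prime))


def read_face_trials(path) -> list[FaceTaskData]:
    """Read a trial-level CSV (participant_id, trial_index, face_present, detected)."""
    df = pd.read_csv(path)
    return face_data_from_frame(df)


def face_data_from_frame(df: pd.DataFrame) -> list[FaceTaskData]:
    required = {"participant_id", "face_present", "detected"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"face trial table missing columns: {sorted(missing)}")
    if "trial_index" in df.columns:
        df = df.sort_values(["participant_id", "trial_index"])
    out = []
    for pid, grp in df.groupby("participant_id", sort=True):
        out.append(FaceTaskData.from_arrays(pid, grp["face_present"].astype(int),
                                            grp["detected"].astype(int)))
    return out


def fit_cohort(datasets: Sequence[FaceTaskData], optimizer: str = "powell") -> pd.DataFrame:
    """Fit every participant; one row per participant with fit + SDT columns."""
    rows = []
    for data in datasets:
        fit = fit_face_model(data, optimizer=optimizer)
        sdt = sdt_summary(data)
        rows.append(dict(participant_id=data.participant_id, prior=fit.prior,
                         sensitivity=fit.sensitivity, log_likelihood=fit.log_likelihood,
                         hit_rate=sdt.hit_rate, fa_rate=sdt.fa_rate, d_prime=sdt.d_prime,
                         criterion_c=sdt.criterion_c, beta=sdt.beta, a_prime=sdt.a_prime,
                         converged=fit.converged))
    return pd.DataFrame(rows)
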