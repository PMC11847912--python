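"""Synthetic cohort generation for remote postoperative wound monitoring.

A cohort is a table of patient responses (eight patient-reported symptom
items, clinician triage label, confirmed-SSI-within-48h outcome, zero or
more wound images) whose marginal and conditional statistics are
calibrated to the published study structure:

* per-response confirmed-SSI rate ``p_ssi48`` (default 3.7%),
* overall symptom-free fraction ``p_no_symptoms`` (default 71.9%) and
  isolated-symptom fraction ``p_isolated_symptom`` (default 16.8%),
* clinician triage conditional SSI rates of 1.4% (low) and 24.0% (high).

Triage labels arise from a latent severity score — true SSI status plus a
weighted symptom burden plus standard normal noise — cut at two
thresholds. The thresholds are solved numerically so the two conditional
rates above hold in expectation: the noise term is integrated analytically
(normal CDF) over a Monte-Carlo reference sample of severity means, which
makes the calibration far more precise than thresholding a single
simulated cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .config import SYMPTOM_ITEMS, TREND_LEVELS, SyntheticConfig
from .images import SyntheticImage, render_wound_image

_CALIBRATION_DRAWS = 60_000

RESPONSE_COLUMNS = (
    ["response_id", "patient_id", "postop_day"]
    + [f"sym_{item}" for item in SYMPTOM_ITEMS]
    + ["triage_label", "ssi48", "image_ids"]
)

IMAGE_COLUMNS = [
    "image_id",
    "response_id",
    "erythema_intensity",
    "pus_count",
    "skin_tone",
    "render_seed",
]


@dataclass
class Cohort:
    """A generated cohort: response table, image ground-truth table, config.

    Image pixels are rendered lazily from the stored per-image seed, so a
    large cohort without downstream image modelling costs nothing; the same
    seed always reproduces the same pixels.
    """

    responses: pd.DataFrame
    images: pd.DataFrame
    config: SyntheticConfig

    def render_image(self, image_id: str) -> SyntheticImage:
        row = self.images.loc[self.images["image_id"] == image_id]
        if row.empty:
            raise KeyError(f"unknown image_id: {image_id}")
        r = row.iloc[0]
        rng = np.random.default_rng(int(r["render_seed"]))
        return render_wound_image(
            erythema_intensity=float(r["erythema_intensity"]),
            pus_count=int(r["pus_count"]),
            skin_tone=float(r["skin_tone"]),
            rng=rng,
            image_size=self.config.image_size,
        )


def _ssi_symptom_probs(config: SyntheticConfig) -> np.ndarray:
    base = np.asarray(config.symptom_baseline, dtype=float)
    eff = np.asarray(config.symptom_effects, dtype=float)
    return expit(logit(base) + eff)


def _nonssi_mixture_weights(config: SyntheticConfig) -> tuple[float, float, float]:
    """Mixture weights (symptom-free, isolated, multiple) for non-SSI rows.

    Calibrated so the *overall* symptom-free and isolated fractions equal
    the configured targets in expectation, accounting for the (small)
    contribution of SSI responses implied by the shifted Bernoulli model.
    """
    p1 = _ssi_symptom_probs(config)
    p_free_ssi = float(np.prod(1.0 - p1))
    p_iso_ssi = float(p_free_ssi * np.sum(p1 / (1.0 - p1)))
    q = config.p_ssi48
    denom = max(1.0 - q, 1e-12)
    w_free = np.clip((config.p_no_symptoms - q * p_free_ssi) / denom, 0.0, 1.0)
    w_iso = np.clip((config.p_isolated_symptom - q * p_iso_ssi) / denom, 0.0, 1.0 - w_free)
    return float(w_free), float(w_iso), float(1.0 - w_free - w_iso)


def _draw_symptoms(ssi: np.ndarray, config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw the (n, 8) boolean symptom matrix given SSI status."""
    n = ssi.size
    base = np.asarray(config.symptom_baseline, dtype=float)
    sym = np.zeros((n, len(SYMPTOM_ITEMS)), dtype=bool)

    idx_ssi = np.flatnonzero(ssi)
    if idx_ssi.size:
        p1 = _ssi_symptom_probs(config)
        sym[idx_ssi] = rng.random((idx_ssi.size, p1.size)) < p1

    idx0 = np.flatnonzero(~ssi.astype(bool))
    if idx0.size:
        w_free, w_iso, w_multi = _nonssi_mixture_weights(config)
        comp = rng.choice(3, size=idx0.size, p=[w_free, w_iso, w_multi])
        iso_rows = idx0[comp == 1]
        if iso_rows.size:
            probs = base / base.sum()
            picks = rng.choice(len(SYMPTOM_ITEMS), size=iso_rows.size, p=probs)
            sym[iso_rows, picks] = True
        multi_rows = idx0[comp == 2]
        if multi_rows.size:
            # 2 + Binomial(6, 0.15) distinct symptoms, weighted by baseline
            counts = 2 + rng.binomial(len(SYMPTOM_ITEMS) - 2, 0.15, size=multi_rows.size)
            probs = base / base.sum()
            for row, m in zip(multi_rows, counts):
                chosen = rng.choice(len(SYMPTOM_ITEMS), size=int(m), replace=False, p=probs)
                sym[row, chosen] = True
    return sym


def _severity_mean(ssi: np.ndarray, symptoms: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    eff = np.asarray(config.symptom_effects, dtype=float)
    burden = symptoms.astype(float) @ eff
    return config.severity_ssi_weight * ssi.astype(float) + config.severity_symptom_scale * burden


def _calibrate_triage_thresholds(config: SyntheticConfig) -> tuple[float, float]:
    """Solve the two severity cutpoints matching the target conditional rates.

    Uses a fixed-seed reference sample of severity means (SSI + symptom
    burden) with the N(0, sd) noise integrated analytically, then brentq on
    the smooth conditional-rate curves. Degenerate targets (no SSI mass)
    push both thresholds to +inf, i.e. everything is triaged low risk.
    """
    r_low, r_high = config.triage_calibration
    if config.p_ssi48 <= 0.0:
        return np.inf, np.inf
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7C1A9]))
    ssi = rng.random(_CALIBRATION_DRAWS) < config.p_ssi48
    symptoms = _draw_symptoms(ssi, config, rng)
    mu = _severity_mean(ssi, symptoms, config)
    sd = config.severity_noise_sd
    mu_ssi = mu[ssi]
    mu_non = mu[~ssi]

    def rate_below(t: float) -> float:
        a = norm.cdf((t - mu_ssi) / sd).sum()
        b = norm.cdf((t - mu_non) / sd).sum()
        return a / max(a + b, 1e-300)

    def rate_above(t: float) -> float:
        a = norm.sf((t - mu_ssi) / sd).sum()
        b = norm.sf((t - mu_non) / sd).sum()
        return a / max(a + b, 1e-300)

    # keep brackets clear of double-precision underflow in the tails
    lo, hi = mu.min() - 8 * sd, mu.max() + 5 * sd
    if rate_below(lo) >= r_low:
        t_low = lo
    else:
        t_low = brentq(lambda t: rate_below(t) - r_low, lo, hi, xtol=1e-10)
    if rate_above(hi) <= r_high:
        t_high = hi  # even the extreme tail never reaches the high-risk rate
    elif rate_above(lo) >= r_high:
        t_high = t_low
    else:
        t_high = brentq(lambda t: rate_above(t) - r_high, lo, hi, xtol=1e-10)
    return float(t_low), float(max(t_high, t_low))


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a full synthetic cohort under ``config``.

    Returns a :class:`Cohort` whose response table follows
    ``RESPONSE_COLUMNS`` (symptom columns hold ``"absent"`` or a trend
    level, which implies presence) and whose image table stores generative
    ground truth plus a per-image render seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    n_pat = config.n_patients

    active = rng.random(n_pat) >= config.nonusage_rate
    n_resp_per_pat = np.where(
        active, 1 + rng.poisson(max(config.mean_responses_per_patient - 1.0, 0.0), n_pat), 0
    )
    skin_tone = rng.uniform(*config.skin_tone_range, size=n_pat)

    patient_ids = np.repeat([f"P{i:05d}" for i in range(n_pat)], n_resp_per_pat)
    pat_index = np.repeat(np.arange(n_pat), n_resp_per_pat)
    n = patient_ids.size

    ssi = rng.random(n) < config.p_ssi48
    postop_day = rng.integers(1, 31, size=n)
    # SSI responses cluster around the typical time-to-diagnosis (~day 10)
    ssi_days = np.clip(np.round(rng.normal(10.0, 5.0, size=n)), 1, 30).astype(int)
    postop_day = np.where(ssi, ssi_days, postop_day)

    symptoms = _draw_symptoms(ssi, config, rng)

    t_low, t_high = _calibrate_triage_thresholds(config)
    severity = _severity_mean(ssi, symptoms, config) + rng.normal(0.0, config.severity_noise_sd, n)
    triage = np.where(severity <= t_low, "low", np.where(severity <= t_high, "moderate", "high"))

    # trend answers for present symptoms; infected wounds trend new/worse
    trend_p_ssi = [0.40, 0.30, 0.20, 0.10]
    trend_p_non = [0.25, 0.15, 0.35, 0.25]
    sym_values = np.full(symptoms.shape, "absent", dtype=object)
    present = np.argwhere(symptoms)
    if present.size:
        rows = present[:, 0]
        draws_ssi = rng.choice(TREND_LEVELS, size=len(rows), p=trend_p_ssi)
        draws_non = rng.choice(TREND_LEVELS, size=len(rows), p=trend_p_non)
        sym_values[present[:, 0], present[:, 1]] = np.where(ssi[rows], draws_ssi, draws_non)

    # images: count per response, truth coupled to SSI status
    n_images = rng.choice(4, size=n, p=np.asarray(config.images_per_response, dtype=float))
    ery = np.where(ssi, rng.beta(7.0, 2.5, n), rng.beta(1.6, 7.0, n))
    pus_rate = np.where(ssi, 1.5, 0.08)
    response_ids = np.empty(n, dtype=object)
    per_pat_counter: dict[str, int] = {}
    for i in range(n):
        k = per_pat_counter.get(patient_ids[i], 0) + 1
        per_pat_counter[patient_ids[i]] = k
        response_ids[i] = f"{patient_ids[i]}-R{k:03d}"

    image_rows = []
    image_ids_col = []
    for i in range(n):
        ids = []
        for j in range(int(n_images[i])):
            image_id = f"{response_ids[i]}-I{j + 1}"
            image_rows.append(
                {
                    "image_id": image_id,
                    "response_id": response_ids[i],
                    "erythema_intensity": float(np.clip(ery[i] + rng.normal(0, 0.05), 0, 1)),
                    "pus_count": int(rng.poisson(pus_rate[i])),
                    "skin_tone": float(skin_tone[pat_index[i]]),
                    "render_seed": int(rng.integers(0, 2**31 - 1)),
                }
            )
            ids.append(image_id)
        image_ids_col.append("|".join(ids))

    responses = pd.DataFrame(
        {
            "response_id": response_ids,
            "patient_id": patient_ids,
            "postop_day": postop_day,
            **{f"sym_{item}": sym_values[:, j] for j, item in enumerate(SYMPTOM_ITEMS)},
            "triage_label": triage,
            "ssi48": ssi.astype(int),
            "image_ids": image_ids_col,
        },
        columns=RESPONSE_COLUMNS,
    )
    images = pd.DataFrame(image_rows, columns=IMAGE_COLUMNS)
    return Cohort(responses=responses, images=images, config=config)
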