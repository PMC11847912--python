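"""Configuration of the synthetic remote-wound-monitoring cohort generator.

The defaults encode the statistical structure of the published remote
postoperative wound-monitoring cohort this package emulates: roughly a
quarter of enrolled patients never submit a response, ~3.7% of responses
are followed by a confirmed surgical-site infection (SSI) within 48 h,
71.9% of responses report no symptoms and 16.8% a single isolated symptom,
and clinician triage conditional SSI rates rise from 1.4% (low risk) to
24.0% (high risk).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

#: The eight patient-reported symptom items, in canonical column order.
SYMPTOM_ITEMS: tuple[str, ...] = (
    "pain",
    "erythema",
    "oedema",
    "warmth",
    "discharge",
    "fever",
    "wound_opening",
    "unwellness",
)

#: Trend answers available for a symptom that is present.
TREND_LEVELS: tuple[str, ...] = ("new", "worse", "same", "better")

# Baseline per-symptom prevalences among symptomatic non-SSI responses and
# log-odds shifts under SSI. Erythema and discharge carry the strongest
# association, matching the clinical picture of wound infection.
_DEFAULT_BASELINE = (0.10, 0.06, 0.06, 0.05, 0.03, 0.04, 0.04, 0.08)
_DEFAULT_EFFECTS = (1.2, 2.6, 1.0, 1.6, 3.0, 1.8, 1.6, 1.4)


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic cohort generator.

    Parameters
    ----------
    n_patients:
        Number of enrolled patients (must be >= 2 so a grouped split is
        possible downstream).
    mean_responses_per_patient:
        Mean number of submitted responses per *active* patient
        (1 + Poisson(mean - 1)).
    nonusage_rate:
        Probability that an enrolled patient never submits a response.
    p_ssi48:
        Per-response probability of confirmed SSI within 48 h.
    p_no_symptoms, p_isolated_symptom:
        Target *overall* fractions of symptom-free and single-symptom
        responses; the non-SSI symptom mixture is calibrated so these
        marginals hold in expectation.
    symptom_effects:
        Per-symptom log-odds shift of symptom presence given SSI.
    symptom_baseline:
        Per-symptom presence probability used for symptomatic non-SSI
        responses.
    triage_calibration:
        (low, high) conditional SSI rates the clinician-triage latent
        severity model is calibrated to.
    severity_ssi_weight, severity_symptom_scale, severity_noise_sd:
        Parameters of the latent severity score behind triage labels.
    images_per_response:
        Distribution over the number of wound images attached to a
        response, as probabilities for counts 0..3.
    image_size:
        Side length in pixels of rendered wound images (>= 64).
    skin_tone_range:
        Interval in [0, 1] the per-patient skin-tone parameter is drawn
        from uniformly (0 = darkest, 1 = lightest base colour).
    seed:
        Root seed; identical config + seed reproduces identical output.
    """

    n_patients: int
    mean_responses_per_patient: float = 5.0
    nonusage_rate: float = 0.25
    p_ssi48: float = 0.037
    p_no_symptoms: float = 0.719
    p_isolated_symptom: float = 0.168
    symptom_effects: tuple[float, ...] = _DEFAULT_EFFECTS
    symptom_baseline: tuple[float, ...] = _DEFAULT_BASELINE
    triage_calibration: tuple[float, float] = (0.014, 0.240)
    severity_ssi_weight: float = 0.8
    severity_symptom_scale: float = 0.30
    severity_noise_sd: float = 1.0
    images_per_response: tuple[float, float, float, float] = (0.30, 0.40, 0.20, 0.10)
    image_size: int = 256
    skin_tone_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2 (grouped splitting needs >= 2 patients)")
        probs = {
            "nonusage_rate": self.nonusage_rate,
            "p_ssi48": self.p_ssi48,
            "p_no_symptoms": self.p_no_symptoms,
            "p_isolated_symptom": self.p_isolated_symptom,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {p}")
        if self.p_no_symptoms + self.p_isolated_symptom > 1.0:
            raise ValueError("p_no_symptoms + p_isolated_symptom must be <= 1")
        if len(self.symptom_effects) != len(SYMPTOM_ITEMS):
            raise ValueError(f"symptom_effects must have {len(SYMPTOM_ITEMS)} entries")
        if len(self.symptom_baseline) != len(SYMPTOM_ITEMS):
            raise ValueError(f"symptom_baseline must have {len(SYMPTOM_ITEMS)} entries")
        lo, hi = self.triage_calibration
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("triage_calibration must satisfy 0 <= low < high <= 1")
        w = np.asarray(self.images_per_response, dtype=float)
        if w.size != 4 or (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError("images_per_response must be 4 probabilities summing to 1")
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if self.mean_responses_per_patient <= 0:
            raise ValueError("mean_responses_per_patient must be positive")
        a, b = self.skin_tone_range
        if not (0.0 <= a <= b <= 1.0):
            raise ValueError("skin_tone_range must be an interval within [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for key in (
            "symptom_effects",
            "symptom_baseline",
            "triage_calibration",
            "images_per_response",
            "skin_tone_range",
        ):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)
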