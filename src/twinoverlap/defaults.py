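"""Default study conditions for the synthetic cohort generator.

The defaults describe a UK-style birth cohort of 1116 same-sex twin
pairs followed to age 18: the published correlated-factors decomposition of
victimization and offending variety scores, the marginal prevalence and
mean of each variety score, the risk-factor-phenotype correlations, and the
pooled prevalence of each adverse childhood experience (ACE) item.
"""

from __future__ import annotations

# Correlated-factors solution of the bivariate ACE model
# (standardized variance components per trait, and the additive-genetic /
# shared-environment / unique-environment factor correlations).
VARIANCE_COMPONENTS_VICTIM = (0.31, 0.19, 0.50)   # (a2, c2, e2)
VARIANCE_COMPONENTS_OFFEND = (0.33, 0.22, 0.45)
FACTOR_CORRELATIONS = (0.28, 0.86, 0.33)  # (rA, rC, rE)

# Variety-score margins: (prevalence of any endorsement, mean variety score)
VICTIM_MARGIN = (0.48, 1.52)
OFFEND_MARGIN = (0.50, 1.74)
VICTIM_MAX = 20   # number of victimization types in the instrument
OFFEND_MAX = 33   # number of offending types

N_PAIRS = 1116
PROP_MZ = 0.55
PROP_MALE = 0.49

# Continuous personal risk factors: target Pearson correlation of the risk
# with the victimization and offending variety scores.
PERSONAL_RISK_LOADINGS: dict[str, tuple[float, float]] = {
    "low_self_control": (0.266, 0.345),
    "cognitive_ability": (-0.088, -0.102),
    "early_puberty": (0.072, 0.019),
    "childhood_delinquency": (0.235, 0.441),
    "childhood_substance_use": (0.192, 0.332),
}

# Reporting scale (mean, sd) for continuous risks; risks are generated on a
# z-score scale and affinely mapped. Cognitive ability is IQ-like, pubertal
# timing a 1-5 Tanner-stage-like scale; the rest stay as z-scores / counts.
PERSONAL_RISK_SCALE: dict[str, tuple[float, float]] = {
    "low_self_control": (0.0, 1.0),
    "cognitive_ability": (99.4, 15.4),
    "early_puberty": (2.65, 1.11),
    "childhood_delinquency": (1.90, 1.95),
    "childhood_substance_use": (0.88, 1.17),
}

# Binary diagnosis treated like an ACE item mechanically (latent threshold).
DIAGNOSIS_LOADINGS: dict[str, tuple[float, float]] = {
    "conduct_disorder": (0.208, 0.320),
}
DIAGNOSIS_PREVALENCES: dict[str, float] = {
    "conduct_disorder": 286 / 1897,
}

# ACE items: 9 "conventional" + 10 "expanded". Prevalences are the pooled
# margins of the four-group comparison table (counts over n = 1897);
# loadings are the published risk-phenotype correlations.
CONVENTIONAL_ACES: list[str] = [
    "physical_abuse",
    "sexual_abuse",
    "emotional_abuse_neglect",
    "physical_neglect",
    "domestic_violence",
    "parental_antisocial_behavior",
    "family_substance_abuse",
    "family_mental_health",
    "parental_separation",
]
EXPANDED_ACES: list[str] = [
    "bullying_victim",
    "foster_care",
    "low_ses",
    "peer_substance_abuse",
    "low_parental_monitoring_mother",
    "low_parental_monitoring_participant",
    "unsafe_neighborhood_perceived",
    "high_neighbor_victimization",
    "neighborhood_rated_unsafe",
    "high_crime_neighborhood",
]
ALL_ACES: list[str] = CONVENTIONAL_ACES + EXPANDED_ACES

ACE_LOADINGS: dict[str, tuple[float, float]] = {
    "physical_abuse": (0.187, 0.140),
    "sexual_abuse": (0.052, 0.061),
    "emotional_abuse_neglect": (0.143, 0.089),
    "physical_neglect": (0.090, 0.062),
    "domestic_violence": (0.124, 0.132),
    "parental_antisocial_behavior": (0.161, 0.151),
    "family_substance_abuse": (0.148, 0.104),
    "family_mental_health": (0.108, 0.072),
    "parental_separation": (0.130, 0.136),
    "bullying_victim": (0.147, 0.023),
    "foster_care": (0.089, 0.068),
    "low_ses": (0.116, 0.107),
    "peer_substance_abuse": (0.168, 0.242),
    "low_parental_monitoring_mother": (0.093, 0.135),
    "low_parental_monitoring_participant": (0.107, 0.213),
    "unsafe_neighborhood_perceived": (0.165, 0.036),
    "high_neighbor_victimization": (0.073, 0.053),
    "neighborhood_rated_unsafe": (0.089, 0.112),
    "high_crime_neighborhood": (0.053, 0.026),
}

ACE_PREVALENCES: dict[str, float] = {
    "physical_abuse": 91 / 1897,
    "sexual_abuse": 16 / 1897,
    "emotional_abuse_neglect": 49 / 1897,
    "physical_neglect": 30 / 1897,
    "domestic_violence": 321 / 1897,
    "parental_antisocial_behavior": 466 / 1897,
    "family_substance_abuse": 407 / 1897,
    "family_mental_health": 566 / 1897,
    "parental_separation": 891 / 1897,
    "bullying_victim": 163 / 1897,
    "foster_care": 15 / 1897,
    "low_ses": 352 / 1897,
    "peer_substance_abuse": 374 / 1897,
    "low_parental_monitoring_mother": 343 / 1897,
    "low_parental_monitoring_participant": 402 / 1897,
    "unsafe_neighborhood_perceived": 232 / 1897,
    "high_neighbor_victimization": 463 / 1897,
    "neighborhood_rated_unsafe": 332 / 1897,
    "high_crime_neighborhood": 432 / 1897,
}
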