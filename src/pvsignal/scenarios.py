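"""Preset synthetic-report scenarios.

Each preset is a complete :class:`~pvsignal.config.ScenarioConfig` and plays a
distinct role:

``default_scenario``
    Emulates the conditions of a large Japanese spontaneous-report extract at
    desk scale: a mixed drug catalog in which bone-resorption inhibitors,
    corticosteroids, sedative-hypnotics, dopaminergic drugs, antivirals and
    aromatase inhibitors carry planted fracture associations, an overall
    fracture-report share around 0.6%, demographic confounding (older,
    female, higher-BMI cases report fractures more often), realistic
    missingness, duplicate rows and implausible anthropometrics.

``null_scenario``
    Many drugs, no planted effects, no confounding: calibrates the false
    signal rate of the disproportionality screen.

``ror_recovery_scenario`` / ``logistic_recovery_scenario``
    Statistical parameter-recovery designs with a single planted effect.
    They use a common (non-rare) outcome and small planted-drug exposure so
    the screen's lnROR, respectively the adjusted logistic coefficient, has a
    small sampling error at the configured case count relative to the
    recovery tolerance (see docs/methods.md for the sizing argument).

``pca_block_scenario``
    Two drug blocks elevate two disjoint fracture-site blocks (an
    osteoclast-mediated block and a fall-type block), giving the lnROR matrix
    a planted two-factor structure for the principal-component map to recover.
"""

from __future__ import annotations

import math

from .config import DemographicModel, ScenarioConfig, _as_drugs, _as_events

__all__ = [
    "default_scenario",
    "null_scenario",
    "ror_recovery_scenario",
    "logistic_recovery_scenario",
    "pca_block_scenario",
]

_BACKGROUND_EVENTS = (
    ("Nausea", False, 0.22),
    ("Rash", False, 0.18),
    ("Pyrexia", False, 0.15),
    ("Hepatic function abnormal", False, 0.12),
    ("Diarrhoea", False, 0.12),
    ("Dizziness", False, 0.10),
    ("Headache", False, 0.10),
    ("Vomiting", False, 0.09),
    ("Interstitial lung disease", False, 0.08),
    ("Malaise", False, 0.08),
    ("Pruritus", False, 0.06),
    ("Fall", False, 0.05),
)


def default_scenario(n_cases: int = 60_000, seed: int = 0) -> ScenarioConfig:
    drugs = _as_drugs([
        # bone-resorption inhibitors (ATC M05B)
        ("alendronic acid", "M05BA04", 0.030),
        ("risedronic acid", "M05BA07", 0.020),
        ("zoledronic acid", "M05BA08", 0.012),
        ("minodronic acid", "M05BA", 0.008),
        ("denosumab", "M05BX04", 0.010),
        # corticosteroids
        ("prednisolone", "H02AB06", 0.050),
        ("methylprednisolone", "H02AB04", 0.012),
        # hypnotics and sedatives
        ("zolpidem", "N05CF02", 0.020),
        ("brotizolam", "N05CD09", 0.012),
        ("zopiclone", "N05CF01", 0.008),
        ("suvorexant", "N05CM19", 0.006),
        # dopaminergic agents
        ("levodopa and carbidopa", "N04BA02", 0.010),
        ("pramipexole", "N04BC05", 0.008),
        # direct acting antivirals
        ("tenofovir disoproxil", "J05AF07", 0.006),
        ("abacavir", "J05AF06", 0.004),
        # hormone antagonists
        ("anastrozole", "L02BG03", 0.008),
        ("enzalutamide", "L02BB04", 0.006),
        # background drugs without planted fracture effects
        ("acetaminophen", "N02BE01", 0.150),
        ("amlodipine", "C08CA01", 0.120),
        ("metformin", "A10BA02", 0.100),
        ("lansoprazole", "A02BC03", 0.100),
        ("rosuvastatin", "C10AA07", 0.080),
        ("loxoprofen", "M01AE", 0.080),
        ("carbocisteine", "R05CB03", 0.060),
        ("warfarin", "B01AA03", 0.050),
    ])
    events = _as_events([
        ("Atypical femur fracture", True, 0.00040),
        ("Fracture", True, 0.00036),
        ("Femur fracture", True, 0.00032),
        ("Spinal compression fracture", True, 0.00026),
        ("Femoral neck fracture", True, 0.00016),
        ("Rib fracture", True, 0.00010),
        ("Upper limb fracture", True, 0.00007),
        ("Cervical vertebral fracture", True, 0.00007),
        ("Jaw fracture", True, 0.00004),
        ("Ulna fracture", True, 0.00004),
        *_BACKGROUND_EVENTS,
    ])
    ln = math.log
    effects = {}
    # osteoclast-mediated block: resorption inhibitors on AFF / jaw / ulna / femur
    for drug, scale in [("alendronic acid", 40.0), ("risedronic acid", 30.0),
                        ("zoledronic acid", 15.0), ("minodronic acid", 25.0),
                        ("denosumab", 30.0)]:
        effects[(drug, "Atypical femur fracture")] = ln(scale)
        effects[(drug, "Jaw fracture")] = ln(scale / 2)
        effects[(drug, "Ulna fracture")] = ln(scale / 2)
        effects[(drug, "Femur fracture")] = ln(scale / 3)
    # corticosteroids: osteoporotic sites plus a weaker osteoclast component
    for drug in ("prednisolone", "methylprednisolone"):
        effects[(drug, "Spinal compression fracture")] = ln(8.0)
        effects[(drug, "Femoral neck fracture")] = ln(6.0)
        effects[(drug, "Rib fracture")] = ln(6.0)
        effects[(drug, "Jaw fracture")] = ln(4.0)
    # fall-mediated block: sedatives and dopaminergics on fall-type sites
    for drug in ("zolpidem", "brotizolam", "zopiclone", "suvorexant",
                 "levodopa and carbidopa", "pramipexole"):
        effects[(drug, "Femoral neck fracture")] = ln(8.0)
        effects[(drug, "Fracture")] = ln(6.0)
        effects[(drug, "Upper limb fracture")] = ln(6.0)
        effects[(drug, "Cervical vertebral fracture")] = ln(5.0)
    # antivirals: diffuse skeletal fragility
    for drug in ("tenofovir disoproxil", "abacavir"):
        effects[(drug, "Fracture")] = ln(10.0)
        effects[(drug, "Femur fracture")] = ln(6.0)
        effects[(drug, "Spinal compression fracture")] = ln(6.0)
    # aromatase inhibition / androgen suppression: osteoporotic sites
    for drug in ("anastrozole", "enzalutamide"):
        effects[(drug, "Spinal compression fracture")] = ln(10.0)
        effects[(drug, "Rib fracture")] = ln(8.0)
        effects[(drug, "Upper limb fracture")] = ln(6.0)
    return ScenarioConfig(
        n_cases=n_cases,
        drugs=drugs,
        events=events,
        planted_effects=effects,
        demographics=DemographicModel(),
        confounding={"age": 0.025, "female": 0.7, "bmi": 0.02},
        missingness={"sex": 0.03, "age": 0.07, "height": 0.58, "weight": 0.51},
        duplicate_rate=0.03,
        outlier_rate=0.003,
        involvement_mix=(0.55, 0.40, 0.05),
        seed=seed,
    )


def null_scenario(n_cases: int = 20_000, n_drugs: int = 200, seed: int = 0) -> ScenarioConfig:
    drugs = _as_drugs([
        (f"drug {i:03d}", f"X{i:03d}", 0.015) for i in range(n_drugs)
    ])
    events = _as_events([
        ("Fracture", True, 0.020),
        ("Femur fracture", True, 0.012),
        ("Spinal compression fracture", True, 0.008),
        *_BACKGROUND_EVENTS,
    ])
    return ScenarioConfig(
        n_cases=n_cases, drugs=drugs, events=events,
        planted_effects={}, confounding={}, missingness={},
        duplicate_rate=0.0, outlier_rate=0.0,
        involvement_mix=(1.0, 0.0, 0.0), seed=seed,
    )


def ror_recovery_scenario(n_cases: int = 50_000, effect: float = math.log(4.0),
                          seed: int = 0) -> ScenarioConfig:
    drugs = _as_drugs([
        ("alendronic acid", "M05BA04", 0.020),
        *[(f"background {i:02d}", f"B{i:02d}", 0.08) for i in range(12)],
    ])
    events = _as_events([
        ("Fracture", True, 0.17),
        *[(t, False, 2.0 * p) for t, _flag, p in _BACKGROUND_EVENTS],
    ])
    return ScenarioConfig(
        n_cases=n_cases, drugs=drugs, events=events,
        planted_effects={("alendronic acid", "Fracture"): effect},
        confounding={}, missingness={},
        duplicate_rate=0.0, outlier_rate=0.0,
        involvement_mix=(1.0, 0.0, 0.0), seed=seed,
    )


def logistic_recovery_scenario(n_cases: int = 100_000, effect: float = math.log(8.0),
                               seed: int = 0) -> ScenarioConfig:
    drugs = _as_drugs([
        ("alendronic acid", "M05BA04", 0.004),
        *[(f"background {i:02d}", f"B{i:02d}", 0.10) for i in range(12)],
    ])
    events = _as_events([
        ("Fracture", True, 0.13),
        *[(t, False, 2.0 * p) for t, _flag, p in _BACKGROUND_EVENTS],
    ])
    return ScenarioConfig(
        n_cases=n_cases, drugs=drugs, events=events,
        planted_effects={("alendronic acid", "Fracture"): effect},
        confounding={"age": 0.02, "female": 0.7, "bmi": 0.02},
        missingness={"sex": 0.05, "age": 0.05, "height": 0.05, "weight": 0.05},
        duplicate_rate=0.0, outlier_rate=0.0,
        involvement_mix=(1.0, 0.0, 0.0), seed=seed,
    )


def pca_block_scenario(n_cases: int = 60_000, seed: int = 0,
                       single_block: bool = False) -> ScenarioConfig:
    ln = math.log
    block_a_drugs = ["alendronic acid", "risedronic acid", "zoledronic acid",
                     "minodronic acid", "denosumab"]
    block_b_drugs = ["zolpidem", "brotizolam", "zopiclone",
                     "levodopa and carbidopa", "pramipexole"]
    background = [f"background {i:02d}" for i in range(14)]
    drugs = _as_drugs(
        [(d, f"A{i:02d}", 0.04) for i, d in enumerate(block_a_drugs)]
        + [(d, f"F{i:02d}", 0.04) for i, d in enumerate(block_b_drugs)]
        + [(d, f"B{i:02d}", 0.04) for i, d in enumerate(background)]
    )
    block_a_events = ["Atypical femur fracture", "Jaw fracture",
                      "Ulna fracture", "Atypical fracture"]
    block_b_events = ["Femoral neck fracture", "Upper limb fracture",
                      "Cervical vertebral fracture", "Rib fracture"]
    neutral_events = ["Fracture", "Pathological fracture"]
    events = _as_events(
        [(t, True, 0.004) for t in block_a_events + block_b_events + neutral_events]
        + list(_BACKGROUND_EVENTS)
    )
    effects = {}
    # strengths vary across drugs within a block so the shared factor has
    # between-drug variance for the correlation PCA to pick up
    strengths = (12.0, 9.0, 6.0, 4.5, 3.0)
    for d, s in zip(block_a_drugs, strengths):
        for t in block_a_events:
            effects[(d, t)] = ln(s)
    if not single_block:
        for d, s in zip(block_b_drugs, strengths):
            for t in block_b_events:
                effects[(d, t)] = ln(s)
    return ScenarioConfig(
        n_cases=n_cases, drugs=drugs, events=events,
        planted_effects=effects, confounding={}, missingness={},
        duplicate_rate=0.0, outlier_rate=0.0,
        involvement_mix=(1.0, 0.0, 0.0), seed=seed,
    )
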