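"""Published normative endotype values for three cohorts.

Trait distributions in NREM sleep have been reported for two community
cohorts analysed with the original MATLAB implementation — the
Osteoporotic Fractures in Men Study (MrOS, n=2316) and the Multi-Ethnic
Study of Atherosclerosis (MESA, n=1792) — and for a clinical cohort from
the China Medical University Hospital (CMUH, n=765) analysed with the
Python implementation.  The tertile (33.3/66.6 percentile) boundaries
below support a coarse low/moderate/high classification of a patient's
traits; no cohort is a default — the user must choose the reference
population (or supply a custom file).

Ventilation traits are %eupnea; loop gains are dimensionless.
"""

from __future__ import annotations

from .endotypes import ReferenceTertiles

COHORTS = ("MrOS", "MESA", "CMUH")

#: 33.3/66.6 percentile trait boundaries per cohort.
COHORT_TERTILES: dict[str, ReferenceTertiles] = {
    "MrOS": ReferenceTertiles(
        cohort="MrOS",
        bounds={
            "vpassive": (70.3, 78.7),
            "vmin": (46.1, 64.9),
            "compensation": (4.1, 11.1),
            "lg1": (0.54, 0.68),
            "lgn": (0.45, 0.55),
            "arousal_threshold": (134.9, 156.0),
        },
    ),
    "MESA": ReferenceTertiles(
        cohort="MESA",
        bounds={
            "vpassive": (76.8, 83.7),
            "vmin": (63.2, 74.8),
            "compensation": (4.3, 8.2),
            "lg1": (0.49, 0.62),
            "lgn": (0.38, 0.47),
            "arousal_threshold": (127.7, 144.4),
        },
    ),
    "CMUH": ReferenceTertiles(
        cohort="CMUH",
        bounds={
            "vpassive": (58.7, 75.5),
            "vmin": (45.7, 59.4),
            "compensation": (-7.4, 6.2),
            "lg1": (0.46, 0.60),
            "lgn": (0.34, 0.42),
            "arousal_threshold": (142.4, 165.3),
        },
    ),
}

#: Cohort mean trait values (same sources), for orientation and checks.
COHORT_MEANS: dict[str, dict[str, float]] = {
    "MrOS": {
        "vpassive": 71.5,
        "vmin": 50.9,
        "compensation": 5.7,
        "lg1": 0.62,
        "lgn": 0.50,
        "arousal_threshold": 148.2,
    },
    "MESA": {
        "vpassive": 77.5,
        "vmin": 63.7,
        "compensation": 6.1,
        "lg1": 0.58,
        "lgn": 0.44,
        "arousal_threshold": 139.5,
    },
    "CMUH": {
        "vpassive": 62.0,
        "vmin": 50.5,
        "compensation": -3.6,
        "lg1": 0.55,
        "lgn": 0.38,
        "arousal_threshold": 159.10,
    },
}
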