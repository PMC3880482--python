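"""Published Danish cost-of-illness results used as reference fixtures.

The 2011 Danish study of the societal cost of osteoporotic fractures
printed its per-person incremental lifetime cost decomposed by health
state and by payer, together with the at-risk cohort sizes.  Those
printed values are inputs here: the aggregation utilities must
reproduce the printed totals and percentage shares exactly, which
anchors the reporting arithmetic independently of the simulation.
All amounts are 2011 EUR per person.
"""

from __future__ import annotations

__all__ = [
    "LIFETIME_COST_BY_STATE",
    "LIFETIME_COST_BY_PAYER",
    "LIFETIME_COST_TOTAL",
    "AT_RISK_COHORT",
    "AT_RISK_FRACTION",
    "NATIONAL_TOTAL_EUR",
]

#: per-person incremental lifetime cost by health state
LIFETIME_COST_BY_STATE = {
    "male": {
        "well": 42.44,
        "wrist": 23.62,
        "post_wrist": 3.32,
        "vertebral": 2_129.51,
        "post_vertebral": 41.77,
        "first_hip": 13_682.59,
        "post_first_hip": 9_187.82,
        "second_hip": 5_759.17,
        "post_second_hip": 4_844.14,
        "death": 0.00,
    },
    "female": {
        "well": 128.85,
        "wrist": 79.16,
        "post_wrist": 114.91,
        "vertebral": 2_462.37,
        "post_vertebral": 479.11,
        "first_hip": 9_385.04,
        "post_first_hip": 5_294.16,
        "second_hip": 4_678.48,
        "post_second_hip": 3_530.10,
        "death": 0.00,
    },
}

#: the same totals decomposed by payer
LIFETIME_COST_BY_PAYER = {
    "male": {
        "regional": 7_621.19,
        "general_practice": 237.69,
        "municipal": 20_381.25,
        "patient": 2_484.78,
        "productivity": 4_989.47,
    },
    "female": {
        "regional": 6_473.71,
        "general_practice": 192.03,
        "municipal": 14_463.27,
        "patient": 1_648.53,
        "productivity": 3_374.64,
    },
}

#: printed per-person lifetime totals (identical across both tables)
LIFETIME_COST_TOTAL = {"male": 35_714.38, "female": 26_152.18}

#: population at risk of osteoporosis, 2011
AT_RISK_COHORT = {"male": 149_466, "female": 388_474}

#: at-risk share of the 50+ population
AT_RISK_FRACTION = {"male": 0.177, "female": 0.408}

#: published national annual burden, EUR
NATIONAL_TOTAL_EUR = {"male": 628e6, "female": 936e6, "total": 1.563e9}
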