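"""Published reference values from the motivating UK Biobank cohort analysis
(n = 175,808; OBS quartiles vs colorectal cancer).

These are *inputs*, not outputs: the package uses them for reporting
transforms (percent risk reduction implied by a hazard ratio), for
count-conservation checks, and to set the scale of simulation defaults.
"""

from __future__ import annotations

#: analytic cohort size and OBS quartile group sizes, [4,19) / [19,22) /
#: [22,26) / [26,41]
ANALYTIC_N = 175_808
QUARTILE_GROUP_SIZES = {"Q1": 40_379, "Q2": 35_004, "Q3": 49_209, "Q4": 51_216}

#: fully adjusted (Model 3) hazard ratios for OBS vs CRC and subsites;
#: "continuous" is per OBS unit, quartile entries are vs Q1
MODEL3_HRS = {
    "crc": {"continuous": 0.974, "Q2": 0.806, "Q3": 0.770, "Q4": 0.713},
    "proximal": {"continuous": 0.981, "Q2": 0.951, "Q3": 0.805, "Q4": 0.784},
    "distal": {"continuous": 0.966, "Q2": 0.652, "Q3": 0.732, "Q4": 0.645},
    "rectal": {"continuous": 0.968, "Q2": 0.842, "Q3": 0.738, "Q4": 0.681},
}

#: percent risk reductions as printed alongside the Model-3 quartile HRs;
#: only rows whose transform is self-consistent with the printed HR
#: (the distal Q4 row prints 36.5 against HR 0.645, whose transform is 35.5,
#: and is therefore excluded here)
PRINTED_RISK_REDUCTIONS = {
    ("crc", "Q2"): 19.4,
    ("crc", "Q3"): 23.0,
    ("crc", "Q4"): 28.7,
    ("proximal", "Q3"): 19.5,
    ("proximal", "Q4"): 21.6,
    ("distal", "Q2"): 34.8,
    ("distal", "Q3"): 26.8,
    ("rectal", "Q3"): 26.2,
    ("rectal", "Q4"): 31.9,
}
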