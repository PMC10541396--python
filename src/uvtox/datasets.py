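"""Reference tables from the underlying UV-filter toxicity study.

The study reports only summary potency tables (no raw dose-response
observations were deposited), so these constants are the study-side
inputs of the pipeline: compound metadata, the single-compound potencies
printed in the text, and the 20-mixture design with its 30-minute
Microtox EC50 denominators.  ``None`` marks a potency that was not
estimable (effect never reached 50% in the tested range).

All single-compound concentrations are mg/L; mixture dilution potencies
are percent of the undiluted mixture.
"""

from __future__ import annotations

from uvtox.assay_core import Compound

# nine organic UV filters; stock concentrations for the crustacean/plant
# tests (the Microtox screening stock was 10 mg/L for all compounds).
# 4-MBC's stock is not reported and defaults to 10 mg/L like the other
# non-benzophenone filters.
COMPOUNDS: dict[str, Compound] = {
    "BP-1": Compound("BP-1", "2,4-dihydroxybenzophenone", stock_conc=100.0),
    "BP-2": Compound("BP-2", "2,2',4,4'-tetrahydroxybenzophenone", stock_conc=100.0),
    "BP-3": Compound("BP-3", "2-hydroxy-4-methoxybenzophenone", stock_conc=12.5),
    "4-MBC": Compound("4-MBC", "4-methylbenzylidene camphor", stock_conc=10.0),
    "EHMC": Compound("EHMC", "ethylhexyl methoxycinnamate", stock_conc=10.0),
    "BMDM": Compound("BMDM", "butyl methoxydibenzoylmethane", stock_conc=10.0),
    "OCR": Compound("OCR", "octocrylene", stock_conc=10.0),
    "EHS": Compound("EHS", "ethylhexyl salicylate", stock_conc=10.0),
    "HMS": Compound("HMS", "homosalate", stock_conc=10.0),
}

MICROTOX_SCREENING_STOCK_MG_L = 10.0
MICROTOX_BASIC_TEST_START_PCT = 81.9  # 2-fold dilution series start

# Marine bacteria (Aliivibrio fischeri), 30 min luminescence inhibition EC50.
# OCR, EHS and HMS never reached 50% inhibition: not estimable.
MICROTOX_EC50_30MIN: dict[str, float | None] = {
    "BP-1": 9.47, "BP-2": 4.52, "BP-3": 4.97, "4-MBC": 15.44,
    "EHMC": 1.38, "BMDM": 2.58, "OCR": None, "EHS": None, "HMS": None,
}

# Brine shrimp (Artemia franciscana), 48 h mortality LC50 (values printed
# in the study's text; the remaining compounds appear only in a figure).
ARTEMIA_LC50_48H: dict[str, float] = {
    "OCR": 0.55, "HMS": 3.06, "BMDM": 3.26, "BP-3": 5.27,
    "BP-1": 15.18, "BP-2": 22.20,
}

# Water flea (Daphnia magna), 48 h immobilisation EC50 (text-printed values).
DAPHNIA_EC50_48H: dict[str, float] = {
    "BMDM": 2.61, "OCR": 2.66, "EHMC": 2.69, "BP-3": 3.25, "BP-2": 54.30,
}

# Duckweed (Lemna minor), 7 d growth-inhibition IC50 (text-printed values).
LEMNA_IC50_7D: dict[str, float] = {
    "HMS": 1.46, "OCR": 1.95, "4-MBC": 2.03, "BMDM": 2.91,
    "EHMC": 3.07, "BP-2": 14.30,
}

MIXTURE_COMPONENT_CONC_MG_L = 10.0  # every component dosed at 10 mg/L

# 14 binary + 6 ternary mixtures, in table order.
MIXTURES: list[tuple[str, list[tuple[str, float]]]] = [
    (mid, [(code, MIXTURE_COMPONENT_CONC_MG_L) for code in mid.split(" + ")])
    for mid in [
        "BP-1 + BP-2",
        "BP-1 + 4-MBC",
        "BP-1 + EHMC",
        "BP-1 + BMDM",
        "BP-2 + BP-3",
        "BP-2 + 4-MBC",
        "BP-2 + EHMC",
        "BP-2 + BMDM",
        "BP-2 + OCR",
        "BP-2 + EHS",
        "BP-2 + HMS",
        "BP-3 + EHMC",
        "BP-3 + BMDM",
        "4-MBC + EHMC",
        "BP-1 + BP-2 + BP-3",
        "BP-2 + BMDM + EHMC",
        "BP-1 + BP-3 + EHMC",
        "BP-2 + BP-3 + EHMC",
        "BP-2 + BP-3 + BMDM",
        "BP-2 + EHS + HMS",
    ]
]

# Mixture dilution potencies EC50 (% of undiluted mixture) per exposure
# time; None = not reached at full strength (reported "> 100%").
MIXTURE_EC50_PERCENT: dict[str, dict[int, float | None]] = {
    "BP-1 + BP-2": {5: 49.54, 15: 47.61, 30: 39.22},
    "BP-1 + 4-MBC": {5: None, 15: None, 30: None},
    "BP-1 + EHMC": {5: 60.72, 15: 69.80, 30: 72.91},
    "BP-1 + BMDM": {5: 61.19, 15: 64.59, 30: 88.26},
    "BP-2 + BP-3": {5: 29.88, 15: 32.78, 30: 46.04},
    "BP-2 + 4-MBC": {5: None, 15: None, 30: None},
    "BP-2 + EHMC": {5: 1.01, 15: 1.09, 30: 0.91},
    "BP-2 + BMDM": {5: None, 15: None, 30: None},
    "BP-2 + OCR": {5: 0.56, 15: 0.63, 30: 0.67},
    "BP-2 + EHS": {5: 0.88, 15: 0.94, 30: 1.32},
    "BP-2 + HMS": {5: 1.32, 15: 2.56, 30: 3.04},
    "BP-3 + EHMC": {5: 1.04, 15: 1.06, 30: 2.29},
    "BP-3 + BMDM": {5: 41.81, 15: 42.91, 30: 96.11},
    "4-MBC + EHMC": {5: 44.61, 15: 51.58, 30: 47.26},
    "BP-1 + BP-2 + BP-3": {5: 44.23, 15: 46.18, 30: 65.30},
    "BP-2 + BMDM + EHMC": {5: None, 15: 80.91, 30: 73.01},
    "BP-1 + BP-3 + EHMC": {5: None, 15: None, 30: None},
    "BP-2 + BP-3 + EHMC": {5: 2.48, 15: 1.41, 30: 1.56},
    "BP-2 + BP-3 + BMDM": {5: 71.46, 15: 66.24, 30: 59.15},
    "BP-2 + EHS + HMS": {5: 4.61, 15: 1.73, 30: 0.88},
}
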