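"""Persoone hazard classification of the study's reported potencies.

Bands the single-compound potencies printed in the study (mg/L scale,
four organisms) and the 30-min mixture dilution potencies (% scale), and
writes the compound x organism class matrix ("n.e." = not estimated) to
results/class_matrix.csv and the mixture classes to
results/mixture_classes.csv.
"""

from pathlib import Path

import pandas as pd

from uvtox import datasets
from uvtox.dose_response import PotencyEstimate
from uvtox.hazard import class_summary, classify_mg_per_l, classify_percent

ROOT = Path(__file__).resolve().parent.parent / "results"

SINGLE_TABLES = [
    ("aliivibrio_fischeri", datasets.MICROTOX_EC50_30MIN),
    ("artemia_franciscana", datasets.ARTEMIA_LC50_48H),
    ("daphnia_magna", datasets.DAPHNIA_EC50_48H),
    ("lemna_minor", datasets.LEMNA_IC50_7D),
]


def main() -> None:
    ROOT.mkdir(parents=True, exist_ok=True)
    estimates = []
    for organism, table in SINGLE_TABLES:
        for code in datasets.COMPOUNDS:
            if code not in table:
                continue  # potency only reported in a figure; not extracted
            value = table[code]
            censored = "none" if value is not None else "above_max_tested"
            estimates.append(PotencyEstimate(
                kind="EC", level=50.0,
                value=value if value is not None else 100.0,
                fit=None, censored=censored,
                compound=code, organism=organism,
            ))
    matrix = class_summary(estimates)
    matrix.to_csv(ROOT / "class_matrix.csv")
    print("Single-compound hazard class matrix:")
    print(matrix.to_string(), "\n")

    rows = []
    for mid, by_time in datasets.MIXTURE_EC50_PERCENT.items():
        v = by_time[30]
        cls = (classify_percent(v) if v is not None
               else classify_percent(PotencyEstimate(
                   "EC", 50.0, 100.0, None, censored="above_max_tested")))
        rows.append({"mixture_id": mid, "ec50_pct_30min": v,
                     "toxicity_class": cls.label})
    mix = pd.DataFrame(rows)
    mix.to_csv(ROOT / "mixture_classes.csv", index=False)
    print("Mixture dilution classes (30 min):")
    print(mix.to_string(index=False))


if __name__ == "__main__":
    main()
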