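"""Toxic-unit interaction typing of the 20 binary/ternary mixtures.

Computes TU_mix = sum C_i / EC50_i for the study's mixture design (every
component at 10 mg/L, 30-min Microtox EC50 denominators) and types each
mixture's interaction.  Expected outcome: 16 computable TU values, all
above 1 (antagonism), and 4 mixtures not estimable because a component
(OCR, EHS or HMS) has no single-compound EC50.  Writes
results/tu_table.csv.
"""

from pathlib import Path

from uvtox import datasets
from uvtox.assay_core import write_results_table
from uvtox.mixtures import summarize_interactions, tu_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ROOT.mkdir(parents=True, exist_ok=True)
    results = tu_table(datasets.MIXTURES, datasets.MICROTOX_EC50_30MIN)
    for r in results:
        tu = "   n.e." if r.tu_mix is None else f"{r.tu_mix:6.2f}"
        print(f"{r.mixture_id:22s} TU_mix {tu}  {r.interaction}")
    counts = summarize_interactions(results)
    print(f"\n{counts['antagonism']} antagonistic, "
          f"{counts['not_estimable']} not estimable "
          f"(of {len(results)} mixtures)")
    write_results_table(results, ROOT / "tu_table.csv")
    print(f"wrote {ROOT / 'tu_table.csv'}")


if __name__ == "__main__":
    main()
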