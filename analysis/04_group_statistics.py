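"""Group-difference statistics over the grouped cohort.

Reads subjects.csv and blocks.csv, then computes the one-way ANOVA of
the response deltas, the two-way (response x marathon, Type II) ANOVA of
the 16-week training parameters with partial eta squared, and the
repeated-measures ANOVAs of the intensity-zone shares over the four
training blocks.  Writes the three tidy ANOVA tables under results/.
"""

from pathlib import Path

import pandas as pd

from marathon_response.pipeline import run_statistics

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    subjects = pd.read_csv(OUT / "subjects.csv")
    blocks = pd.read_csv(OUT / "blocks.csv")
    one_way, two_way, rm = run_statistics(subjects, blocks)
    one_way.to_csv(OUT / "anova_one_way.csv", index=False, float_format="%.6g")
    two_way.to_csv(OUT / "anova_two_way.csv", index=False, float_format="%.6g")
    rm.to_csv(OUT / "anova_repeated_measures.csv", index=False, float_format="%.6g")

    print("one-way ANOVA of the response deltas across response groups:")
    print(one_way[["parameter", "F", "p", "partial_eta2", "stars"]].round(4).to_string(index=False))
    main_effects = two_way[two_way["effect"] != "interaction"]
    wide = main_effects.pivot(index="parameter", columns="effect", values="partial_eta2")
    print("\ntwo-way partial eta squared (response vs marathon main effects):")
    print(wide.round(4).to_string())
    print(f"\nwrote three ANOVA tables under {OUT}")


if __name__ == "__main__":
    main()
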