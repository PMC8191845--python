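"""Cross-tabulate response and marathon-performance groups.

Reads the per-subject table written by 02_run_pipeline.py, reports the
decile-stratified response terciles against the marathon-time terciles,
and compares both assignments with the generator's true tiers.
"""

from pathlib import Path

import pandas as pd

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    subjects = pd.read_csv(OUT / "subjects.csv")
    truth = pd.read_csv(OUT / "truth.csv")
    st = subjects.merge(truth, on="subject_id")

    crosstab = pd.crosstab(st["response"], st["marathon"])
    crosstab.to_csv(OUT / "group_crosstab.csv")
    print("response x marathon group sizes:")
    print(crosstab.to_string())

    resp_agree = (st["response"] == st["response_tier"]).mean()
    mar_agree = (st["marathon"] == st["perf_tier"]).mean()
    print(f"\nresponse-group agreement with generator truth: {resp_agree:.1%}")
    print(f"marathon-group agreement with generator truth:  {mar_agree:.1%}")
    st[["subject_id", "velocity_decile", "response", "marathon",
        "response_tier", "perf_tier"]].to_csv(OUT / "groups.csv", index=False)
    print(f"wrote group_crosstab.csv and groups.csv under {OUT}")


if __name__ == "__main__":
    main()
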