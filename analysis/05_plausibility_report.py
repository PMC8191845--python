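"""Plausibility checks of the cohort: distribution shapes and trends.

Reads subjects.csv and reports the marathon-time and hr_max histograms,
the sorted Δv10 response curve, the regression of marathon velocity on
the overall best 10-km velocity, and the share of marathons started on a
weekend.
"""

from pathlib import Path

import pandas as pd

from marathon_response.stats import plausibility_report

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    s = pd.read_csv(OUT / "subjects.csv")
    rep = plausibility_report(
        s["t_mp"].to_numpy(), s["hr_max"].to_numpy(), s["delta_v10"].to_numpy(),
        s["v10_overall"].to_numpy(), s["v_mp"].to_numpy(),
        s["marathon_start"].to_numpy(),
    )
    pd.DataFrame([{
        "pearson_r": rep.pearson_r, "slope": rep.slope,
        "intercept": rep.intercept, "weekend_share": rep.weekend_share,
    }]).to_csv(OUT / "plausibility.csv", index=False, float_format="%.6g")
    counts, edges = rep.t_mp_hist
    pd.DataFrame({"bin_start_s": edges[:-1], "count": counts}).to_csv(
        OUT / "hist_t_mp.csv", index=False)
    counts, edges = rep.hr_max_hist
    pd.DataFrame({"bin_start_bpm": edges[:-1], "count": counts}).to_csv(
        OUT / "hist_hr_max.csv", index=False)
    pd.DataFrame({"rank": range(len(rep.delta_v10_sorted)),
                  "delta_v10": rep.delta_v10_sorted}).to_csv(
        OUT / "delta_v10_sorted.csv", index=False, float_format="%.6g")

    print(f"marathon times span {s['t_mp'].min()/3600:.2f}-{s['t_mp'].max()/3600:.2f} h")
    print(f"v10 vs v_mp: Pearson r = {rep.pearson_r:.3f} "
          f"(slope {rep.slope:.3f}, intercept {rep.intercept:.3f})")
    print(f"weekend share of marathon starts: {rep.weekend_share:.1%}")
    print(f"wrote plausibility tables under {OUT}")


if __name__ == "__main__":
    main()
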