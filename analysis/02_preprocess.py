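#!/usr/bin/env python
"""Apply the trial-level filtering rules to the simulated cohort.

Reads results/cohort/responses.csv; writes the RT-trimmed table, the
per-participant removal log, and the counting-strategy-filtered duration
trials.  Prints what each rule removed."""

import argparse
from pathlib import Path

from weberkit import preprocess as pp
from weberkit.pipeline import read_responses


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--responses", type=Path, default=Path("results/cohort/responses.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/preprocessed"))
    args = ap.parse_args()

    df = read_responses(args.responses)
    test = df[~df["is_practice"]]
    retained, log = pp.trim_rts(test)
    args.out.mkdir(parents=True, exist_ok=True)
    retained.to_csv(args.out / "responses_trimmed.csv", index=False)
    log.to_csv(args.out / "rt_removal_log.csv", index=False)

    n_fast, n_slow = int(log["n_fast"].sum()), int(log["n_slow"].sum())
    print(f"RT trimming: {len(test)} test trials in, {len(retained)} retained "
          f"({n_fast} fast guesses < 200 ms, {n_slow} slow outliers > mean + 2.5 SD)")

    sym = pp.symbolic_clean(df)
    kept, excluded = pp.exclude_high_error(sym)
    sym.to_csv(args.out / "symbolic_summary.csv", index=False)
    print(f"symbolic task: {len(excluded)} participants above 20% errors "
          f"excluded: {excluded or 'none'}")

    windowed = pp.filter_counting_window(test)
    n_time_removed = len(test) - len(windowed)
    windowed.to_csv(args.out / "responses_counting_window.csv", index=False)
    print(f"counting-strategy window (|target - reference| <= 1200 ms): "
          f"{n_time_removed} duration trials removed (the whole 1:2 bin)")


if __name__ == "__main__":
    main()
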