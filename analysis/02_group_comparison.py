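"""Compare responders and non-responders variable by variable on the
simulated cohort (Welch t / Mann-Whitney for continuous, chi-square /
Fisher for categorical).

Reads results/cohort.csv (run 01 first); writes
results/group_comparison.csv.
"""

import argparse
from pathlib import Path

from ppv_greyzone.cohort_model import apply_validity_filters, read_cohort
from ppv_greyzone.pipeline import compare_groups


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = apply_validity_filters(read_cohort(args.outdir / "cohort.csv"))
    table = compare_groups(cohort)
    table.to_csv(args.outdir / "group_comparison.csv", index=False)
    sig = table[table.p < 0.05]["variable"].tolist()
    print(f"analysed {cohort.n} patients; excluded {len(cohort.exclusion_log)}")
    print(f"variables separating the groups at p < 0.05: {sig}")
    print("(the generator separates groups only on PPV, CVP and baseline stroke")
    print(" volume; any other hits above are chance at the ~5% level)")


if __name__ == "__main__":
    main()
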