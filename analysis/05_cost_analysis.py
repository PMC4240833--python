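"""Risk/benefit analysis: cost-ratio-weighted PPV thresholds per ARDS
stratum (R = 2 / 1 / 0.5 for severe / moderate / mild hypoxemia) and for
the pooled population with per-patient stratum costs.

Reads results/cohort.csv; writes results/cost_analysis.json. The
cost-weighted grey zone (bootstrap CI of cost-optimal thresholds
combined with the unweighted tolerance zone) is a reconstruction — the
source report does not describe its construction.
"""

import argparse
import json
from pathlib import Path

from ppv_greyzone.cohort_model import apply_validity_filters, read_cohort
from ppv_greyzone.cost_weighted import CostSpec, stratified_cost_analysis
from ppv_greyzone.grey_zone import BootstrapConfig
from ppv_greyzone.pipeline import _jsonify


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = apply_validity_filters(read_cohort(args.outdir / "cohort.csv"))
    res = stratified_cost_analysis(
        cohort, "ppv_pct", CostSpec(), BootstrapConfig(1000, args.seed)
    )
    with open(args.outdir / "cost_analysis.json", "w") as fh:
        json.dump(_jsonify(res), fh, indent=2, sort_keys=True)

    for name, row in {**res["strata"], "pooled": res["pooled"]}.items():
        if row.get("status") != "ok":
            print(f"{name}: insufficient data (n = {row.get('n', 0)})")
            continue
        gz = row["grey_zone"]
        print(
            f"{name}: n = {row['n']}, R = {row.get('cost_ratio', 'per-patient')}, "
            f"AUC {row['auc']:.2f}, cost-optimal threshold {row['threshold']:.0f}%, "
            f"grey zone {gz.lower:.0f}-{gz.upper:.0f}% ({gz.source})"
        )
    print("note: a higher false-positive cost (severe stratum, R = 2) pushes the")
    print("cut-off upward; a lower one (mild, R = 0.5) pulls it down.")


if __name__ == "__main__":
    main()
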