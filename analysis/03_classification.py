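#!/usr/bin/env python
"""Shape-factor statistics: Fisher-LSD comparison and jackknife Bayes rates.

Reads results/records.csv (from 02), compares control vs. treated mean shape
factors with Fisher's LSD, and estimates jackknife correct-classification
rates for the BI shape factor alone, the YI alone, and both combined —
reporting the percentage-point gain of the combined feature set per class.
"""

import json
from pathlib import Path

from pearbrowning.classify import (
    improvement_over_singles,
    jackknife_rate,
    lsd_compare,
    read_records,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    records = read_records(ROOT / "results" / "records.csv")
    out = {}
    for feature in ("beta_bi", "beta_yi"):
        table = lsd_compare(records, feature)
        row = table.iloc[0]
        out[f"lsd_{feature}"] = {
            "mean_diff": row.mean_diff, "lsd": row.lsd,
            "p_value": row.p_value, "significant": bool(row.significant),
        }
        print(f"LSD {feature}: control−treated = {row.mean_diff:+.3f} "
              f"(LSD {row.lsd:.3f}, p = {row.p_value:.2e})")
    rates = {
        name: jackknife_rate(records, feats)
        for name, feats in (("bi", ("beta_bi",)), ("yi", ("beta_yi",)),
                            ("both", ("beta_bi", "beta_yi")))
    }
    out["jackknife_percent"] = rates
    out["improvement_points"] = {
        cls: improvement_over_singles(
            [rates["bi"][cls], rates["yi"][cls]], rates["both"][cls]
        )
        for cls in rates["both"]
    }
    for name in ("bi", "yi", "both"):
        r = rates[name]
        print(f"jackknife {name:4s}: control {r['control']:5.2f}%  "
              f"treated {r['treated']:5.2f}%")
    for cls, gain in out["improvement_points"].items():
        print(f"combined-feature gain, {cls}: {gain:+.2f} points")
    path = ROOT / "results" / "classification_analysis.json"
    path.write_text(json.dumps(out, indent=1, sort_keys=True))
    print(f"wrote {path.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
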