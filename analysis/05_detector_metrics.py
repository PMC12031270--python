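#!/usr/bin/env python
"""Evaluation arithmetic for the deployed CNN sorter's field test.

Feeds the benchmark confusion counts (4080 real-time predictions: 2080
brown→brown, 137 brown→good, 0 good→brown, 1863 good→good) through the
exact-rational metric formulas and reports per-class precision, recall and
F1 plus overall accuracy, alongside the benchmark jackknife rates of the
shape-factor classifier and the combined-feature improvement they imply.
"""

import json
from pathlib import Path

from pearbrowning.classify import improvement_over_singles, two_class_report
from pearbrowning.reference import CNN_FIELD_CONFUSION, JACKKNIFE_RATES_PERCENT

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    report = two_class_report(CNN_FIELD_CONFUSION, "brown", "good")
    print(f"field test: {report['total']} predictions, "
          f"accuracy {report['accuracy_percent']:.1f}%")
    for cls in ("brown", "good"):
        m = report[cls]
        print(f"  {cls:5s}: precision {m['precision']}%  recall {m['recall']}%  "
              f"F1 {m['f1']}")
    gains = {
        cls: improvement_over_singles(
            [JACKKNIFE_RATES_PERCENT["bi"][cls], JACKKNIFE_RATES_PERCENT["yi"][cls]],
            JACKKNIFE_RATES_PERCENT["both"][cls],
        )
        for cls in ("control", "treated")
    }
    for cls, g in gains.items():
        print(f"benchmark combined-feature gain, {cls}: {g:+.1f} points")
    out = {"field_metrics": report, "combined_feature_gain_points": gains}
    (ROOT / "results").mkdir(exist_ok=True)
    path = ROOT / "results" / "detector_metrics.json"
    path.write_text(json.dumps(out, indent=1, sort_keys=True))
    print(f"wrote {path.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
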