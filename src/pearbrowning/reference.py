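"""Benchmark evaluation numbers from the pear-browning study.

These are inputs, not results: the printed confusion matrix of the deployed
CNN sorter's field test (4080 real-time predictions of brown vs. good
slices) and the jackknife correct-classification rates of the shape-factor
Bayes classifier on the photograph-derived records.  The metric arithmetic
and improvement calculations in this package operate on them; the trend-line
coefficients the generator emulates live in
:class:`pearbrowning.synthetic.GeneratorConfig`.
"""

from pearbrowning.classify import ConfusionMatrix

__all__ = ["CNN_FIELD_CONFUSION", "JACKKNIFE_RATES_PERCENT"]

#: Field-test confusion counts of the deployed CNN sorter, brown as the
#: positive class: 2080 brown slices predicted brown, 137 brown predicted
#: good, 0 good predicted brown, 1863 good predicted good.
CNN_FIELD_CONFUSION = ConfusionMatrix(TP=2080, FP=0, FN=137, TN=1863)

#: Jackknife correct-classification rates (%) of the kernel-Bayes classifier
#: on the study's 108 control + 108 treated slice records, per feature set.
JACKKNIFE_RATES_PERCENT = {
    "bi": {"control": 71.29, "treated": 79.63},
    "yi": {"control": 85.18, "treated": 70.37},
    "both": {"control": 82.85, "treated": 89.81},
}
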