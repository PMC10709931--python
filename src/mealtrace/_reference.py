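"""Worked-example confusion-count tables for metric validation.

Each row pairs raw event-matching counts (meals, predictions, FP, FN, TP)
with the rounded PPV / TPR / F1 / F2 values those counts imply.  The rows
come from reference runs of this class of per-participant meal-detection
evaluation; they serve as ground truth for the metric arithmetic: tests
and the acceptance script recompute every metric from the counts alone and
compare against the stored rounded strings (half-even decimal rounding at
the stored precision).

The counts satisfy the one-to-one matching identities tp + fp =
predictions and tp + fn = meals, which is itself asserted as an invariant.
"""

from __future__ import annotations

from decimal import ROUND_HALF_EVEN, Decimal
from fractions import Fraction

# Per-participant validation (model-selection) results:
# (participant, classifier, meals, predictions, fp, fn, tp, ppv, tpr, f1, f2)
VALIDATION_BY_PARTICIPANT = [
    ("540", "DecisionTree", 23, 9, 4, 18, 5, "0.56", "0.22", "0.31", "0.25"),
    ("544", "RandomForest", 31, 43, 15, 3, 28, "0.65", "0.90", "0.76", "0.84"),
    ("552", "MLP", 3, 14, 13, 2, 1, "0.07", "0.33", "0.12", "0.19"),
    ("559", "GaussianNB", 25, 32, 18, 11, 14, "0.44", "0.56", "0.49", "0.53"),
    ("563", "DecisionTree", 25, 34, 19, 10, 15, "0.44", "0.60", "0.51", "0.56"),
    ("567", "GradientBoosting", 1, 6, 5, 0, 1, "0.17", "1.00", "0.29", "0.50"),
    ("570", "RandomForest", 29, 40, 19, 8, 21, "0.52", "0.72", "0.61", "0.67"),
    ("575", "MLP", 46, 53, 17, 10, 36, "0.68", "0.78", "0.73", "0.76"),
    ("584", "DecisionTree", 15, 20, 11, 6, 9, "0.45", "0.60", "0.51", "0.56"),
    ("588", "AdaBoost", 43, 49, 17, 11, 32, "0.65", "0.74", "0.70", "0.72"),
    ("591", "AdaBoost", 40, 65, 35, 10, 30, "0.46", "0.75", "0.57", "0.67"),
    ("596", "GradientBoosting", 44, 54, 25, 15, 29, "0.54", "0.66", "0.59", "0.63"),
]

# One participant's validation results per classifier (43 meals):
# (classifier, predictions, fp, fn, tp, ppv, tpr, f1, f2)
VALIDATION_588_BY_CLASSIFIER = [
    ("AdaBoost", 49, 17, 11, 32, "0.65", "0.74", "0.70", "0.72"),
    ("RandomForest", 41, 12, 14, 29, "0.71", "0.67", "0.69", "0.68"),
    ("GradientBoosting", 47, 17, 13, 30, "0.64", "0.70", "0.67", "0.68"),
    ("DecisionTree", 38, 13, 18, 25, "0.66", "0.58", "0.62", "0.60"),
    ("MLP", 38, 13, 18, 25, "0.66", "0.58", "0.62", "0.60"),
    ("GaussianNB", 36, 15, 22, 21, "0.58", "0.49", "0.53", "0.50"),
]
VALIDATION_588_MEALS = 43

# Per-day validation results of the selected classifier for the same
# participant: (day, meals, predictions, fp, fn, tp, ppv, tpr, f1, f2)
VALIDATION_588_BY_DAY = [
    ("2021-10-05", 4, 6, 2, 0, 4, "0.67", "1.00", "0.80", "0.91"),
    ("2021-10-06", 4, 6, 2, 0, 4, "0.67", "1.00", "0.80", "0.91"),
    ("2021-10-07", 4, 5, 2, 1, 3, "0.60", "0.75", "0.67", "0.71"),
    ("2021-10-08", 5, 4, 1, 2, 3, "0.75", "0.60", "0.67", "0.62"),
    ("2021-10-09", 3, 5, 3, 1, 2, "0.40", "0.67", "0.50", "0.59"),
    ("2021-10-10", 3, 2, 1, 2, 1, "0.50", "0.33", "0.40", "0.36"),
    ("2021-10-11", 5, 6, 2, 1, 4, "0.67", "0.80", "0.73", "0.77"),
    ("2021-10-12", 6, 4, 2, 4, 2, "0.50", "0.33", "0.40", "0.36"),
    ("2021-10-13", 4, 6, 2, 0, 4, "0.67", "1.00", "0.80", "0.91"),
    ("2021-10-14", 5, 5, 0, 0, 5, "1.00", "1.00", "1.00", "1.00"),
]
# Macro (per-day arithmetic mean) row for the table above:
VALIDATION_588_MACRO = ("4.3", "4.9", "1.7", "1.1", "3.2", "0.64", "0.75", "0.68", "0.71")

# Per-day test results of the selected classifier, same participant:
TEST_588_BY_DAY = [
    ("2021-10-15", 5, 4, 3, 4, 1, "0.25", "0.20", "0.22", "0.21"),
    ("2021-10-16", 2, 3, 2, 1, 1, "0.33", "0.50", "0.40", "0.45"),
    ("2021-10-17", 4, 8, 6, 2, 2, "0.25", "0.50", "0.33", "0.42"),
    ("2021-10-18", 3, 2, 1, 2, 1, "0.50", "0.33", "0.40", "0.36"),
    ("2021-10-19", 4, 7, 3, 0, 4, "0.57", "1.00", "0.73", "0.87"),
    ("2021-10-20", 4, 6, 2, 0, 4, "0.67", "1.00", "0.80", "0.91"),
    ("2021-10-21", 4, 4, 0, 0, 4, "1.00", "1.00", "1.00", "1.00"),
    ("2021-10-22", 2, 5, 3, 0, 2, "0.40", "1.00", "0.57", "0.77"),
    ("2021-10-23", 2, 3, 1, 0, 2, "0.67", "1.00", "0.80", "0.91"),
    ("2021-10-24", 4, 8, 4, 0, 4, "0.50", "1.00", "0.67", "0.83"),
]
TEST_588_MACRO = ("3.4", "5.0", "2.5", "0.9", "2.5", "0.51", "0.75", "0.59", "0.67")

# Per-participant test results of each selected model:
TEST_BY_PARTICIPANT = [
    ("540", "DecisionTree", 20, 9, 8, 19, 1, "0.11", "0.05", "0.07", "0.06"),
    ("544", "RandomForest", 32, 38, 9, 3, 29, "0.76", "0.91", "0.83", "0.87"),
    ("552", "MLP", 14, 18, 12, 8, 6, "0.33", "0.43", "0.38", "0.41"),
    ("559", "GaussianNB", 23, 31, 20, 12, 11, "0.35", "0.48", "0.41", "0.45"),
    ("563", "DecisionTree", 23, 28, 18, 13, 10, "0.36", "0.43", "0.39", "0.42"),
    ("570", "RandomForest", 31, 37, 13, 7, 24, "0.65", "0.77", "0.71", "0.75"),
    ("575", "MLP", 37, 42, 18, 13, 24, "0.57", "0.65", "0.61", "0.63"),
    ("584", "DecisionTree", 20, 34, 23, 9, 11, "0.32", "0.55", "0.41", "0.48"),
    ("588", "AdaBoost", 34, 50, 25, 9, 25, "0.5", "0.74", "0.6", "0.67"),
    ("591", "AdaBoost", 37, 64, 38, 11, 26, "0.41", "0.7", "0.51", "0.61"),
    ("596", "GradientBoosting", 45, 59, 27, 13, 32, "0.54", "0.71", "0.62", "0.67"),
]


def exact_metrics(tp: int, fp: int, fn: int) -> dict[str, Fraction]:
    """PPV/TPR/F1/F2 as exact rationals from integer counts (0 when tp=0)."""
    if tp == 0:
        zero = Fraction(0)
        return {"ppv": zero, "tpr": zero, "f1": zero, "f2": zero}
    ppv = Fraction(tp, tp + fp)
    tpr = Fraction(tp, tp + fn)
    out = {"ppv": ppv, "tpr": tpr}
    for name, b2 in (("f1", 1), ("f2", 4)):
        out[name] = (1 + b2) * ppv * tpr / (b2 * ppv + tpr)
    return out


def round_like(value: Fraction, printed: str) -> str:
    """Round an exact rational to the precision of the printed string,
    using half-even decimal rounding (e.g. 0.625 -> '0.62')."""
    places = len(printed.split(".")[1]) if "." in printed else 0
    quant = Decimal(1).scaleb(-places)
    d = Decimal(value.numerator) / Decimal(value.denominator)
    return str(d.quantize(quant, rounding=ROUND_HALF_EVEN))
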