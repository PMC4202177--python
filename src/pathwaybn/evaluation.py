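"""Edge-level evaluation of predicted relation networks.

Predictions are compared with a target pathway's edge set by recall (the
fraction of target relations recovered) and precision (the fraction of
predicted relations that are correct), either respecting edge orientation
or ignoring it.  Repeated stochastic runs are summarised by order statistics
(min, quartiles, median, max) and two methods are compared by per-instance
median wins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np

Edge = tuple[str, str]


@dataclass
class EvalResult:
    recall: float
    precision: float
    true_positives: int
    n_target: int
    n_predicted: int
    direction_mode: str

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class MetricSummary:
    minimum: float
    quartile_25: float
    median: float
    quartile_75: float
    maximum: float

    def __post_init__(self) -> None:
        seq = [self.minimum, self.quartile_25, self.median, self.quartile_75, self.maximum]
        if any(a > b + 1e-12 for a, b in zip(seq, seq[1:])):
            raise ValueError("order statistics out of order")


@dataclass
class RunSummary:
    recall: MetricSummary
    precision: MetricSummary
    n_runs: int

    def to_json(self) -> str:
        return json.dumps({"n_runs": self.n_runs,
                           "quantile_rule": "linear interpolation (type 7)",
                           "recall": self.recall.__dict__,
                           "precision": self.precision.__dict__}, indent=1)


def evaluate_edges(predicted: set[Edge], target: set[Edge],
                   direction_mode: str = "directed") -> EvalResult:
    """Edge recall and precision of a prediction against a target edge set."""
    if direction_mode not in ("directed", "undirected"):
        raise ValueError(f"unknown direction mode {direction_mode!r}")
    for e in list(predicted) + list(target):
        if e[0] == e[1]:
            raise ValueError(f"self-edge in input: {e}")
    if direction_mode == "undirected":
        pred: set = {frozenset(e) for e in predicted}
        targ: set = {frozenset(e) for e in target}
    else:
        pred, targ = set(predicted), set(target)
    tp = len(pred & targ)
    recall = tp / len(targ) if targ else 0.0
    precision = tp / len(pred) if pred else 0.0
    return EvalResult(recall, precision, tp, len(targ), len(pred), direction_mode)


def _summary(values: list[float]) -> MetricSummary:
    q = np.percentile(values, [0, 25, 50, 75, 100], method="linear")
    return MetricSummary(*map(float, q))


def summarize_runs(results: list[EvalResult]) -> RunSummary:
    """Order statistics over repeated runs; quartiles by linear interpolation."""
    if not results:
        raise ValueError("no results to summarize")
    return RunSummary(_summary([r.recall for r in results]),
                      _summary([r.precision for r in results]),
                      len(results))


@dataclass
class MethodComparison:
    win_fraction: float
    tie_fraction: float
    loss_fraction: float
    n_instances: int


def compare_methods(a: Mapping[str, RunSummary], b: Mapping[str, RunSummary],
                    metric: str = "recall") -> MethodComparison:
    """Fraction of instances where method a's median strictly beats method b's."""
    if set(a) != set(b):
        raise ValueError("instance sets differ between methods: "
                         f"{sorted(set(a) ^ set(b))}")
    if not a:
        raise ValueError("no instances to compare")
    wins = ties = 0
    for inst in a:
        ma = getattr(a[inst], metric).median
        mb = getattr(b[inst], metric).median
        if ma > mb:
            wins += 1
        elif ma == mb:
            ties += 1
    n = len(a)
    return MethodComparison(wins / n, ties / n, (n - wins - ties) / n, n)
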