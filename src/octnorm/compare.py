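"""Quantifying how flagging changes between two reference databases.

The central bookkeeping object is the 3x3 transition table of flag colors
(green/yellow/red) for the same eyes flagged under database A and database
B.  From it follow the signed changes in true/false positives at the 5%
level (positive = yellow or red) and the 1% level (positive = red), hence
delta sensitivity, delta specificity and delta accuracy, and the share of
eyes whose flag changed at all ("accuracy of flagging" discordance).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .flags import COLORS

__all__ = [
    "TransitionTable",
    "ConfusionDelta",
    "transition_table",
    "delta_confusion",
    "accuracy_of_flagging",
    "screening_projection",
    "round_percent",
]


def round_percent(x: float, digits: int = 1) -> float:
    """Half-up rounding to one decimal, matching report formatting
    (16.39 -> 16.4)."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class TransitionTable:
    """Counts of flag-color changes A -> B over one metric and cohort."""

    counts: dict[tuple[str, str], int]  # (colorA, colorB) -> count
    n: int
    cohort: str = ""
    metric: str = ""

    def __post_init__(self) -> None:
        for pair in self.counts:
            if pair[0] not in COLORS or pair[1] not in COLORS:
                raise ValueError(f"unknown color pair {pair}")
        for a in COLORS:
            for b in COLORS:
                self.counts.setdefault((a, b), 0)
        total = sum(self.counts.values())
        if total != self.n:
            raise ValueError(f"transition cells sum to {total}, expected n={self.n}")

    @classmethod
    def from_counts(
        cls, n: int, cohort: str = "", metric: str = "", **cells: int
    ) -> "TransitionTable":
        """Build from named off-diagonal cells, e.g. ``g_to_y=8, y_to_r=22``;
        the remaining eyes are placed on the green diagonal (unchanged)."""
        short = {"g": "green", "y": "yellow", "r": "red"}
        counts: dict[tuple[str, str], int] = {}
        used = 0
        for key, v in cells.items():
            a, _, b = key.lower().partition("_to_")
            counts[(short[a], short[b])] = int(v)
            if a != b:
                used += int(v)
        diag_given = sum(
            v for (a, b), v in counts.items() if a == b
        )
        counts[("green", "green")] = counts.get(("green", "green"), 0) + (
            n - used - diag_given
        )
        return cls(counts, n, cohort=cohort, metric=metric)

    def n_changed(self) -> int:
        return self.n - sum(self.counts[(c, c)] for c in COLORS)

    def percent_changed(self) -> float:
        return 100.0 * self.n_changed() / self.n if self.n else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.counts[(a, b)] for b in COLORS] for a in COLORS],
            index=pd.Index(COLORS, name="from"),
            columns=pd.Index(COLORS, name="to"),
        )

    def paper_rows(self) -> dict[str, int]:
        """The four row categories used in the published tables plus the two
        extreme transitions the tables omit."""
        c = self.counts
        return {
            "G to Y": c[("green", "yellow")],
            "Y to G": c[("yellow", "green")],
            "Y to R": c[("yellow", "red")],
            "R to Y": c[("red", "yellow")],
            "G to R": c[("green", "red")],
            "R to G": c[("red", "green")],
        }


def transition_table(flagsA: pd.DataFrame, flagsB: pd.DataFrame) -> TransitionTable:
    """Cross-tabulate one metric's flags for the same eyes under two RDBs."""
    metrics = set(flagsA["metric"]) | set(flagsB["metric"])
    if len(metrics) != 1:
        raise ValueError(f"expected one metric, got {sorted(metrics)}")
    a = flagsA.set_index("eye_id")["color"]
    b = flagsB.set_index("eye_id")["color"]
    if set(a.index) != set(b.index) or len(a) != len(b):
        diff = set(a.index).symmetric_difference(set(b.index))
        raise ValueError(f"eye sets differ between flag tables: {sorted(diff)[:10]}")
    b = b.reindex(a.index)
    counts = {
        (ca, cb): int(np.sum((a.to_numpy() == ca) & (b.to_numpy() == cb)))
        for ca in COLORS
        for cb in COLORS
    }
    return TransitionTable(counts, len(a), metric=metrics.pop())


def _delta_positives(table: TransitionTable, level: str) -> int:
    """Signed change (A -> B) in the number of flagged-positive eyes."""
    c = table.counts
    if level == "5%":
        gained = c[("green", "yellow")] + c[("green", "red")]
        lost = c[("yellow", "green")] + c[("red", "green")]
    elif level == "1%":
        gained = c[("yellow", "red")] + c[("green", "red")]
        lost = c[("red", "yellow")] + c[("red", "green")]
    else:
        raise ValueError(f"level must be '5%' or '1%', got {level!r}")
    return gained - lost


@dataclass
class ConfusionDelta:
    """Signed changes in the confusion matrix when switching RDB A -> B."""

    level: str
    delta_tp: int
    delta_tn: int
    n_disease: int
    n_healthy: int

    @property
    def delta_fp(self) -> int:
        return -self.delta_tn

    @property
    def delta_fn(self) -> int:
        return -self.delta_tp

    @property
    def delta_sensitivity(self) -> float:
        return 100.0 * self.delta_tp / self.n_disease

    @property
    def delta_specificity(self) -> float:
        return 100.0 * self.delta_tn / self.n_healthy

    @property
    def delta_accuracy(self) -> float:
        """(dTP + dTN) / (n_disease + n_healthy), the traditional convention."""
        return 100.0 * (self.delta_tp + self.delta_tn) / (self.n_disease + self.n_healthy)

    @property
    def delta_accuracy_tp_only(self) -> float:
        """dTP / (n_disease + n_healthy); emitted alongside the traditional
        convention because published per-level accuracy deltas are not always
        computable under a single convention."""
        return 100.0 * self.delta_tp / (self.n_disease + self.n_healthy)

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "delta_tp": self.delta_tp,
            "delta_tn": self.delta_tn,
            "delta_fp": self.delta_fp,
            "delta_fn": self.delta_fn,
            "delta_sensitivity_pct": self.delta_sensitivity,
            "delta_specificity_pct": self.delta_specificity,
            "delta_accuracy_pct": self.delta_accuracy,
            "delta_accuracy_tp_only_pct": self.delta_accuracy_tp_only,
        }


def delta_confusion(
    tableH: TransitionTable, tableD: TransitionTable, level: str
) -> ConfusionDelta:
    """Changes in TP (disease cohort) and TN (healthy cohort) at one level.

    A healthy eye gaining a positive flag is a new false positive, so
    dTN = -dFP = -(positives gained among healthy).
    """
    delta_tp = _delta_positives(tableD, level)
    delta_fp = _delta_positives(tableH, level)
    return ConfusionDelta(
        level=level,
        delta_tp=delta_tp,
        delta_tn=-delta_fp,
        n_disease=tableD.n,
        n_healthy=tableH.n,
    )


def accuracy_of_flagging(
    flagsA: pd.DataFrame, flagsB: pd.DataFrame, truth_labels: pd.Series | dict
) -> dict:
    """Fraction of eyes whose flag color changed, overall and per truth label.

    ``truth_labels`` maps eye_id -> 'healthy' | 'disease'.  Flag discordance
    is the complement of per-eye flagging agreement between the two RDBs —
    two databases can have near-identical overall test accuracy yet flag
    different individual eyes.
    """
    truth = pd.Series(truth_labels)
    a = flagsA.set_index("eye_id")["color"]
    b = flagsB.set_index("eye_id")["color"].reindex(a.index)
    missing = [e for e in a.index if e not in truth.index]
    if missing:
        raise ValueError(f"missing truth labels for eyes {missing[:10]}")
    changed = (a != b)
    out = {
        "n": int(len(a)),
        "n_changed": int(changed.sum()),
        "percent_discordant": 100.0 * float(changed.mean()),
        "per_cohort": {},
    }
    for label in sorted(set(truth.loc[a.index])):
        mask = truth.loc[a.index] == label
        out["per_cohort"][label] = {
            "n": int(mask.sum()),
            "n_changed": int(changed[mask.to_numpy()].sum()),
            "percent_discordant": 100.0 * float(changed[mask.to_numpy()].mean()),
        }
    return out


def screening_projection(pop_size: int, prevalence: float, delta_sensitivity: float) -> dict:
    """Project a sensitivity change onto a screening population.

    ``delta_sensitivity`` is a fraction (0.164 for +16.4%).  Counts are
    rounded to whole individuals.
    """
    if pop_size < 0 or not 0.0 <= prevalence <= 1.0:
        raise ValueError("need pop_size >= 0 and prevalence in [0, 1]")
    cases = round(pop_size * prevalence)
    additional = round(cases * delta_sensitivity)
    return {
        "pop_size": int(pop_size),
        "cases": int(cases),
        "additional_detected": int(additional),
        "percent_of_population": 100.0 * additional / pop_size if pop_size else 0.0,
        "percent_of_disease": 100.0 * additional / cases if cases else 0.0,
    }
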