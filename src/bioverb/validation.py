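"""Summary arithmetic over expert validation of expanded verb classes.

Experts judge each automatically added candidate verb as a correct or
incorrect member of its class.  Classes belong to one of two domains
(general scientific vs biomedical).  Per class we report percent
correct/incorrect; per domain and overall we report both the **macro**
average (unweighted mean of per-class percentages, the convention used when
such validations are published) and the **micro** figure (pooled counts),
which differ whenever class sizes differ.  Percentages are computed on
unrounded values and rounded half-up to one decimal at report time only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence


@dataclass(frozen=True)
class ClassValidationRecord:
    class_index: str
    class_name: str
    domain: str  # "general" | "biomedical"
    n_candidates: int
    n_correct: int

    def __post_init__(self) -> None:
        if self.domain not in ("general", "biomedical"):
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.n_candidates < 1:
            raise ValueError("n_candidates must be >= 1")
        if not 0 <= self.n_correct <= self.n_candidates:
            raise ValueError(
                f"class {self.class_index}: n_correct {self.n_correct} "
                f"outside [0, {self.n_candidates}]"
            )

    @property
    def pct_correct(self) -> float:
        return 100.0 * self.n_correct / self.n_candidates

    @property
    def pct_incorrect(self) -> float:
        return 100.0 * (self.n_candidates - self.n_correct) / self.n_candidates


@dataclass(frozen=True)
class GroupTotals:
    sum_candidates: int
    sum_correct: int
    sum_incorrect: int
    macro_pct_correct: float
    macro_pct_incorrect: float
    micro_pct_correct: float
    micro_pct_incorrect: float


@dataclass
class ValidationSummary:
    per_class: list[ClassValidationRecord]
    totals: dict[str, GroupTotals]  # keyed "general", "biomedical", "overall"

    def to_json(self, path: str | Path, ndigits: int = 1) -> None:
        payload = {
            "per_class": [
                {
                    "class_index": r.class_index,
                    "class_name": r.class_name,
                    "domain": r.domain,
                    "n_candidates": r.n_candidates,
                    "n_correct": r.n_correct,
                    "pct_correct": round_half_up(r.pct_correct, ndigits),
                    "pct_incorrect": round_half_up(r.pct_incorrect, ndigits),
                }
                for r in self.per_class
            ],
            "totals": {
                key: {
                    "sum_candidates": t.sum_candidates,
                    "sum_correct": t.sum_correct,
                    "sum_incorrect": t.sum_incorrect,
                    "macro_pct_correct": round_half_up(t.macro_pct_correct, ndigits),
                    "macro_pct_incorrect": round_half_up(t.macro_pct_incorrect, ndigits),
                    "micro_pct_correct": round_half_up(t.micro_pct_correct, ndigits),
                    "micro_pct_incorrect": round_half_up(t.micro_pct_incorrect, ndigits),
                }
                for key, t in self.totals.items()
            },
        }
        with open(path, "w", encoding="utf-8") as out:
            json.dump(payload, out, indent=1)
            out.write("\n")


def round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _group_totals(records: Sequence[ClassValidationRecord]) -> GroupTotals:
    n = sum(r.n_candidates for r in records)
    c = sum(r.n_correct for r in records)
    return GroupTotals(
        sum_candidates=n,
        sum_correct=c,
        sum_incorrect=n - c,
        # fsum keeps the macro averages exact under record reordering
        macro_pct_correct=math.fsum(r.pct_correct for r in records) / len(records),
        macro_pct_incorrect=math.fsum(r.pct_incorrect for r in records) / len(records),
        micro_pct_correct=100.0 * c / n,
        micro_pct_incorrect=100.0 * (n - c) / n,
    )


def summarize(records: Sequence[ClassValidationRecord]) -> ValidationSummary:
    """Per-class percentages plus per-domain and overall totals.

    Macro percentages are unweighted means of per-class percentages inside
    each grouping; count totals are plain sums.  Record order does not
    affect any total.
    """
    records = list(records)
    if not records:
        raise ValueError("no validation records")
    totals: dict[str, GroupTotals] = {}
    for domain in ("general", "biomedical"):
        group = [r for r in records if r.domain == domain]
        if group:
            totals[domain] = _group_totals(group)
    totals["overall"] = _group_totals(records)
    return ValidationSummary(per_class=records, totals=totals)


def load_records(path: str | Path) -> list[ClassValidationRecord]:
    """Read a TSV of (class_index, class_name, domain, n_candidates, n_correct)."""
    records = []
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        cols = {name: i for i, name in enumerate(header)}
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            records.append(
                ClassValidationRecord(
                    class_index=parts[cols["class_index"]],
                    class_name=parts[cols["class_name"]],
                    domain=parts[cols["domain"]],
                    n_candidates=int(parts[cols["n_candidates"]]),
                    n_correct=int(parts[cols["n_correct"]]),
                )
            )
    return records


def expert_validation_records() -> list[ClassValidationRecord]:
    """The published 14-class expert-validation counts shipped with the package.

    Seven general-scientific and seven biomedical classes from the expert
    review of the automatically expanded biomedical verb classification.
    """
    ref = resources.files("bioverb.data") / "expert_validation.tsv"
    with resources.as_file(ref) as path:
        return load_records(path)
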