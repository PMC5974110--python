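"""Set algebra and summary arithmetic over detected gene lists.

Two-set Venn partitions (genes exclusive to each list and common to
both), overlap percentages and a:1 count ratios, all reported to one
decimal place with round-half-to-even (the convention that reproduces
the printed style of summary percentages such as 10/160 → 6.2%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

Denominator = Literal["union", "total_sum", "a"]


def _round1(x: float) -> float:
    """Round to one decimal, half to even."""
    return round(float(x), 1)


@dataclass(frozen=True)
class VennPartition:
    """Two-set partition: exclusive-to-A, exclusive-to-B and common genes."""

    exclusive_a: frozenset
    exclusive_b: frozenset
    common: frozenset
    percent_common: float
    denominator: str

    @property
    def n_exclusive_a(self) -> int:
        return len(self.exclusive_a)

    @property
    def n_exclusive_b(self) -> int:
        return len(self.exclusive_b)

    @property
    def n_common(self) -> int:
        return len(self.common)

    @property
    def n_union(self) -> int:
        return self.n_exclusive_a + self.n_exclusive_b + self.n_common

    def summary(self) -> dict:
        return {
            "n_exclusive_a": self.n_exclusive_a,
            "n_exclusive_b": self.n_exclusive_b,
            "n_common": self.n_common,
            "n_union": self.n_union,
            "percent_common": self.percent_common,
            "denominator": self.denominator,
        }


def venn(a: Iterable, b: Iterable, denominator: Denominator = "union") -> VennPartition:
    """Partition two gene lists into exclusive and common subsets.

    ``percent_common`` is 100·|A∩B| over the chosen denominator:
    ``union`` and ``total_sum`` both count every gene once (|A∪B|);
    ``a`` uses |A|.  Reported to one decimal.
    """
    a, b = set(a), set(b)
    common = a & b
    if denominator in ("union", "total_sum"):
        denom = len(a | b)
    elif denominator == "a":
        denom = len(a)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    pct = _round1(100.0 * len(common) / denom) if denom else 0.0
    return VennPartition(
        exclusive_a=frozenset(a - b),
        exclusive_b=frozenset(b - a),
        common=frozenset(common),
        percent_common=pct,
        denominator=denominator,
    )


def overlap_fraction(subset_count: int, total_count: int) -> float:
    """Percentage 100·subset/total to one decimal (e.g. 3 of 22 → 13.6)."""
    if total_count <= 0:
        raise ValueError(f"total_count must be > 0, got {total_count}")
    if not 0 <= subset_count <= total_count:
        raise ValueError(
            f"require 0 <= subset_count <= total_count, got {subset_count}/{total_count}"
        )
    return _round1(100.0 * subset_count / total_count)


def count_ratio(n_a: int, n_b: int) -> float:
    """Count ratio n_a/n_b to one decimal, in the "a:1" convention."""
    if n_b <= 0:
        raise ValueError(f"n_b must be > 0, got {n_b}")
    if n_a < 0:
        raise ValueError(f"n_a must be >= 0, got {n_a}")
    return _round1(n_a / n_b)


def summary_from_counts(counts: dict) -> dict:
    """Derived arithmetic summary of a study's printed gene counts.

    Consumes the count schema of the shipped worked-example fixture
    (overlaps between up-regulated lists, interaction totals per mutant,
    deconvolved vs control-chart detections, spurious-transcription
    tallies) and recomputes every overlap percentage, count ratio and
    total from the raw counts.
    """
    up = counts["up_regulated_overlap"]
    inter = counts["interaction_counts"]
    det = counts["mutant_ratio_detection"]
    annot = counts["negative_interaction_annotation"]
    spur = counts["spurious_transcription"]
    patz = counts["patZ_enhanced"]
    cobb_total = inter["cobB_positive"] + inter["cobB_negative"]
    patz_total = inter["patZ_positive"] + inter["patZ_negative"]
    return {
        "common_up_percent": overlap_fraction(up["common"], up["total"]),
        "cobB_total_interaction_genes": cobb_total,
        "patZ_total_interaction_genes": patz_total,
        "cobB_to_patZ_ratio": count_ratio(cobb_total, patz_total),
        "control_chart_up_shared_percent": overlap_fraction(
            det["control_chart_up_shared"], det["control_chart_up"]
        ),
        "deconvolved_down_specific_percent": overlap_fraction(
            det["deconvolved_down_specific"], det["deconvolved_down"]
        ),
        "negative_interaction_hypothetical_percent": overlap_fraction(
            annot["hypothetical"], annot["total"]
        ),
        "spurious_exponential_total": spur["exponential_false_negative"]
        + spur["exponential_false_positive"],
        "spurious_stationary_total": spur["stationary_false_negative"]
        + spur["stationary_false_positive"],
        "spurious_grand_total": sum(spur.values()),
        "patZ_enhanced_total": patz["from_down_list"] + patz["added_from_control_chart"],
    }
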