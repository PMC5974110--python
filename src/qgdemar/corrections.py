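"""Spurious-transcription corrections for detected gene lists.

Strains whose mutant gene is cloned at an ectopic locus transcribe some
probes spuriously.  Two correction strategies are supported:

1. Quantitative positional control: detect on the WT − ΔN difference
   variable; probes significantly *below* zero are spuriously induced in
   the insertion-bearing strains (false positives for up-regulation) and
   probes significantly *above* zero are spuriously attenuated (false
   negatives for down-regulation).  These lists are crossed against the
   detected lists (``cross_exclude``).
2. Operon blacklist: remove only genes belonging to the operon hosting
   the insertion (default: the paaABCDEFGHIJK operon), a much less
   protective alternative (``operon_exclude``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import pandas as pd

from .deconvolution import DEFAULT_FDR_TARGET, DEFAULT_WINDOW, detect
from .design import ConditionKey, ProbeMatrix, difference

logger = logging.getLogger("qgdemar")

#: Genes of the paa operon hosting the ectopic crp insertion (paaA..paaK).
PAA_OPERON: tuple[str, ...] = (
    "paaA", "paaB", "paaC", "paaD", "paaE", "paaF",
    "paaG", "paaH", "paaI", "paaJ", "paaK",
)


class CorrectionError(ValueError):
    """Invalid correction request (e.g. mixed identifier spaces)."""


@dataclass(frozen=True)
class CorrectionReport:
    """Outcome of removing a spurious list from a detected list."""

    input_id: str
    input_count: int
    removal_id: str
    removed: frozenset
    removed_count: int
    removed_fraction_pct: float
    retained: frozenset

    def __post_init__(self) -> None:
        assert self.removed_count == len(self.removed)
        assert self.input_count == len(self.retained) + len(self.removed)


def load_operon_blacklist(path=None) -> tuple[str, ...]:
    """Read a one-column gene-symbol blacklist; default is the shipped paa list."""
    if path is None:
        text = resources.files("qgdemar").joinpath("data/paa_operon.txt").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    genes = tuple(line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#"))
    return genes


def build_spurious_lists(
    matrix: ProbeMatrix,
    wt: ConditionKey,
    dn: ConditionKey,
    q_lo: float = DEFAULT_WINDOW[0],
    q_hi: float = DEFAULT_WINDOW[1],
    fdr_target: float = DEFAULT_FDR_TARGET,
) -> tuple[frozenset, frozenset]:
    """Detect spuriously transcribed probes from the WT − ΔN difference.

    Returns ``(false_positives, false_negatives)``: lower-tail detections
    (WT − ΔN << 0, over-expressed in the insertion strain) and upper-tail
    detections (WT − ΔN >> 0, under-expressed).  Per-phase lists are built
    by calling once per phase.  ``wt == dn`` is the trivial self-comparison
    and yields empty lists.
    """
    if wt == dn:
        return frozenset(), frozenset()
    result = detect(difference(matrix, wt, dn), q_lo, q_hi, fdr_target)
    false_positives = result.lower.probes
    false_negatives = result.upper.probes
    logger.info(
        "spurious lists from %s - %s: %d false positives, %d false negatives",
        wt, dn, len(false_positives), len(false_negatives),
    )
    return false_positives, false_negatives


def _gene_sets(items: Iterable, gene_map: pd.Series) -> set[str]:
    genes = gene_map.reindex(list(items)).dropna()
    return {str(g) for g in genes if str(g)}


def cross_exclude(
    detected: Iterable,
    spurious: Iterable,
    gene_map: pd.Series | None = None,
    input_id: str = "detected",
    removal_id: str = "spurious",
) -> CorrectionReport:
    """Remove the spurious list from a detected list.

    Without ``gene_map`` both inputs must live in the same identifier
    space (plain set difference).  With ``gene_map`` (probe_id → gene
    symbol) the crossing is done at gene granularity: every detected
    probe whose gene matches a gene of the spurious set is removed.
    """
    detected = set(detected)
    spurious = set(spurious)
    if gene_map is None:
        removed = detected & spurious
    else:
        known = set(gene_map.index)
        stray = [x for x in (detected | spurious) if x not in known]
        if stray:
            raise CorrectionError(
                f"gene-level crossing requires probe ids covered by gene_map; unknown: {sorted(map(str, stray))[:5]}"
            )
        flagged_genes = _gene_sets(spurious, gene_map)
        removed = {p for p in detected if str(gene_map.get(p)) in flagged_genes}
    retained = detected - removed
    frac = 100.0 * len(removed) / len(detected) if detected else 0.0
    return CorrectionReport(
        input_id=input_id,
        input_count=len(detected),
        removal_id=removal_id,
        removed=frozenset(removed),
        removed_count=len(removed),
        removed_fraction_pct=frac,
        retained=frozenset(retained),
    )


def operon_exclude(
    detected: Iterable,
    operon_genes: Iterable[str] = PAA_OPERON,
    gene_map: pd.Series | None = None,
    input_id: str = "detected",
) -> CorrectionReport:
    """Remove only members of an operon blacklist from a detected list.

    ``detected`` may hold gene symbols directly, or probe ids together
    with a ``gene_map`` (probe_id → gene symbol).
    """
    detected = set(detected)
    operon = set(operon_genes)
    if gene_map is None:
        removed = {g for g in detected if g in operon}
    else:
        removed = {p for p in detected if str(gene_map.get(p)) in operon}
    retained = detected - removed
    frac = 100.0 * len(removed) / len(detected) if detected else 0.0
    return CorrectionReport(
        input_id=input_id,
        input_count=len(detected),
        removal_id="operon",
        removed=frozenset(removed),
        removed_count=len(removed),
        removed_fraction_pct=frac,
        retained=frozenset(retained),
    )


def report_to_frame(report: CorrectionReport) -> pd.DataFrame:
    """Serialize a correction report as a tidy table (one row per probe/gene)."""
    rows = [(x, "removed") for x in sorted(report.removed, key=str)]
    rows += [(x, "retained") for x in sorted(report.retained, key=str)]
    return pd.DataFrame(rows, columns=["id", "status"])
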