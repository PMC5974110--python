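"""Probe matrices, factorial condition keys and discrimination variables.

A :class:`ProbeMatrix` holds log2-normalized probe intensities (probes ×
samples) together with per-sample factorial metadata (strain, phase,
replicate).  Analysis stays at probe level throughout — probes are never
summarized into per-gene values; gene symbols ride along as annotation.

From the matrix, four kinds of per-probe discrimination variable are
built over condition means:

- ``log_ratio``      : mean(num) − mean(den), the log2 of the intensity ratio;
  values significantly > 0 mean the numerator condition is up-regulated.
- ``super_ratio``    : the 2×2 factorial interaction — the mutant-vs-wild-type
  log-ratio in one phase minus the same log-ratio in a second phase.
- ``difference``     : mean(a) − mean(b); used for the positional control
  (WT − ΔN), where strongly negative values mark spuriously induced probes.
- ``log2_quotient``  : mean(num) / mean(den) — a literal division of log2
  means, the control-chart ordinate; never silently substituted for the
  log-ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("qgdemar")

VARIABLE_KINDS = ("log_ratio", "super_ratio", "difference", "log2_quotient")


class DesignError(ValueError):
    """Base class for factorial-design errors."""


class UnknownConditionError(DesignError):
    """A condition key matches no sample in the matrix."""


@dataclass(frozen=True)
class ConditionKey:
    """One cell of the factorial design: a (strain, phase) pair."""

    strain: str
    phase: str

    def __str__(self) -> str:
        return f"{self.strain}:{self.phase}"


@dataclass
class ProbeMatrix:
    """Log2 probe intensities with factorial sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by unique probe_id, one column per sample;
        entries are log2 intensities, NaN marks a missing measurement.
    samples
        DataFrame indexed by sample name with columns ``strain``, ``phase``,
        ``replicate`` (and optionally ``growth_rate`` in 1/h, carried as
        metadata only).
    genes
        Optional Series mapping probe_id to gene symbol; probes without a
        symbol hold NaN/empty.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    genes: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise DesignError(f"duplicate probe ids: {dupes[:5]}")
        missing_meta = [c for c in self.values.columns if c not in self.samples.index]
        if missing_meta:
            raise DesignError(f"samples without metadata: {missing_meta}")
        for col in ("strain", "phase"):
            if col not in self.samples.columns:
                raise DesignError(f"sample metadata lacks required column {col!r}")
        self.values.index.name = "probe_id"
        if self.genes is None:
            self.genes = pd.Series(pd.NA, index=self.values.index, name="gene")
        else:
            self.genes = self.genes.reindex(self.values.index)

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_probes(self) -> int:
        return len(self.values.index)

    def condition_columns(self, key: ConditionKey) -> list[str]:
        meta = self.samples.loc[list(self.values.columns)]
        mask = (meta["strain"] == key.strain) & (meta["phase"] == key.phase)
        return list(meta.index[mask])

    def gene_of(self, probes: Iterable) -> set[str]:
        """Unique gene symbols annotating the given probes (unannotated dropped)."""
        sub = self.genes.loc[list(probes)].dropna()
        return set(str(g) for g in sub if str(g))


@dataclass(frozen=True)
class DiscriminationVariable:
    """One scalar per probe, the input to tail detection."""

    kind: str
    values: pd.Series  # indexed by probe_id
    definition: str
    genes: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in VARIABLE_KINDS:
            raise ValueError(f"unknown variable kind {self.kind!r}")

    @property
    def variable_id(self) -> str:
        return f"{self.kind}[{self.definition}]"


@dataclass(frozen=True)
class ConcordanceResult:
    """OLS concordance between two per-probe expression series."""

    slope: float
    intercept: float
    r_squared: float
    n_probes: int


def condition_mean(matrix: ProbeMatrix, key: ConditionKey) -> pd.Series:
    """Per-probe arithmetic mean of log2 values across a condition's replicates.

    Probes missing in some replicates use the mean of the available ones;
    probes missing in all replicates come back NaN (flagged missing).
    """
    cols = matrix.condition_columns(key)
    if not cols:
        raise UnknownConditionError(f"no samples match condition {key}")
    mean = matrix.values[cols].mean(axis=1, skipna=True)
    n_all_missing = int(mean.isna().sum())
    if n_all_missing:
        logger.info("condition %s: %d probes missing in all replicates", key, n_all_missing)
    return mean


def _variable(kind: str, values: pd.Series, definition: str, matrix: ProbeMatrix) -> DiscriminationVariable:
    n_missing = int((~np.isfinite(values.to_numpy(dtype=float))).sum())
    if n_missing:
        logger.info("variable %s[%s]: %d probes excluded as missing", kind, definition, n_missing)
    return DiscriminationVariable(kind=kind, values=values, definition=definition, genes=matrix.genes)


def log_ratio(matrix: ProbeMatrix, numerator: ConditionKey, denominator: ConditionKey) -> DiscriminationVariable:
    """log2 intensity ratio: mean(numerator) − mean(denominator) per probe.

    Positive values mean the numerator condition is up-regulated.
    """
    values = condition_mean(matrix, numerator) - condition_mean(matrix, denominator)
    return _variable("log_ratio", values, f"{numerator}/{denominator}", matrix)


def super_ratio(
    matrix: ProbeMatrix,
    mutant: str,
    wildtype: str,
    condition_1: str,
    condition_2: str,
) -> DiscriminationVariable:
    """2×2 factorial interaction between strain and culture phase.

    ``[mean(mutant, c1) − mean(WT, c1)] − [mean(mutant, c2) − mean(WT, c2)]``.
    A positive value means the mutant-vs-wild-type transcription change in
    ``condition_1`` exceeds the change for the same transition in
    ``condition_2`` (a positive interaction); with ``condition_1`` a
    glucose-limited chemostat and ``condition_2`` batch-exponential this is
    the growth-rate × mutation interaction contrast.
    """
    d1 = condition_mean(matrix, ConditionKey(mutant, condition_1)) - condition_mean(
        matrix, ConditionKey(wildtype, condition_1)
    )
    d2 = condition_mean(matrix, ConditionKey(mutant, condition_2)) - condition_mean(
        matrix, ConditionKey(wildtype, condition_2)
    )
    definition = f"({mutant}-{wildtype})@{condition_1} - ({mutant}-{wildtype})@{condition_2}"
    return _variable("super_ratio", d1 - d2, definition, matrix)


def difference(matrix: ProbeMatrix, a: ConditionKey, b: ConditionKey) -> DiscriminationVariable:
    """Plain difference of condition means, mean(a) − mean(b).

    With ``a = WT`` and ``b = ΔN`` (the positional cloning control), values
    far below zero mark probes spuriously induced by the insertion (false
    positives downstream) and values far above zero mark spuriously
    attenuated probes (false negatives).
    """
    values = condition_mean(matrix, a) - condition_mean(matrix, b)
    return _variable("difference", values, f"{a} - {b}", matrix)


def log2_quotient(matrix: ProbeMatrix, numerator: ConditionKey, denominator: ConditionKey) -> DiscriminationVariable:
    """Division of log2 condition means: mean(num) / mean(den), per probe.

    This is the literal quotient of the log2 intensities (dimensionless,
    clustering near 1 for unchanged probes) — the ordinate of the
    control-chart representation — and is distinct from the log-ratio.
    Probes whose denominator mean is 0 are flagged missing.
    """
    num = condition_mean(matrix, numerator)
    den = condition_mean(matrix, denominator)
    if (den.fillna(0) == 0).all():
        raise DesignError(f"denominator condition {denominator} is zero for every probe")
    values = num / den.where(den != 0)
    return _variable("log2_quotient", values, f"{numerator}/{denominator}", matrix)


def concordance(
    matrix: ProbeMatrix,
    pair_a: tuple[ConditionKey, ConditionKey],
    pair_b: tuple[ConditionKey, ConditionKey] | None = None,
) -> ConcordanceResult:
    """OLS concordance across probes between two expression series.

    With ``pair_b`` omitted, the per-probe condition mean of ``pair_a[0]``
    is regressed on that of ``pair_a[1]`` (the mutant-vs-mutant scatter,
    whose near-unit slope and high R² indicate globally concordant
    transcriptomes).  With ``pair_b`` given, the log-ratio of ``pair_a``
    is regressed on the log-ratio of ``pair_b``.
    """
    if pair_b is None:
        y = condition_mean(matrix, pair_a[0])
        x = condition_mean(matrix, pair_a[1])
    else:
        y = log_ratio(matrix, *pair_a).values
        x = log_ratio(matrix, *pair_b).values
    ok = np.isfinite(x.to_numpy(dtype=float)) & np.isfinite(y.to_numpy(dtype=float))
    n = int(ok.sum())
    if n < 3:
        raise DesignError(f"concordance needs >= 3 shared probes, got {n}")
    fit = stats.linregress(x.to_numpy(dtype=float)[ok], y.to_numpy(dtype=float)[ok])
    return ConcordanceResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_probes=n,
    )
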