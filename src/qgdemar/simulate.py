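"""Factorial spike-in simulator with known differential-expression truth.

Emulates the structure of a two-series *E. coli* Affymetrix study:
~10,207 probes of which 8,662 carry a gene symbol, a small set of strains
(wild type, deletion mutants, a ΔN-like positional cloning control)
crossed with culture phases, and 2–3 replicates per condition.  Each
probe has a baseline log2 intensity shared across conditions; spiked
probes receive an additive log2 offset in designated conditions;
replicate noise is i.i.d. Gaussian.  The returned :class:`SpikeTruth`
records every injected effect, so downstream detection can be scored for
sensitivity and realized false-discovery proportion.

Every random draw comes from a named stream derived from the seed and a
stable label, so adding a spike specification never perturbs the null
draws: the same seed gives bit-identical output for the parts of the
model that did not change.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .deconvolution import DetectionResult
from .design import ProbeMatrix

__all__ = [
    "SpikeSpec",
    "InteractionSpikeSpec",
    "PositionalArtifactSpec",
    "SimulationParams",
    "SpikeTruth",
    "RecoveryReport",
    "SimulationParamsError",
    "UniverseMismatchError",
    "simulate_factorial",
    "evaluate_detection",
]


class SimulationParamsError(ValueError):
    """Invalid simulation parameters; the message names the offending field."""


class UniverseMismatchError(ValueError):
    """Detection result and truth refer to different probe universes."""


def _named_rng(seed: int, name: str) -> np.random.Generator:
    """Independent deterministic stream keyed by (seed, label)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


@dataclass(frozen=True)
class SpikeSpec:
    """Differential spikes in one condition cell (strain, phase).

    ``frac_up`` / ``frac_down`` of all probes receive a ±``effect_size``
    log2 offset to that condition's mean; against any reference condition
    these probes populate the upper / lower tail of the log-ratio.
    """

    strain: str
    phase: str
    frac_up: float = 0.0
    frac_down: float = 0.0
    effect_size: float = 2.0

    @property
    def contrast(self) -> str:
        return f"{self.strain}:{self.phase}"


@dataclass(frozen=True)
class InteractionSpikeSpec:
    """Interaction-only spikes for the super-ratio contrast.

    Implemented as a balanced mutant-only pattern: +effect/2 in
    ``phase_1`` and −effect/2 in ``phase_2`` (reversed for down spikes),
    so the super-ratio carries the full effect while each within-phase
    mutant-vs-WT ratio carries only half of it and the wild-type cells
    stay untouched.
    """

    mutant: str
    phase_1: str
    phase_2: str
    frac_up: float = 0.0
    frac_down: float = 0.0
    effect_size: float = 2.0

    @property
    def contrast(self) -> str:
        return f"interaction:{self.mutant}:{self.phase_1}-{self.phase_2}"


@dataclass(frozen=True)
class PositionalArtifactSpec:
    """Insertion-site artifact: probes over/under-expressed in the strains
    carrying the ectopic cloning, across phases.

    ``phase_fractions`` maps phase → (frac_over, frac_under); the default
    mirrors the asymmetric pattern of a positional control (many more
    spuriously induced probes in exponential phase).  ``strains`` lists
    every strain carrying the insertion (the ΔN-like control and,
    biologically, the mutants cloned at the same locus).
    """

    strains: tuple[str, ...] = ("dN",)
    phase_fractions: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "exponential": (0.0187, 0.0022),
            "stationary": (0.0021, 0.0046),
        }
    )
    effect_size: float = 1.5

    def contrast(self, phase: str) -> str:
        return f"positional:{phase}"


@dataclass(frozen=True)
class SimulationParams:
    """Complete description of one simulated factorial dataset.

    Defaults emulate the CRP-mutant series: 10,207 probes (8,662
    gene-annotated), four strains × two batch phases, duplicate arrays,
    baseline log2 intensities ~ N(7, 1) shared across conditions, and
    replicate noise of 0.25 log2 units.  ``phase_metadata`` (e.g. specific
    growth rates in 1/h) is carried into the sample table as annotation
    only and never used in computation.
    """

    n_probes: int = 10207
    n_annotated: int = 8662
    strains: tuple[str, ...] = ("WT", "dN", "crpQ", "crpR")
    phases: tuple[str, ...] = ("exponential", "stationary")
    phase_metadata: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"exponential": {"growth_rate": 0.62}}
    )
    replicates_per_condition: int = 2
    null_mu: float = 7.0
    null_sigma: float = 1.0
    replicate_sigma: float = 0.25
    spike_specs: tuple[SpikeSpec, ...] = ()
    interaction_spike_specs: tuple[InteractionSpikeSpec, ...] = ()
    positional_artifact_spec: PositionalArtifactSpec | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_probes < 1:
            raise SimulationParamsError("n_probes must be >= 1")
        if not 0 <= self.n_annotated <= self.n_probes:
            raise SimulationParamsError("n_annotated must satisfy 0 <= n_annotated <= n_probes")
        if not self.strains or len(set(self.strains)) != len(self.strains):
            raise SimulationParamsError("strains must be non-empty and unique")
        if not self.phases or len(set(self.phases)) != len(self.phases):
            raise SimulationParamsError("phases must be non-empty and unique")
        if self.replicates_per_condition < 1:
            raise SimulationParamsError("replicates_per_condition must be >= 1")
        if not self.null_sigma > 0:
            raise SimulationParamsError("null_sigma must be > 0")
        if not self.replicate_sigma > 0:
            raise SimulationParamsError("replicate_sigma must be > 0")
        for spec in self.spike_specs:
            self._check_fractions(spec.frac_up, spec.frac_down, spec.effect_size, "spike_specs")
            if spec.strain not in self.strains:
                raise SimulationParamsError(f"spike_specs: unknown strain {spec.strain!r}")
            if spec.phase not in self.phases:
                raise SimulationParamsError(f"spike_specs: unknown phase {spec.phase!r}")
        for spec in self.interaction_spike_specs:
            self._check_fractions(
                spec.frac_up, spec.frac_down, spec.effect_size, "interaction_spike_specs"
            )
            if spec.mutant not in self.strains:
                raise SimulationParamsError(
                    f"interaction_spike_specs: unknown strain {spec.mutant!r}"
                )
            for ph in (spec.phase_1, spec.phase_2):
                if ph not in self.phases:
                    raise SimulationParamsError(
                        f"interaction_spike_specs: unknown phase {ph!r}"
                    )
        pa = self.positional_artifact_spec
        if pa is not None:
            if not pa.effect_size > 0:
                raise SimulationParamsError("positional_artifact_spec: effect_size must be > 0")
            for s in pa.strains:
                if s not in self.strains:
                    raise SimulationParamsError(
                        f"positional_artifact_spec: unknown strain {s!r}"
                    )
            for ph, (f_over, f_under) in pa.phase_fractions.items():
                if ph not in self.phases:
                    raise SimulationParamsError(
                        f"positional_artifact_spec: unknown phase {ph!r}"
                    )
                self._check_fractions(f_over, f_under, pa.effect_size, "positional_artifact_spec")

    @staticmethod
    def _check_fractions(frac_up: float, frac_down: float, effect: float, where: str) -> None:
        for name, frac in (("frac_up", frac_up), ("frac_down", frac_down)):
            if not 0 <= frac <= 1:
                raise SimulationParamsError(f"{where}: {name} must be in [0, 1], got {frac}")
        if frac_up + frac_down >= 0.5:
            raise SimulationParamsError(
                f"{where}: frac_up + frac_down must be < 0.5, got {frac_up + frac_down}"
            )
        if not effect > 0:
            raise SimulationParamsError(f"{where}: effect_size must be > 0, got {effect}")


@dataclass(frozen=True)
class SpikeTruth:
    """Ground truth of every injected effect, per probe and contrast."""

    table: pd.DataFrame  # columns: probe_id, contrast, direction, effect_size
    probe_universe: frozenset

    def probes(self, contrast: str, direction: int | None = None) -> frozenset:
        """Probes spiked in ``contrast``; optionally only one direction (±1)."""
        sub = self.table[self.table["contrast"] == contrast]
        if direction is not None:
            sub = sub[sub["direction"] == direction]
        return frozenset(sub["probe_id"])

    @property
    def contrasts(self) -> set[str]:
        return set(self.table["contrast"].unique())

    def direction_of(self, contrast: str) -> pd.Series:
        """Per-probe direction (−1/0/+1) over the whole universe for a contrast."""
        out = pd.Series(0, index=sorted(self.probe_universe), dtype=int)
        sub = self.table[self.table["contrast"] == contrast]
        if len(sub):
            out.loc[list(sub["probe_id"])] = sub["direction"].to_numpy()
        return out

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _select_disjoint(rng: np.random.Generator, n: int, n_up: int, n_down: int) -> tuple[np.ndarray, np.ndarray]:
    idx = rng.choice(n, size=n_up + n_down, replace=False)
    return idx[:n_up], idx[n_up:]


def simulate_factorial(params: SimulationParams) -> tuple[ProbeMatrix, SpikeTruth]:
    """Generate one factorial probe matrix plus its spike-in ground truth.

    The matrix holds ``n_probes × (|strains|·|phases|·replicates)`` log2
    values: a per-probe baseline ~ N(null_mu, null_sigma) shared across
    conditions, plus the condition-cell offsets implied by the spike
    specifications, plus i.i.d. replicate noise.  Identical parameters and
    seed give bit-identical output.
    """
    params.validate()
    n = params.n_probes
    seed = params.seed
    probe_ids = np.array([f"P{i + 1:06d}" for i in range(n)])
    gene_syms = pd.Series(
        [f"gene_{i + 1:05d}" if i < params.n_annotated else None for i in range(n)],
        index=probe_ids,
        name="gene",
        dtype="object",
    )

    baseline = _named_rng(seed, "baseline").normal(params.null_mu, params.null_sigma, n)
    effects: dict[tuple[str, str], np.ndarray] = {
        (s, p): np.zeros(n) for s in params.strains for p in params.phases
    }
    truth_rows: list[tuple[str, str, int, float]] = []

    for spec in params.spike_specs:
        rng = _named_rng(seed, f"spike:{spec.contrast}")
        up, down = _select_disjoint(
            rng, n, int(round(spec.frac_up * n)), int(round(spec.frac_down * n))
        )
        cell = effects[(spec.strain, spec.phase)]
        cell[up] += spec.effect_size
        cell[down] -= spec.effect_size
        truth_rows += [(probe_ids[i], spec.contrast, +1, spec.effect_size) for i in up]
        truth_rows += [(probe_ids[i], spec.contrast, -1, spec.effect_size) for i in down]

    for spec in params.interaction_spike_specs:
        rng = _named_rng(seed, f"interaction:{spec.contrast}")
        up, down = _select_disjoint(
            rng, n, int(round(spec.frac_up * n)), int(round(spec.frac_down * n))
        )
        half = spec.effect_size / 2.0
        c1 = effects[(spec.mutant, spec.phase_1)]
        c2 = effects[(spec.mutant, spec.phase_2)]
        c1[up] += half
        c2[up] -= half
        c1[down] -= half
        c2[down] += half
        truth_rows += [(probe_ids[i], spec.contrast, +1, spec.effect_size) for i in up]
        truth_rows += [(probe_ids[i], spec.contrast, -1, spec.effect_size) for i in down]

    pa = params.positional_artifact_spec
    if pa is not None:
        for phase, (f_over, f_under) in pa.phase_fractions.items():
            rng = _named_rng(seed, f"positional:{phase}")
            over, under = _select_disjoint(
                rng, n, int(round(f_over * n)), int(round(f_under * n))
            )
            for strain in pa.strains:
                cell = effects[(strain, phase)]
                cell[over] += pa.effect_size
                cell[under] -= pa.effect_size
            truth_rows += [(probe_ids[i], pa.contrast(phase), +1, pa.effect_size) for i in over]
            truth_rows += [(probe_ids[i], pa.contrast(phase), -1, pa.effect_size) for i in under]

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for strain in params.strains:
        for phase in params.phases:
            for rep in range(1, params.replicates_per_condition + 1):
                name = f"{strain}_{phase}_r{rep}"
                noise = _named_rng(seed, f"noise:{strain}:{phase}:{rep}").normal(
                    0.0, params.replicate_sigma, n
                )
                columns[name] = baseline + effects[(strain, phase)] + noise
                row = {"sample": name, "strain": strain, "phase": phase, "replicate": rep}
                row.update(dict(params.phase_metadata.get(phase, {})))
                meta_rows.append(row)

    values = pd.DataFrame(columns, index=probe_ids)
    samples = pd.DataFrame(meta_rows).set_index("sample")
    matrix = ProbeMatrix(values=values, samples=samples, genes=gene_syms)
    truth = SpikeTruth(
        table=pd.DataFrame(
            truth_rows, columns=["probe_id", "contrast", "direction", "effect_size"]
        ),
        probe_universe=frozenset(probe_ids),
    )
    return matrix, truth


@dataclass(frozen=True)
class RecoveryReport:
    """Detection performance against simulator ground truth.

    Sensitivities and false-discovery proportions that are 0/0 are
    reported as ``None`` (absent), e.g. the FDP of an empty detection.
    """

    sensitivity_upper: float | None
    sensitivity_lower: float | None
    fdp_upper: float | None
    fdp_lower: float | None
    n_true_up: int
    n_true_down: int
    n_detected_up: int
    n_detected_down: int
    tp_up: int
    tp_down: int

    @property
    def sensitivity(self) -> float | None:
        """Pooled sensitivity across both tails."""
        total = self.n_true_up + self.n_true_down
        return (self.tp_up + self.tp_down) / total if total else None

    @property
    def fdp(self) -> float | None:
        """Pooled realized false-discovery proportion across both tails."""
        detected = self.n_detected_up + self.n_detected_down
        if detected == 0:
            return None
        false = (self.n_detected_up - self.tp_up) + (self.n_detected_down - self.tp_down)
        return false / detected


def evaluate_detection(result: DetectionResult, truth: SpikeTruth, contrast: str) -> RecoveryReport:
    """Score a detection result against the simulator's ground truth.

    Upper-tail detections are scored against direction +1 spikes of the
    contrast, lower-tail against −1.  Sensitivity = detected true spikes /
    total true spikes; realized FDP = detected non-spikes / detected.
    """
    if not result.probe_ids <= truth.probe_universe:
        extra = sorted(result.probe_ids - truth.probe_universe)[:5]
        raise UniverseMismatchError(f"detection probes not in truth universe, e.g. {extra}")
    true_up = truth.probes(contrast, +1)
    true_down = truth.probes(contrast, -1)
    det_up = result.upper.probes
    det_down = result.lower.probes
    tp_up = len(det_up & true_up)
    tp_down = len(det_down & true_down)
    return RecoveryReport(
        sensitivity_upper=(tp_up / len(true_up)) if true_up else None,
        sensitivity_lower=(tp_down / len(true_down)) if true_down else None,
        fdp_upper=(len(det_up - true_up) / len(det_up)) if det_up else None,
        fdp_lower=(len(det_down - true_down) / len(det_down)) if det_down else None,
        n_true_up=len(true_up),
        n_true_down=len(true_down),
        n_detected_up=len(det_up),
        n_detected_down=len(det_down),
        tp_up=tp_up,
        tp_down=tp_down,
    )
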