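"""Tests for the factorial spike-in simulator and its scoring oracle."""

import numpy as np
import pandas as pd
import pytest

from qgdemar import (
    ConditionKey,
    DetectionResult,
    GaussianNull,
    InteractionSpikeSpec,
    PositionalArtifactSpec,
    SimulationParams,
    SimulationParamsError,
    SpikeSpec,
    SpikeTruth,
    TailDetection,
    UniverseMismatchError,
    detect,
    evaluate_detection,
    log_ratio,
    simulate_factorial,
    super_ratio,
)

SMALL = dict(n_probes=400, n_annotated=300, strains=("WT", "M"),
             phases=("exponential", "chemostat"), replicates_per_condition=2)


class TestSimulateFactorial:
    def test_shape_and_annotation(self):
        matrix, truth = simulate_factorial(SimulationParams(**SMALL, seed=1))
        assert matrix.values.shape == (400, 2 * 2 * 2)
        assert int(matrix.genes.notna().sum()) == 300
        assert truth.probe_universe == set(matrix.probe_ids)

    def test_no_spikes_means_all_null_truth(self):
        _, truth = simulate_factorial(SimulationParams(**SMALL, seed=1))
        assert len(truth.table) == 0
        assert (truth.direction_of("M:chemostat") == 0).all()

    def test_seed_determinism_is_bitwise(self):
        p = SimulationParams(**SMALL, spike_specs=(SpikeSpec("M", "chemostat", 0.02, 0.01, 2.0),), seed=5)
        m1, t1 = simulate_factorial(p)
        m2, t2 = simulate_factorial(p)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_different_seeds_differ(self):
        m1, _ = simulate_factorial(SimulationParams(**SMALL, seed=1))
        m2, _ = simulate_factorial(SimulationParams(**SMALL, seed=2))
        assert not m1.values.equals(m2.values)

    def test_adding_spikes_does_not_perturb_null_draws(self):
        """Named RNG streams: introducing a spike spec changes only the
        spiked probes in the spiked condition."""
        base, _ = simulate_factorial(SimulationParams(**SMALL, seed=9))
        spiked, truth = simulate_factorial(
            SimulationParams(**SMALL, spike_specs=(SpikeSpec("M", "chemostat", 0.05, 0.0, 3.0),), seed=9)
        )
        wt_cols = [c for c in base.values.columns if c.startswith("WT")]
        pd.testing.assert_frame_equal(base.values[wt_cols], spiked.values[wt_cols])
        untouched = sorted(set(base.probe_ids) - truth.probes("M:chemostat"))
        pd.testing.assert_frame_equal(
            base.values.loc[untouched], spiked.values.loc[untouched]
        )

    def test_spike_offsets_are_additive(self):
        base, _ = simulate_factorial(SimulationParams(**SMALL, seed=9))
        spiked, truth = simulate_factorial(
            SimulationParams(**SMALL, spike_specs=(SpikeSpec("M", "chemostat", 0.05, 0.02, 3.0),), seed=9)
        )
        up = sorted(truth.probes("M:chemostat", +1))
        col = "M_chemostat_r1"
        np.testing.assert_allclose(
            spiked.values.loc[up, col] - base.values.loc[up, col], 3.0
        )

    def test_interaction_spikes_hit_super_ratio_at_full_effect(self):
        spec = InteractionSpikeSpec("M", "chemostat", "exponential", 0.02, 0.01, 2.0)
        matrix, truth = simulate_factorial(
            SimulationParams(**SMALL, interaction_spike_specs=(spec,), seed=4)
        )
        var = super_ratio(matrix, "M", "WT", "chemostat", "exponential")
        up = sorted(truth.probes(spec.contrast, +1))
        assert var.values.loc[up].mean() == pytest.approx(2.0, abs=0.4)
        # WT cells are untouched by construction
        base, _ = simulate_factorial(SimulationParams(**SMALL, seed=4))
        wt_cols = [c for c in base.values.columns if c.startswith("WT")]
        pd.testing.assert_frame_equal(base.values[wt_cols], matrix.values[wt_cols])

    def test_positional_artifact_lands_in_designated_strains(self):
        pa = PositionalArtifactSpec(
            strains=("M",), phase_fractions={"exponential": (0.05, 0.0)}, effect_size=1.5
        )
        matrix, truth = simulate_factorial(
            SimulationParams(**SMALL, positional_artifact_spec=pa, seed=6)
        )
        base, _ = simulate_factorial(SimulationParams(**SMALL, seed=6))
        over = sorted(truth.probes("positional:exponential", +1))
        np.testing.assert_allclose(
            matrix.values.loc[over, "M_exponential_r1"]
            - base.values.loc[over, "M_exponential_r1"],
            1.5,
        )
        wt_cols = [c for c in base.values.columns if c.startswith("WT")]
        pd.testing.assert_frame_equal(base.values[wt_cols], matrix.values[wt_cols])

    @pytest.mark.parametrize(
        "bad,field",
        [
            (dict(n_probes=0), "n_probes"),
            (dict(n_annotated=500), "n_annotated"),
            (dict(null_sigma=0.0), "null_sigma"),
            (dict(replicates_per_condition=0), "replicates"),
            (dict(spike_specs=(SpikeSpec("M", "chemostat", 0.3, 0.3, 2.0),)), "frac"),
            (dict(spike_specs=(SpikeSpec("M", "chemostat", -0.1, 0.0, 2.0),)), "frac_up"),
            (dict(spike_specs=(SpikeSpec("M", "chemostat", 0.1, 0.0, 0.0),)), "effect_size"),
            (dict(spike_specs=(SpikeSpec("X", "chemostat", 0.1, 0.0, 1.0),)), "strain"),
        ],
    )
    def test_invalid_params_name_the_field(self, bad, field):
        params = SimulationParams(**{**SMALL, **bad}, seed=0)
        with pytest.raises(SimulationParamsError, match=field):
            simulate_factorial(params)

    @pytest.mark.parametrize("effects", [(1.0, 3.0)])
    def test_sensitivity_monotone_in_effect_size(self, effects):
        """Median sensitivity never decreases when the spike grows."""
        med = []
        for effect in effects:
            sens = []
            for seed in range(5):
                params = SimulationParams(
                    n_probes=3000, n_annotated=2000, strains=("WT", "M"),
                    phases=("exponential", "chemostat"), replicates_per_condition=2,
                    spike_specs=(SpikeSpec("M", "chemostat", 0.01, 0.0, effect),),
                    seed=seed,
                )
                matrix, truth = simulate_factorial(params)
                var = log_ratio(
                    matrix, ConditionKey("M", "chemostat"), ConditionKey("WT", "chemostat")
                )
                rep = evaluate_detection(detect(var), truth, "M:chemostat")
                sens.append(rep.sensitivity_upper)
            med.append(float(np.median(sens)))
        assert med[1] >= med[0]


def _fake_result(universe, up=(), down=()) -> DetectionResult:
    null = GaussianNull(0.0, 1.0, (0.25, 0.75), 100, 1.0)
    def tail(probes):
        if probes:
            return TailDetection("detected", 2.0 if probes is up else -2.0, frozenset(probes), 1.0)
        return TailDetection("NDAS", None, frozenset(), None)
    return DetectionResult(
        variable_id="v", null=null, upper=tail(up), lower=tail(down),
        n_total=len(universe), probe_ids=frozenset(universe),
    )


class TestEvaluateDetection:
    def _truth(self, universe, up=(), down=()):
        rows = [(p, "c", +1, 2.0) for p in up] + [(p, "c", -1, 2.0) for p in down]
        return SpikeTruth(
            table=pd.DataFrame(rows, columns=["probe_id", "contrast", "direction", "effect_size"]),
            probe_universe=frozenset(universe),
        )

    def test_empty_detection_gives_zero_sensitivity_absent_fdp(self):
        universe = [f"p{i}" for i in range(10)]
        rep = evaluate_detection(_fake_result(universe), self._truth(universe, up=["p1"]), "c")
        assert rep.sensitivity_upper == 0.0
        assert rep.fdp_upper is None and rep.fdp is None

    def test_exact_detection_gives_perfect_scores(self):
        universe = [f"p{i}" for i in range(10)]
        rep = evaluate_detection(
            _fake_result(universe, up=("p1", "p2")), self._truth(universe, up=["p1", "p2"]), "c"
        )
        assert rep.sensitivity_upper == 1.0 and rep.fdp_upper == 0.0

    def test_pure_null_detections_are_all_false(self):
        universe = [f"p{i}" for i in range(10)]
        rep = evaluate_detection(_fake_result(universe, up=("p3",)), self._truth(universe), "c")
        assert rep.fdp_upper == 1.0 and rep.sensitivity_upper is None

    def test_mismatched_universe_raises(self):
        rep_universe = ["a", "b"]
        truth = self._truth(["x", "y"])
        with pytest.raises(UniverseMismatchError):
            evaluate_detection(_fake_result(rep_universe), truth, "c")
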