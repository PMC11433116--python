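"""Model types, packaged defaults, validation and config round-trips."""

import dataclasses

import pytest
import yaml

from markovcua import (
    ConfigError,
    HealthState,
    ModelDefinition,
    ModelSettings,
    StrategyDefinition,
    TransitionRule,
    copy_model,
    packaged_model,
    read_model,
    validate,
    write_model,
)
from markovcua.io import model_from_dict, model_to_dict
from markovcua.packaged import packaged_model_path


def minimal_model(**settings_kwargs) -> ModelDefinition:
    """Tiny valid three-state model used to construct violations."""
    return ModelDefinition(
        states=[
            HealthState("start", utility=0.9),
            HealthState("bsc", utility=0.0, followup="none", is_terminal_care=True),
            HealthState("death", utility=0.0, followup="none", is_absorbing=True),
        ],
        rules=[
            TransitionRule("shared", "start", "bsc", 0.1),
            TransitionRule("shared", "bsc", "death", 1.0),
        ],
        strategies=[
            StrategyDefinition("A", 1_000_000.0),
            StrategyDefinition("B", 500_000.0),
        ],
        settings=ModelSettings(horizon_cycles=20, **settings_kwargs),
        start_state="start",
    )


class TestPackagedDefaults:
    def test_upfront_costs(self, rare_model, non_rare_model):
        # radiotherapy fee plus admission/chemotherapy
        assert rare_model.upfront_cost("PBT") == 2_375_000 + 1_325_370
        assert rare_model.upfront_cost("3DCRT") == 727_600 + 1_325_370
        assert (
            non_rare_model.upfront_cost("PBT") - rare_model.upfront_cost("PBT")
            == -775_000
        )

    def test_arm_specific_severe_effusion_probability(self, rare_model):
        # severe pleural effusion only occurs after photon radiotherapy
        probs = {
            r.strategy: r.probability
            for r in rare_model.rules
            if r.from_state == "no_late_ae" and r.to_state == "pe_g3"
        }
        assert probs == {"PBT": 0.0, "3DCRT": 0.06}

    def test_packaged_models_validate_cleanly(self, rare_model, non_rare_model):
        assert validate(rare_model) == []
        assert validate(non_rare_model) == []

    def test_fee_levels_differ_in_exactly_one_scalar(self):
        def flatten(doc, prefix=""):
            if isinstance(doc, dict):
                for k, v in doc.items():
                    yield from flatten(v, f"{prefix}.{k}")
            elif isinstance(doc, list):
                for i, v in enumerate(doc):
                    yield from flatten(v, f"{prefix}[{i}]")
            else:
                yield prefix, doc

        docs = [
            dict(flatten(yaml.safe_load(packaged_model_path(level).read_text())))
            for level in ("rare", "non_rare")
        ]
        assert docs[0].keys() == docs[1].keys()
        diffs = {k for k in docs[0] if docs[0][k] != docs[1][k]}
        assert len(diffs) == 1
        (key,) = diffs
        assert "treatment_fee" in key
        assert docs[0][key] - docs[1][key] == 775_000

    def test_unknown_fee_level_rejected(self):
        with pytest.raises(ValueError, match="fee_level"):
            packaged_model("discounted")

    def test_death_and_terminal_care_structure(self, rare_model):
        death = rare_model.state("death")
        assert death.is_absorbing and death.utility == 0 and death.entry_cost == 0
        bsc = rare_model.state("bsc")
        assert bsc.is_terminal_care
        assert bsc.utility == 0.32
        assert bsc.entry_cost == 632_100


class TestValidate:
    def test_overcommitted_row_reported(self):
        m = minimal_model()
        m.rules.append(TransitionRule("shared", "start", "death", 0.95))
        violations = validate(m)
        assert any("row sum" in v for v in violations)

    def test_utility_ordering_violation_reported(self, rare_model):
        m = copy_model(rare_model)
        m.state("rp_g1").utility = 0.80  # below Grade 2's 0.83
        violations = validate(m)
        assert any("utility ordering" in v for v in violations)
        assert any("rp_g1" in v for v in violations)

    @pytest.mark.parametrize(
        "mutate, fragment",
        [
            (lambda m: setattr(m.state("start"), "utility", 1.4), "utility"),
            (lambda m: setattr(m.state("start"), "entry_cost", -5.0), "entry cost"),
            (lambda m: setattr(m.settings, "annual_discount_rate", 1.5), "discount"),
            (lambda m: setattr(m.rules[0], "window_start", 0), "window_start"),
            (lambda m: setattr(m.rules[0], "probability", -0.1), "probability"),
            (lambda m: setattr(m.strategies[0], "treatment_fee", -2e6), "upfront"),
        ],
    )
    def test_invariant_violations_reported(self, mutate, fragment):
        m = minimal_model()
        mutate(m)
        violations = validate(m)
        assert violations, "expected at least one violation"
        assert any(fragment in v for v in violations)

    def test_unreachable_death_reported(self):
        m = minimal_model()
        m.rules = [TransitionRule("shared", "bsc", "death", 1.0)]
        assert any("no path" in v for v in validate(m))

    def test_missing_death_state_reported(self):
        m = minimal_model()
        m.states = m.states[:2]
        m.rules = m.rules[:1]
        assert any("death" in v for v in validate(m))


class TestConfigRoundTrip:
    def test_round_trip_is_field_identical(self, rare_model, tmp_path):
        path = tmp_path / "model.yaml"
        write_model(rare_model, path)
        again = read_model(path)
        assert dataclasses.asdict(again) == dataclasses.asdict(rare_model)

    def test_missing_death_state_rejected(self, rare_model, tmp_path):
        doc = model_to_dict(rare_model)
        doc["states"] = [s for s in doc["states"] if s["id"] != "death"]
        doc["rules"] = [r for r in doc["rules"] if r["to"] != "death"]
        with pytest.raises(ConfigError, match="death"):
            model_from_dict(doc)

    def test_negative_probability_rejected(self, rare_model):
        doc = model_to_dict(rare_model)
        doc["rules"][2]["probability"] = -0.1
        with pytest.raises(ConfigError, match="probability"):
            model_from_dict(doc)

    def test_unknown_state_reference_rejected(self, rare_model):
        doc = model_to_dict(rare_model)
        doc["rules"][2]["to"] = "nonexistent"
        with pytest.raises(ConfigError, match="nonexistent"):
            model_from_dict(doc)

    @pytest.mark.parametrize(
        "corrupt, key",
        [
            (lambda d: d.pop("start_state"), "start_state"),
            (lambda d: d["settings"].pop("horizon_cycles"), "horizon_cycles"),
            (lambda d: d["states"][0].pop("id"), "id"),
            (lambda d: d["states"][0].update(utility="high"), "utility"),
        ],
    )
    def test_malformed_configs_name_offending_key(self, rare_model, corrupt, key):
        doc = model_to_dict(rare_model)
        corrupt(doc)
        with pytest.raises(ConfigError, match=key):
            model_from_dict(doc)
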