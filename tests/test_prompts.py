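"""Scale binning, template rendering, augmentation and prompt assembly."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modfus.augment import RuleBasedParaphraser, augment_sentence
from modfus.exceptions import CapacityError, ScoreRangeError, ValidationError
from modfus.scales import (
    ClinicalRecord,
    ScaleDefinition,
    build_prompt_set,
    categorize_score,
    render_sentence,
    sample_training_prompt,
)


def _record(scale_defs, **overrides):
    scores = {"MDS-UPDRS": 20.0, "STAI": 41.0, "ESS": 7.0, "CDT": 4.0}
    scores.update(overrides)
    return ClinicalRecord(subject_id="S1", scores=scores, diagnosis=1)


class TestCategorize:
    @pytest.mark.parametrize(
        "score,expected",
        [(3, "Mild"), (6, "Moderate"), (10.9, "Moderate"), (11, "Significant"),
         (16, "Serious"), (24, "Serious"), (0, "Mild")],
    )
    def test_half_open_bins_final_bin_closed(self, ess_def, score, expected):
        assert categorize_score(score, ess_def) == expected

    def test_out_of_range_names_the_scale(self, ess_def):
        with pytest.raises(ScoreRangeError, match="ESS"):
            categorize_score(25, ess_def)

    def test_inverted_scale_maps_low_scores_to_severe(self, scale_defs):
        cdt = scale_defs["CDT"]
        assert categorize_score(0, cdt) == "Serious"
        assert categorize_score(5, cdt) == "Mild"

    def test_bin_coverage_and_monotonicity_on_half_step_grid(self, scale_defs):
        for sdef in scale_defs.values():
            lo, hi = sdef.score_range
            grid = np.arange(lo, hi + 0.25, 0.5)
            grid = grid[grid <= hi]
            indices = []
            for s in grid:
                label = categorize_score(float(s), sdef)
                assert label in sdef.labels  # exactly one label, no gaps
                i = sdef.labels.index(label)
                indices.append(len(sdef.labels) - 1 - i if sdef.invert else i)
            assert all(a <= b for a, b in zip(indices, indices[1:]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=24.0, allow_nan=False))
    def test_any_in_range_score_gets_exactly_one_bin(self, score):
        sdef = ScaleDefinition(
            "ESS", (0, 24), (6, 11, 16),
            template="The subject noted {label} (ESS) drowsiness during the day.",
        )
        label = categorize_score(score, sdef)
        i = sdef.labels.index(label)
        edges = (0,) + sdef.breakpoints + (24,)
        assert edges[i] <= score and (score < edges[i + 1] or i == 3)


class TestRender:
    def test_published_template_fills_in_the_label(self, ess_def):
        assert (
            render_sentence(ess_def, "Moderate")
            == "The subject noted Moderate (ESS) drowsiness during the day."
        )

    def test_label_appears_exactly_once(self, ess_def):
        assert render_sentence(ess_def, "Mild").count("Mild") == 1

    def test_unknown_label_rejected(self, ess_def):
        with pytest.raises(ValidationError):
            render_sentence(ess_def, "Catastrophic")

    @pytest.mark.parametrize("template", ["no placeholder here", "{label} and {label}"])
    def test_bad_templates_rejected_at_construction(self, template):
        with pytest.raises(ValidationError):
            ScaleDefinition("ESS", (0, 24), (6, 11, 16), template=template)

    def test_breakpoints_must_increase_inside_range(self):
        with pytest.raises(ValidationError):
            ScaleDefinition("X", (0, 10), (5, 5), labels=("a", "b", "c"),
                            template="{label}")
        with pytest.raises(ValidationError):
            ScaleDefinition("X", (0, 10), (0, 5), labels=("a", "b", "c"),
                            template="{label}")


class TestAugment:
    SENT = "The subject noted Moderate (ESS) drowsiness during the day."

    def test_n_equals_one_is_identity(self):
        assert augment_sentence(self.SENT, 1) == [self.SENT]

    def test_deterministic_given_seed(self):
        a = augment_sentence(self.SENT, 8, seed=7)
        b = augment_sentence(self.SENT, 8, seed=7)
        assert a == b
        assert a[0] == self.SENT
        assert len(set(a)) == 8

    def test_severity_label_survives_every_variant(self, ess_def):
        for variant in augment_sentence(self.SENT, 8, seed=3):
            hits = [lab for lab in ess_def.labels if lab in variant]
            assert hits == ["Moderate"]

    def test_capacity_error_suggests_alternatives(self):
        with pytest.raises(CapacityError, match="plugin"):
            augment_sentence("Entirely unrelated wording.", 4, seed=0)

    def test_bank_capacity_covers_large_n(self):
        bank = RuleBasedParaphraser()
        assert bank.capacity(self.SENT) >= 32
        out = augment_sentence(self.SENT, 32, seed=1)
        assert len(set(out)) == 32

    def test_plugin_augmenter_is_honoured(self):
        class Fake:
            def paraphrases(self, sentence, k, seed):
                return [f"{sentence} [v{i}]" for i in range(k)]

        out = augment_sentence(self.SENT, 3, augmenter=Fake(), seed=0)
        assert out == [self.SENT, f"{self.SENT} [v0]", f"{self.SENT} [v1]"]


class TestPromptSet:
    def test_four_scales_times_n_variants_in_fixed_order(self, scale_defs):
        ps = build_prompt_set(_record(scale_defs), scale_defs, n=5, seed=1)
        assert list(ps.sentences) == ["MDS-UPDRS", "STAI", "ESS", "CDT"]
        assert all(len(v) == 5 for v in ps.variants.values())

    def test_byte_identical_for_identical_inputs(self, scale_defs):
        a = build_prompt_set(_record(scale_defs), scale_defs, n=8, seed=4)
        b = build_prompt_set(_record(scale_defs), scale_defs, n=8, seed=4)
        assert json.dumps(a.to_dict(), sort_keys=True) == json.dumps(
            b.to_dict(), sort_keys=True
        )

    def test_missing_score_names_the_scale(self, scale_defs):
        rec = ClinicalRecord(
            "S2", {"STAI": 41.0, "ESS": 7.0, "CDT": 4.0}, diagnosis=0
        )
        with pytest.raises(ValidationError, match="MDS-UPDRS"):
            build_prompt_set(rec, scale_defs, n=2, seed=0)

    def test_round_trip_label_decoding(self, scale_defs):
        """Every variant decodes (by substring) to the originating severity."""
        rec = _record(scale_defs)
        ps = build_prompt_set(rec, scale_defs, n=8, seed=11)
        for sid, sdef in scale_defs.items():
            expected = categorize_score(rec.scores[sid], sdef)
            for variant in ps.variants[sid]:
                hits = [lab for lab in sdef.labels if lab in variant]
                assert hits == [expected]


class TestSampling:
    def test_n1_prompt_is_deterministic_template_concatenation(self, scale_defs):
        ps = build_prompt_set(_record(scale_defs), scale_defs, n=1, seed=0)
        rng = np.random.default_rng(0)
        prompt = sample_training_prompt(ps, rng)
        assert prompt == " ".join(ps.sentences[sid] for sid in ps.sentences)
        assert prompt == sample_training_prompt(ps, np.random.default_rng(99))

    def test_prompt_mentions_each_scale_once(self, scale_defs):
        ps = build_prompt_set(_record(scale_defs), scale_defs, n=4, seed=2)
        prompt = sample_training_prompt(ps, np.random.default_rng(1))
        for sid in ("MDS-UPDRS", "STAI", "ESS", "CDT"):
            assert prompt.count(f"({sid})") == 1

    def test_variants_sampled_uniformly(self, scale_defs):
        ps = build_prompt_set(_record(scale_defs), scale_defs, n=8, seed=5)
        rng = np.random.default_rng(0)
        counts = {v: 0 for v in ps.variants["ESS"]}
        draws = 10_000
        for _ in range(draws):
            prompt = sample_training_prompt(ps, rng)
            for v in counts:
                if v in prompt:
                    counts[v] += 1
                    break
        expected = draws / 8
        se = np.sqrt(draws * (1 / 8) * (7 / 8))
        for v, c in counts.items():
            assert abs(c - expected) < 3 * se
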