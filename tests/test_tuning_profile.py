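"""Preference/response indexes, tuning rule, and categorical labels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from s1pop.errors import ContractError, UndefinedPreferenceError
from s1pop.trace_processing import ResponseTensor
from s1pop.tuning_profile import (
    categorize_intensity_cells,
    discriminative_class,
    intensity_category,
    intensity_summary,
    per_group_percentages,
    preference_index,
    response_index,
    tuned_set,
    venn_categorize,
)


def make_tensor(peaks, max_per_cell=None, labels=None, threshold=0.30):
    peaks = np.asarray(peaks, dtype=float)
    n_cells, n_stim, n_trials = peaks.shape
    if max_per_cell is None:
        max_per_cell = peaks.max(axis=(1, 2))
    labels = tuple(labels or (f"s{j}" for j in range(n_stim)))
    return ResponseTensor(
        peaks=peaks,
        max_per_cell=np.asarray(max_per_cell, dtype=float),
        fidelity=(peaks > threshold).mean(axis=2),
        responder_flags=(peaks > threshold).any(axis=(1, 2)),
        stimulus_labels=labels,
        trial_indices=tuple(range(1, n_trials + 1)),
        response_threshold=threshold,
    )


class TestPreferenceIndex:
    def test_peaks_at_max_give_unity(self):
        t = make_tensor(np.full((1, 1, 5), 0.8), max_per_cell=[0.8])
        assert preference_index(t)[0, 0] == pytest.approx(1.0)

    def test_mean_over_trials_then_normalize(self):
        t = make_tensor([[[0.5, 1.0, 1.5]]], max_per_cell=[3.0])
        assert preference_index(t)[0, 0] == pytest.approx(1.0 / 3.0)

    def test_zero_peaks_give_zero(self):
        t = make_tensor(np.zeros((1, 2, 3)), max_per_cell=[1.0])
        assert np.all(preference_index(t) == 0.0)

    def test_zero_max_is_undefined(self):
        t = make_tensor(np.zeros((1, 1, 2)), max_per_cell=[0.0])
        with pytest.raises(UndefinedPreferenceError):
            preference_index(t)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(7)
        peaks = rng.uniform(0, 1, size=(4, 3, 5))
        base = make_tensor(peaks)
        scaled = make_tensor(peaks * scale, max_per_cell=base.max_per_cell * scale)
        np.testing.assert_allclose(
            preference_index(base), preference_index(scaled), rtol=1e-9
        )

    def test_response_index_shares_the_formula(self):
        # per-level trial means (0.1..0.4) over Max 0.5 -> (0.2,0.4,0.6,0.8)
        peaks = np.array([[[0.1] * 3, [0.2] * 3, [0.3] * 3, [0.4] * 3]])
        t = make_tensor(peaks, max_per_cell=[0.5],
                        labels=("P0", "P1", "P2", "P3"))
        np.testing.assert_allclose(
            response_index(t)[0], [0.2, 0.4, 0.6, 0.8]
        )


class TestTunedSet:
    def test_equal_pis_tune_to_everything(self):
        tuned = tuned_set(np.array([[0.5, 0.5, 0.5]]))
        assert tuned.all()  # 0.5 > 0.8 * 0.5

    def test_dominant_stimulus_only(self):
        tuned = tuned_set(np.array([[1.0, 0.1]]))  # cutoff 0.8*0.55 = 0.44
        assert tuned.tolist() == [[True, False]]

    def test_zero_pi_row_tunes_to_nothing(self):
        assert not tuned_set(np.array([[0.0, 0.0]])).any()


class TestVennCategorize:
    def test_subset_assignment_and_proportions(self):
        tuned = np.array(
            [
                [True, True, True],
                [True, True, True],
                [True, False, False],
                [False, True, True],
            ]
        )
        cats, props = venn_categorize(tuned, ("Brush", "Press", "Pinch"))
        assert cats.tolist() == [
            "Brush+Press+Pinch",
            "Brush+Press+Pinch",
            "Brush",
            "Press+Pinch",
        ]
        assert props["Brush+Press+Pinch"] == pytest.approx(0.5)
        assert props["Brush"] == pytest.approx(0.25)
        assert props["Press+Pinch"] == pytest.approx(0.25)
        assert sum(props.values()) == pytest.approx(1.0)

    def test_requires_exactly_three_stimuli(self):
        with pytest.raises(ContractError):
            venn_categorize(np.ones((2, 4), bool), ("a", "b", "c", "d"))


FEATURES_2x2 = pd.DataFrame(
    {
        "texture": ["brush", "brush", "forceps", "forceps"],
        "dynamics": ["stroke", "press", "stroke", "press"],
    },
    index=["B-stroke", "B-press", "F-stroke", "F-press"],
)
LABELS_2x2 = tuple(FEATURES_2x2.index)


class TestDiscriminativeClass:
    @pytest.mark.parametrize(
        "tuned_labels, expected",
        [
            ({"F-stroke", "F-press"}, "texture"),  # forceps-preferring
            ({"B-stroke", "B-press"}, "texture"),
            ({"B-press", "F-press"}, "dynamics"),  # press-preferring
            ({"B-stroke", "F-stroke"}, "dynamics"),
            ({"B-stroke", "B-press", "F-stroke"}, "other"),
            ({"B-stroke", "F-press"}, "other"),  # diagonal pair
            ({"B-stroke"}, "other"),
            (set(LABELS_2x2), "broad"),
            (set(), "none"),
        ],
    )
    def test_exact_set_rule(self, tuned_labels, expected):
        tuned = np.array([[lab in tuned_labels for lab in LABELS_2x2]])
        out = discriminative_class(tuned, LABELS_2x2, FEATURES_2x2)
        assert out[0] == expected

    def test_superset_mode_relaxes_pairs(self):
        tuned = np.array([[True, True, True, False]])  # brush pair + F-stroke
        exact = discriminative_class(tuned, LABELS_2x2, FEATURES_2x2)
        relaxed = discriminative_class(
            tuned, LABELS_2x2, FEATURES_2x2, mode="superset"
        )
        assert exact[0] == "other" and relaxed[0] == "texture"

    def test_non_crossed_design_rejected(self):
        bad = FEATURES_2x2.copy()
        bad["dynamics"] = ["stroke"] * 4
        with pytest.raises(ContractError):
            discriminative_class(np.ones((1, 4), bool), LABELS_2x2, bad)

    def test_per_mouse_percentages_average(self):
        labels = np.array(["texture"] * 3 + ["none"] + ["texture", "none"],
                          dtype=object)
        groups = np.array([1, 1, 1, 1, 2, 2])
        pct = per_group_percentages(labels, groups, classes=["texture", "none"])
        assert pct.loc[1, "texture"] == pytest.approx(75.0)
        assert pct.loc[2, "texture"] == pytest.approx(50.0)
        assert pct["texture"].mean() == pytest.approx(62.5)


class TestIntensityCategory:
    @pytest.mark.parametrize(
        "amps, expected",
        [
            ((0.1, 0.2, 0.3, 0.4), "intensity_coding"),
            ((0.4, 0.3, 0.2, 0.1), "inverse"),
            ((0.3, 0.3, 0.3, 0.3), "invariant"),
            ((0.1, 0.4, 0.2, 0.5), "irregular"),
        ],
    )
    def test_examples(self, amps, expected):
        assert intensity_category(np.array(amps), tolerance=0.01) == expected

    def test_reversal_maps_coding_to_inverse(self, rng):
        for _ in range(200):
            amps = rng.uniform(0, 1, size=4)
            cat = intensity_category(amps)
            rev = intensity_category(amps[::-1])
            pairs = {("intensity_coding", "inverse"),
                     ("inverse", "intensity_coding")}
            if cat in ("intensity_coding", "inverse"):
                assert (cat, rev) in pairs
            else:
                assert rev == cat

    def test_needs_three_levels(self):
        with pytest.raises(ContractError):
            intensity_category(np.array([0.1, 0.2]))


class TestIntensitySummary:
    def test_recruitment_counts(self):
        # no cell responds at P0; all 10 respond at P3
        peaks = np.zeros((10, 2, 5))
        peaks[:, 1, :] = 0.8
        t = make_tensor(peaks, labels=("P0", "P3"))
        summary = intensity_summary(t)
        assert summary.loc["P0", "recruited_cells"] == 0
        assert summary.loc["P3", "recruited_cells"] == 10

    def test_single_cell_fidelity_passthrough(self):
        peaks = np.stack(
            [np.tile([[0.0], [0.2], [0.8], [1.0]], (1, 5))]
        )  # fidelities 0, 0, 1, 1 at threshold 0.3 -> use varied trials
        peaks[0, 1, 0] = 0.4  # one of five trials above threshold -> 0.2
        peaks[0, 2, :4] = 0.4
        peaks[0, 2, 4] = 0.1  # 4/5 -> 0.8
        t = make_tensor(peaks, labels=("P0", "P1", "P2", "P3"))
        summary = intensity_summary(t)
        np.testing.assert_allclose(
            summary["mean_fidelity"].to_numpy(), [0.0, 0.2, 0.8, 1.0]
        )

    def test_population_mean_amplitude(self):
        peaks = np.array(
            [
                [[0.2] * 3, [0.4] * 3],
                [[0.4] * 3, [0.6] * 3],
            ]
        )
        t = make_tensor(peaks, labels=("P0", "P1"))
        np.testing.assert_allclose(
            intensity_summary(t)["mean_amplitude"].to_numpy(), [0.3, 0.5]
        )

    def test_categorize_cells_vectorizes_over_population(self):
        peaks = np.stack(
            [
                np.tile(np.array([[0.1], [0.2], [0.3], [0.4]]), (1, 5)),
                np.tile(np.array([[0.3], [0.3], [0.3], [0.3]]), (1, 5)),
            ]
        )
        t = make_tensor(peaks, labels=("P0", "P1", "P2", "P3"))
        cats = categorize_intensity_cells(t, tolerance=0.01)
        assert cats.tolist() == ["intensity_coding", "invariant"]
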