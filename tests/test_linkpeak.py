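"""Link-peak scoring: classification, profiles, reciprocal calls, orientation."""

import numpy as np
import pytest

from pmforge.linkpeak import (
    call_links,
    classify_mate_pairs,
    link_score_profile,
    profiles_to_wiggle,
    propagate_orientations,
    relative_orientation,
)
from pmforge.records import LibrarySpec, LinkCall, MatePairRecord


LIBS = {
    "w2": LibrarySpec("w2", "DM", "long_insert_454", 5000.0, 500.0, 2.0),
    "w1": LibrarySpec("w1", "RH", "clone_end", 5000.0, 500.0, 1.0),
}


def _pair(pid, s1, p1, st1, s2, p2, st2, lib="w2", ok=True):
    return MatePairRecord(pid, lib, s1, p1, st1, s2, p2, st2, mapq_ok=ok)


class TestClassification:
    def test_same_scaffold_pair_satisfied(self):
        sat, unsat = classify_mate_pairs([_pair("p", "S", 100, "+", "S", 5000, "-")])
        assert len(sat) == 1 and unsat == []

    def test_layout_adjacent_pair_satisfied_and_excluded(self):
        layout = {"chr1": [("A", "+"), ("B", "+"), ("C", "+"), ("D", "+")]}
        sat, unsat = classify_mate_pairs(
            [_pair("p", "A", 900, "+", "B", 100, "-")], layout=layout
        )
        assert len(sat) == 1 and unsat == []

    def test_distant_in_layout_is_unsatisfied(self):
        layout = {"chr1": [("A", "+"), ("B", "+"), ("C", "+"), ("D", "+")]}
        sat, unsat = classify_mate_pairs(
            [_pair("p", "A", 900, "+", "D", 100, "-")], layout=layout
        )
        assert sat == [] and len(unsat) == 1

    def test_without_layout_cross_scaffold_is_unsatisfied(self):
        sat, unsat = classify_mate_pairs([_pair("p", "A", 900, "+", "B", 100, "-")])
        assert sat == [] and len(unsat) == 1

    def test_unreliable_pairs_discarded(self):
        sat, unsat = classify_mate_pairs(
            [_pair("p", "A", 900, "+", "B", 100, "-", ok=False)]
        )
        assert sat == [] and unsat == []

    def test_sibling_segments_of_one_parent_satisfied(self):
        parent = {"S_p1": "S", "S_p2": "S"}
        sat, unsat = classify_mate_pairs(
            [_pair("p", "S_p1", 900, "+", "S_p2", 100, "-")], parent=parent
        )
        assert len(sat) == 1 and unsat == []


class TestProfile:
    def test_group_scores_peak_and_noise(self):
        pairs = [
            _pair("a", "S", 2000, "+", "T1", 10, "-", lib="w2"),
            _pair("b", "S", 2500, "+", "T1", 20, "-", lib="w2"),
            _pair("c", "S", 3000, "+", "T1", 30, "-", lib="w2"),
            _pair("d", "S", 2200, "+", "T2", 40, "-", lib="w1"),
        ]
        profile = link_score_profile("S", 10_000, pairs, LIBS)
        w0 = profile.windows[0]
        assert w0.peak_target == "T1"
        assert w0.peak_score == 6.0
        assert w0.noise_score == 1.0
        assert w0.direction == "right"

    def test_empty_window_scores_zero(self):
        profile = link_score_profile("S", 20_000, [], LIBS)
        assert all(w.peak_score == 0.0 and w.peak_target is None for w in profile.windows)

    def test_equal_scores_tie_flagged_lexicographic(self):
        pairs = [
            _pair("a", "S", 1000, "+", "TB", 10, "-", lib="w2"),
            _pair("b", "S", 1100, "+", "TB", 10, "-", lib="w2"),
            _pair("c", "S", 1000, "+", "TA", 10, "-", lib="w2"),
            _pair("d", "S", 1100, "+", "TA", 10, "-", lib="w2"),
        ]
        profile = link_score_profile("S", 10_000, pairs, LIBS)
        w0 = profile.windows[0]
        assert w0.tie
        assert w0.peak_target == "TA"
        assert w0.peak_score == 4.0

    def test_unknown_library_rejected(self):
        with pytest.raises(KeyError):
            link_score_profile(
                "S", 10_000, [_pair("a", "S", 100, "+", "T", 1, "-", lib="xx")], LIBS
            )

    def test_window_must_cover_step(self):
        with pytest.raises(ValueError):
            link_score_profile("S", 10_000, [], LIBS, window_bp=1000, step_bp=5000)

    def test_conservation_peak_plus_noise_equals_window_weight(self):
        """Per window, peak + noise equals the summed weight of unsatisfied
        pair ends falling in that window (each pair counted once per
        covering window)."""
        rng = np.random.default_rng(23)
        pairs = []
        for i in range(300):
            pairs.append(
                _pair(
                    f"p{i}",
                    "S",
                    int(rng.integers(0, 100_000)),
                    str(rng.choice(["+", "-"])),
                    f"T{rng.integers(0, 6)}",
                    int(rng.integers(0, 50_000)),
                    str(rng.choice(["+", "-"])),
                    lib=str(rng.choice(["w1", "w2"])),
                )
            )
        profile = link_score_profile("S", 100_000, pairs, LIBS)
        for w in profile.windows:
            expected = sum(
                LIBS[p.lib_id].value_weight
                for p in pairs
                if w.start <= p.pos1 < w.start + profile.window_bp
            )
            assert w.peak_score + w.noise_score == pytest.approx(expected)

    def test_satisfied_pairs_never_contribute(self):
        all_pairs = [
            _pair("same", "S", 100, "+", "S", 4000, "-"),
            _pair("cross", "S", 6000, "-", "T", 100, "+"),
        ]
        _sat, unsat = classify_mate_pairs(all_pairs)
        profile = link_score_profile("S", 10_000, unsat, LIBS)
        total = sum(w.peak_score + w.noise_score for w in profile.windows)
        # only the cross pair's single S end, in 2 covering windows, weight 2
        assert total == pytest.approx(4.0)

    def test_doubling_weights_doubles_scores_and_preserves_calls(self):
        pairs = [
            _pair(f"p{i}", "S", 29_000 + i * 100, "+", "T", 500 + i * 10, "-")
            for i in range(3)
        ]
        libs2 = {
            k: LibrarySpec(k, v.origin, v.kind, v.insert_mean, v.insert_sd,
                           2 * v.value_weight)
            for k, v in LIBS.items()
        }
        prof1 = [
            link_score_profile("S", 30_000, pairs, LIBS),
            link_score_profile("T", 30_000, pairs, LIBS),
        ]
        prof2 = [
            link_score_profile("S", 30_000, pairs, libs2),
            link_score_profile("T", 30_000, pairs, libs2),
        ]
        for p1, p2 in zip(prof1, prof2):
            for w1, w2 in zip(p1.windows, p2.windows):
                assert w2.peak_score == pytest.approx(2 * w1.peak_score)
                assert w2.noise_score == pytest.approx(2 * w1.noise_score)
        links1, _ = call_links(prof1, LIBS, min_score=4.0)
        links2, _ = call_links(prof2, libs2, min_score=8.0)
        assert [(l.scaffold_a, l.end_a, l.scaffold_b, l.end_b) for l in links1] == [
            (l.scaffold_a, l.end_a, l.scaffold_b, l.end_b) for l in links2
        ]


def _junction_pairs(n, s, s_pos, s_strand, t, t_pos, t_strand, lib="w2", tag=""):
    return [
        _pair(f"{tag}{i}", s, s_pos + i * 37, s_strand, t, t_pos + i * 23, t_strand, lib=lib)
        for i in range(n)
    ]


class TestCallLinks:
    def test_reciprocal_link_called_with_orientation(self):
        pairs = _junction_pairs(3, "S", 28_000, "+", "T", 500, "-")
        profiles = [
            link_score_profile("S", 30_000, pairs, LIBS),
            link_score_profile("T", 30_000, pairs, LIBS),
        ]
        links, suggestions = call_links(profiles, LIBS)
        (link,) = links
        assert (link.scaffold_a, link.end_a, link.scaffold_b, link.end_b) == (
            "S", "R", "T", "L",
        )
        assert link.reciprocal
        assert link.implied_relative_orientation == "same"
        assert suggestions == []

    def test_same_end_pairing_implies_opposite_strand(self):
        # T's evidence also sits near its *right* end pointing right
        pairs = _junction_pairs(3, "S", 28_000, "+", "T", 29_000, "+")
        profiles = [
            link_score_profile("S", 30_000, pairs, LIBS),
            link_score_profile("T", 30_000, pairs, LIBS),
        ]
        (link,), _ = call_links(profiles, LIBS)
        assert {link.end_a, link.end_b} == {"R"}
        assert link.implied_relative_orientation == "opposite"

    def test_non_reciprocal_peak_reported_as_suggestion(self):
        pairs = _junction_pairs(3, "S", 28_000, "+", "T", 500, "-")
        # T's left end is dominated by stronger evidence toward V
        pairs += _junction_pairs(5, "T", 900, "-", "V", 600, "-")
        profiles = [
            link_score_profile(sid, 30_000, pairs, LIBS) for sid in ("S", "T", "V")
        ]
        links, suggestions = call_links(profiles, LIBS)
        assert ("S", "T") not in {(l.scaffold_a, l.scaffold_b) for l in links}
        assert ("S", "R", "T") in {
            (s.scaffold_a, s.end_a, s.scaffold_b) for s in suggestions
        }

    def test_noisy_end_rejected_as_repeat_like(self):
        pairs = _junction_pairs(3, "S", 28_000, "+", "T", 500, "-", lib="w2")
        pairs += _junction_pairs(5, "S", 28_100, "+", "U", 500, "-", lib="w1")
        profiles = [
            link_score_profile(sid, 30_000, pairs, LIBS) for sid in ("S", "T", "U")
        ]
        links, _ = call_links(profiles, LIBS)
        # peak 6 toward T but co-window noise 5 toward U: ratio 0.83 > 0.5
        assert all(l.scaffold_a != "S" or l.end_a != "R" for l in links)

    def test_score_below_threshold_not_called(self):
        pairs = _junction_pairs(1, "S", 28_000, "+", "T", 500, "-", lib="w1")
        profiles = [
            link_score_profile(sid, 30_000, pairs, LIBS) for sid in ("S", "T")
        ]
        links, suggestions = call_links(profiles, LIBS, min_score=4.0)
        assert links == [] and suggestions == []


class TestOrientation:
    def test_end_pairing_convention(self):
        assert relative_orientation("R", "L") == "same"
        assert relative_orientation("L", "R") == "same"
        assert relative_orientation("R", "R") == "opposite"
        assert relative_orientation("L", "L") == "opposite"

    def _link(self, a, ea, b, eb):
        return LinkCall(a, ea, b, eb, 6.0, 6.0, True, relative_orientation(ea, eb))

    def test_chain_propagation(self):
        links = [self._link("A", "R", "B", "L"), self._link("B", "R", "C", "R")]
        signs, components, n_conflicts, conflicted = propagate_orientations(links)
        assert n_conflicts == 0 and not conflicted
        assert signs["A"] == signs["B"] == -signs["C"]

    def test_conflicting_triangle_flags_component(self):
        links = [
            self._link("A", "R", "B", "L"),  # same
            self._link("B", "R", "C", "L"),  # same
            self._link("A", "L", "C", "L"),  # opposite: parity conflict
        ]
        signs, _components, n_conflicts, conflicted = propagate_orientations(links)
        assert n_conflicts >= 1
        assert conflicted == {"A", "B", "C"}
        assert signs == {}


class TestWiggleExport:
    def test_signed_peaks_and_noise_tracks(self):
        pairs = [
            _pair("r", "S", 1000, "+", "T", 10, "-"),  # rightward, weight 2
            _pair("l", "S", 27_000, "-", "U", 10, "+", lib="w1"),  # leftward
        ]
        profile = link_score_profile("S", 30_000, pairs, LIBS)
        peak_track, noise_track = profiles_to_wiggle([profile])
        assert peak_track.values[0] == 2.0  # right-directed positive
        assert min(peak_track.values) == -1.0  # left-directed negative
        assert all(v >= 0 for v in noise_track.values)

    def test_all_zero_profile_gives_zero_track(self):
        profile = link_score_profile("S", 20_000, [], LIBS)
        peak_track, noise_track = profiles_to_wiggle([profile])
        assert set(peak_track.values) == {0.0}
        assert set(noise_track.values) == {0.0}
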