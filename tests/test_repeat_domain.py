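import warnings

import numpy as np
import pytest

from hairpinreg.repeat_domain import (
    K18_SEQUENCE,
    RepeatSpec,
    interhexapeptide_pairing,
    k18_default_spec,
    local_hairpin_probabilities,
    local_hairpin_probability,
    sasa_differential,
    segment_region_map,
    total_beta_for_segment,
)
from hairpinreg.structure_io import Ensemble, TAU295_SEQUENCE
from hairpinreg.synthetic_ensembles import (
    build_extended,
    build_ideal_hairpin,
    build_k18_frame,
)


@pytest.fixture(scope="module")
def spec():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return k18_default_spec()


def k18_ensemble(frames):
    return Ensemble(
        [c.with_coords(c.coords, frame_id=i) for i, c in enumerate(frames)],
        K18_SEQUENCE,
        numbering_offset=243,
    )


@pytest.fixture(scope="module")
def extended_k18(spec):
    return build_k18_frame(spec, set())


@pytest.fixture(scope="module")
def h2_frame(spec):
    return build_k18_frame(spec, {"H2"})


@pytest.fixture(scope="module")
def pair23_frame(spec):
    return build_k18_frame(spec, {(2, 3)})


class TestRepeatSpec:
    def test_default_layout_matches_published_ranges(self, spec):
        assert spec.hexapeptides[0] == (275, 280)
        assert spec.hexapeptides[1] == (306, 311)
        assert spec.hexapeptides[2] == (337, 342)
        assert spec.flanks[1] == (295, 299)
        assert spec.flanks[2] == (325, 329)
        assert spec.flanks[3] == (357, 361)

    def test_hexapeptide4_clipped_to_terminus_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            s = k18_default_spec()
        assert s.hexapeptides[3] == (369, 372)

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            RepeatSpec(
                hexapeptides=[(275, 280), (278, 283)],
                flanks=[(264, 268), (295, 299)],
                pggg_motifs=[(270, 273), (301, 304)],
            )

    def test_segment_map_mirrors_tau_conventions(self, spec):
        rm = segment_region_map(spec, 2)
        assert rm.even_set == {306, 308, 310}
        assert rm.odd_set == {305, 307, 309}
        assert rm.scored_hex == set(range(306, 311))
        assert max(rm.n_arm) == 304 and min(rm.n_arm) == 281


class TestLocalHairpins:
    def test_h2_frame_scores_only_h2(self, spec, h2_frame):
        ens = k18_ensemble([h2_frame])
        probs = local_hairpin_probabilities(ens, spec)
        assert probs == {"H1": 0.0, "H2": 1.0, "H3": 0.0, "H4": 0.0}

    def test_extended_chain_scores_nothing(self, spec, extended_k18):
        ens = k18_ensemble([extended_k18])
        assert set(local_hairpin_probabilities(ens, spec).values()) == {0.0}

    def test_mixture_recovers_event_rate(self, spec, h2_frame, extended_k18):
        ens = k18_ensemble([h2_frame] * 3 + [extended_k18] * 3)
        assert local_hairpin_probability(ens, spec, k=2) == pytest.approx(0.5)
        assert local_hairpin_probability(ens, spec, k=1) == 0.0

    def test_every_local_event_detected(self, spec):
        for k in (1, 3, 4):
            frame = build_k18_frame(spec, {f"H{k}"})
            probs = local_hairpin_probabilities(k18_ensemble([frame]), spec)
            assert probs[f"H{k}"] == 1.0
            assert sum(probs.values()) == 1.0

    def test_invalid_segment_rejected(self, spec, extended_k18):
        with pytest.raises(ValueError, match="out of range"):
            local_hairpin_probability(k18_ensemble([extended_k18]), spec, k=5)


class TestPairing:
    def test_constructed_23_pairing_detected(self, spec, pair23_frame, extended_k18):
        ens = k18_ensemble([pair23_frame] + [extended_k18] * 4)
        mat = interhexapeptide_pairing(ens, spec)
        assert mat.pairwise[1, 2] == pytest.approx(0.2)
        assert mat.pairwise.sum() == pytest.approx(0.4)  # symmetric entry only

    def test_extended_ensemble_zero_matrix(self, spec, extended_k18):
        mat = interhexapeptide_pairing(k18_ensemble([extended_k18]), spec)
        assert np.all(mat.pairwise == 0.0)

    def test_matrix_symmetric(self, spec, h2_frame, pair23_frame):
        mat = interhexapeptide_pairing(
            k18_ensemble([h2_frame, pair23_frame]), spec
        )
        assert np.array_equal(mat.pairwise, mat.pairwise.T)

    def test_min_bonds_monotonicity(self, spec, pair23_frame, extended_k18):
        ens = k18_ensemble([pair23_frame, extended_k18])
        loose = interhexapeptide_pairing(ens, spec, min_bonds=1, include_local=False)
        strict = interhexapeptide_pairing(ens, spec, min_bonds=2, include_local=False)
        assert np.all(loose.pairwise + 1e-12 >= strict.pairwise)


class TestTotalBeta:
    @pytest.mark.parametrize(
        "local_k,row,expected",
        [(0.06, [0.15], 0.21), (0.17, [0.02], 0.19), (0.0, [0, 0, 0], 0.0)],
    )
    def test_segment_totals(self, local_k, row, expected):
        assert total_beta_for_segment(local_k, row) == pytest.approx(expected)

    def test_total_above_one_warns(self):
        with pytest.warns(UserWarning, match="exceeds 1"):
            total = total_beta_for_segment(0.8, [0.5])
        assert total == pytest.approx(1.3)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            total_beta_for_segment(1.2, [0.1])


class TestSASADifferential:
    def test_identical_ensembles_zero(self, tau_regions):
        conf = build_ideal_hairpin(TAU295_SEQUENCE, tau_regions)
        ens = Ensemble([conf], TAU295_SEQUENCE, numbering_offset=294)
        diff = sasa_differential(ens, ens)
        assert np.allclose(diff, 0.0)

    def test_extended_more_exposed_than_compact(self, tau_regions):
        ext = Ensemble(
            [build_extended(TAU295_SEQUENCE)], TAU295_SEQUENCE, numbering_offset=294
        )
        compact = Ensemble(
            [build_ideal_hairpin(TAU295_SEQUENCE, tau_regions)],
            TAU295_SEQUENCE,
            numbering_offset=294,
        )
        diff = sasa_differential(ext, compact)
        # ladder-rung residues face the partner strand and are buried
        rungs = [r - 294 for r in (298, 300, 302, 306, 308, 310)]
        assert all(diff[i - 1] > 0 for i in rungs)

    def test_antisymmetry(self, tau_regions):
        a = Ensemble(
            [build_extended(TAU295_SEQUENCE)], TAU295_SEQUENCE, numbering_offset=294
        )
        b = Ensemble(
            [build_ideal_hairpin(TAU295_SEQUENCE, tau_regions)],
            TAU295_SEQUENCE,
            numbering_offset=294,
        )
        assert np.allclose(sasa_differential(a, b), -sasa_differential(b, a))

    def test_length_mismatch_rejected(self, tau_regions):
        a = Ensemble(
            [build_extended(TAU295_SEQUENCE)], TAU295_SEQUENCE, numbering_offset=294
        )
        b = Ensemble(
            [build_extended(TAU295_SEQUENCE[:10])],
            TAU295_SEQUENCE[:10],
            numbering_offset=294,
        )
        with pytest.raises(ValueError, match="equal sequence lengths"):
            sasa_differential(a, b)
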