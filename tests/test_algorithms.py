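"""The three effort-to-ignorance transforms and their defining properties."""

import numpy as np
import pytest

from ignomap import (
    ConfigurationError,
    DegenerateEffortError,
    certainty,
    ignorance_half,
    ignorance_log_normalization,
    ignorance_normalization,
)


class TestWorkedValues:
    def test_half_ignorance_single_observation(self, make_effort):
        """With O50=1 one observation halves ignorance; with O50=0.5 it drops to 1/3."""
        eff = make_effort([[1.0]])
        assert ignorance_half(eff, 1.0).I[0, 0] == pytest.approx(0.5)
        assert ignorance_half(eff, 0.5).I[0, 0] == pytest.approx(1 / 3)

    def test_half_ignorance_at_o50_is_half(self, make_effort):
        for o50 in (0.5, 1.0, 5.0, 10.0):
            eff = make_effort([[o50]])
            assert ignorance_half(eff, o50).I[0, 0] == pytest.approx(0.5)

    def test_normalization_is_linear_in_effort(self, make_effort):
        eff = make_effort([[8.0, 2.0]])
        I = ignorance_normalization(eff).I
        assert I[0, 0] == 0.0
        assert I[0, 1] == pytest.approx(0.75)

    def test_log_normalization_uses_natural_log(self, make_effort):
        # ln(10)/ln(100) = 1/2 pins the base: wrong base changes nothing here,
        # but the +1 shift plus this ratio does distinguish ln(x+1) from ln(x).
        eff = make_effort([[99.0, 9.0]])
        I = ignorance_log_normalization(eff).I
        assert I[0, 0] == 0.0
        assert I[0, 1] == pytest.approx(0.5)


class TestEndpoints:
    def test_zero_effort_means_total_ignorance(self, make_effort):
        eff = make_effort([[0.0, 3.0]])
        for ign in (
            ignorance_normalization(eff),
            ignorance_log_normalization(eff),
            ignorance_half(eff, 1.0),
        ):
            assert ign.I[0, 0] == 1.0

    def test_dataset_maximum_means_zero_ignorance(self, make_effort):
        eff = make_effort([[0.0, 7.0, 3.0]])
        assert ignorance_normalization(eff).I[0, 1] == 0.0
        assert ignorance_log_normalization(eff).I[0, 1] == 0.0

    def test_half_ignorance_never_reaches_zero(self, make_effort):
        eff = make_effort([[1e9]])
        assert 0 < ignorance_half(eff, 1.0).I[0, 0] < 1e-8


class TestDegenerateInputs:
    @pytest.mark.parametrize("algo", [ignorance_normalization, ignorance_log_normalization])
    def test_all_zero_layer_is_undefined_for_normalizers(self, make_effort, algo):
        with pytest.raises(DegenerateEffortError, match="degenerate effort layer"):
            algo(make_effort([[0.0, 0.0]]))

    def test_all_zero_layer_is_all_ones_for_half(self, make_effort):
        I = ignorance_half(make_effort([[0.0, 0.0]]), 2.0).I
        assert np.all(I == 1.0)

    @pytest.mark.parametrize("o50", [0.0, -1.0])
    def test_nonpositive_o50_rejected(self, make_effort, o50):
        with pytest.raises(ConfigurationError):
            ignorance_half(make_effort([[1.0]]), o50)

    def test_nodata_propagates(self, make_effort):
        valid = np.array([[True, False], [True, True]])
        eff = make_effort([[2.0, 0.0], [0.0, 1.0]], valid=valid)
        for ign in (
            ignorance_normalization(eff),
            ignorance_log_normalization(eff),
            ignorance_half(eff, 1.0),
        ):
            assert np.array_equal(ign.valid, valid)
            assert np.isnan(ign.I[0, 1])


class TestProperties:
    """Shape properties checked over randomized layers (fixed seed)."""

    @pytest.fixture
    def random_layers(self, make_effort):
        rng = np.random.default_rng(2024)
        layers = []
        for _ in range(25):
            shape = rng.integers(2, 8, size=2)
            x = rng.gamma(0.5, 20.0, size=shape).round()  # long-right-tail counts
            x.flat[rng.integers(0, x.size)] = x.max() + 1  # ensure a positive max
            layers.append(make_effort(x))
        return layers

    def test_monotone_nonincreasing_in_effort(self, random_layers):
        for eff in random_layers:
            order = np.argsort(eff.x.ravel())
            for ign in (
                ignorance_normalization(eff),
                ignorance_log_normalization(eff),
                ignorance_half(eff, 3.0),
            ):
                sorted_I = ign.I.ravel()[order]
                assert np.all(np.diff(sorted_I) <= 1e-12)
                assert np.all((ign.I >= 0) & (ign.I <= 1))

    def test_log_normalization_dominated_by_normalization(self, random_layers):
        """Concavity of log: I_lognorm <= I_norm, equal only at 0 and the max."""
        for eff in random_layers:
            In = ignorance_normalization(eff).I
            Il = ignorance_log_normalization(eff).I
            assert np.all(Il <= In + 1e-12)
            x_m = np.nanmax(eff.x)
            interior = (eff.x > 0) & (eff.x < x_m)
            assert np.all(Il[interior] < In[interior])
            endpoints = (eff.x == 0) | (eff.x == x_m)
            assert np.allclose(Il[endpoints], In[endpoints])

    def test_half_ignorance_is_max_independent(self, make_effort):
        """Appending a hugely sampled cell leaves half-ignorance scores alone
        but shifts every normalization score (its zero point moves)."""
        base = np.array([[0.0, 1.0, 4.0, 10.0]])
        extended = np.array([[0.0, 1.0, 4.0, 10.0, 10_000.0]])
        half_base = ignorance_half(make_effort(base), 1.0).I
        half_ext = ignorance_half(make_effort(extended), 1.0).I
        assert np.array_equal(half_base[0], half_ext[0, :4])

        norm_base = ignorance_normalization(make_effort(base)).I
        norm_ext = ignorance_normalization(make_effort(extended)).I
        changed = norm_base[0] != norm_ext[0, :4]
        assert np.all(changed[base[0] > 0])

    def test_half_ignorance_monotone_in_o50(self, make_effort):
        eff = make_effort(np.linspace(0.5, 50, 20).reshape(4, 5))
        I_small = ignorance_half(eff, 1.0).I
        I_big = ignorance_half(eff, 10.0).I
        assert np.all(I_big > I_small)


def test_certainty_is_the_complement_and_involutive(make_effort):
    eff = make_effort([[0.0, 1.0, 3.0, 4.0]])
    ign = ignorance_half(eff, 2.0)
    cert = certainty(ign)
    assert np.allclose(cert.values, 1.0 - ign.I)
    # applying the complement twice returns the original scores
    from ignomap.grids import IgnoranceLayer

    twice = certainty(IgnoranceLayer(cert.gridspec, cert.values, cert.valid))
    assert np.allclose(twice.values, ign.I)


def test_provenance_records_algorithm_parameters(make_effort):
    eff = make_effort([[1.0, 5.0]], source="counts")
    ign_n = ignorance_normalization(eff)
    assert ign_n.provenance["algorithm"] == "normalization"
    assert ign_n.provenance["effort_max"] == 5.0
    assert ign_n.provenance["source"] == "counts"
    ign_h = ignorance_half(eff, 2.5)
    assert ign_h.provenance["o50"] == 2.5
    assert "effort_max" not in ign_h.provenance
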