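import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirclock import compare_regulation, integrate, measure, period_drift, phase
from mirclock.model import species_index
from mirclock.simulate import SimulationSettings, Trajectory


def synthetic_trajectory(params, signals: dict, t_end=500.0, step=0.05,
                         transient=200.0):
    """Trajectory whose named species follow prescribed waveforms."""
    t = np.arange(0.0, t_end + step / 2, step)
    y = np.zeros((t.size, 19))
    for sp, fn in signals.items():
        y[:, species_index(sp)] = fn(t)
    s = SimulationSettings(t_end=t_end, output_step=step, transient=transient)
    return Trajectory(t, y, params, y[0].copy(), s)


def test_sinusoid_metrics(set3):
    traj = synthetic_trajectory(
        set3, {"M_B": lambda t: 0.5 + 0.3 * np.sin(2 * np.pi * t / 24.0)})
    m = measure(traj, "M_B")
    assert m.regime == "sustained"
    assert m.period == pytest.approx(24.0, abs=0.01)
    assert m.amplitude == pytest.approx(0.6, rel=1e-3)
    assert m.mean_level == pytest.approx(0.5, abs=1e-3)


def test_damped_exponential_classified(set3):
    traj = synthetic_trajectory(
        set3, {"M_B": lambda t: 1.0 + np.exp(-t / 100.0) * np.sin(2 * np.pi * t / 24.0)},
        transient=0.0)
    m = measure(traj, "M_B")
    assert m.regime == "damped"
    assert m.decay_ratio < 1.0


def test_steady_signal_has_zero_amplitude(set3):
    traj = synthetic_trajectory(set3, {"M_B": lambda t: np.full_like(t, 0.7)})
    m = measure(traj, "M_B")
    assert m.regime == "steady" and m.amplitude == 0.0


@settings(max_examples=25, derandomize=True, deadline=None)
@given(period=st.floats(10.0, 40.0), step=st.sampled_from([0.02, 0.05, 0.1]),
       phi=st.floats(0.0, 2 * np.pi))
def test_period_recovery_property(period, step, phi):
    """Constructed sinusoids are recovered to < 0.1% over 10-40 h periods."""
    from mirclock import load_parameters

    traj = synthetic_trajectory(
        load_parameters("Set3"),
        {"M_B": lambda t: 1.0 + 0.4 * np.sin(2 * np.pi * t / period + phi)},
        step=step)
    m = measure(traj, "M_B")
    assert m.period == pytest.approx(period, rel=1e-3)
    assert m.amplitude == pytest.approx(0.8, rel=1e-3)


def test_frequency_period_reciprocity(basal_traj):
    for sp in ("M_B", "M_my", "M_P"):
        m = measure(basal_traj, sp)
        assert m.regime == "sustained"
        assert m.frequency * m.period == pytest.approx(1.0, abs=1e-9)
        assert m.amplitude >= 0.0


def test_regime_invariant_under_uniform_scaling(set3):
    for scale in (1e-3, 1.0, 100.0):
        traj = synthetic_trajectory(
            set3, {"M_B": lambda t: scale * (1.0 + 0.5 * np.sin(2 * np.pi * t / 24.0))})
        assert measure(traj, "M_B").regime == "sustained"


def test_too_short_trajectory_rejected(set3):
    traj = synthetic_trajectory(set3, {"M_B": np.sin}, t_end=250.0)
    with pytest.raises(ValueError, match="too short"):
        measure(traj, "M_B")


def test_phase_self_is_zero(basal_traj):
    pr = phase(basal_traj, "M_B", "M_B")
    assert pr.lag == pytest.approx(0.0, abs=0.05)
    assert pr.classification == "in-phase"


def test_phase_of_constructed_offsets(set3):
    base = lambda t: 1.0 + 0.4 * np.sin(2 * np.pi * t / 24.0)
    quarter = lambda t: 1.0 + 0.4 * np.sin(2 * np.pi * (t - 6.0) / 24.0)
    opposite = lambda t: 1.0 - 0.4 * np.sin(2 * np.pi * t / 24.0)
    traj = synthetic_trajectory(set3, {"M_B": base, "M_my": opposite,
                                       "M_P": quarter})
    anti = phase(traj, "M_B", "M_my")
    assert anti.classification == "antiphase"
    assert abs(anti.lag) == pytest.approx(12.0, abs=0.1)
    lagged = phase(traj, "M_B", "M_P")
    assert lagged.lag == pytest.approx(6.0, abs=0.1)
    assert lagged.classification == "other"


def test_phase_requires_oscillation(set3):
    traj = synthetic_trajectory(set3, {"M_B": lambda t: np.full_like(t, 1.0),
                                       "M_my": lambda t: 1 + np.sin(t / 4)})
    with pytest.raises(ValueError):
        phase(traj, "M_B", "M_my")


def test_compare_regulation_identity_when_uncoupled(set1):
    """With C3 already 0 both arms are the same system: ratios exactly 1."""
    df = compare_regulation(set1, species=["M_B", "M_my"])
    assert np.allclose(df["ratio_without_over_with"], 1.0, atol=0.0)
    assert np.allclose(df["percent_change"], 0.0, atol=0.0)


def test_compare_regulation_amplitude_conventions(set3):
    df = compare_regulation(set3, species=["M_my"])
    df_peak = compare_regulation(set3, species=["M_my"],
                                 amplitude_convention="peak")
    # the peak level bounds the excursion from above for a non-negative signal
    assert df_peak.at[0, "amplitude_with"] >= df.at[0, "amplitude_with"]
    with pytest.raises(ValueError):
        compare_regulation(set3, species=["M_my"], amplitude_convention="rms")


def test_period_drift_constant_on_limit_cycle(set3):
    table = period_drift(set3, [350.0, 450.0])
    assert table.shape[0] == 2
    assert abs(table.period.iloc[0] - table.period.iloc[1]) < 0.1


def test_period_drift_rejects_flat_and_out_of_span(set3):
    dead = set3.replace(d1=0, d3=0, d5=0, V_sB=0, V_sC=0, V_sM=0, V_s=0,
                        k_s=0, k_sB=0, k_sC=0, C1=0)
    with pytest.raises(ValueError):
        period_drift(dead, [100.0])
    with pytest.raises(ValueError):
        period_drift(set3, [250.0, 10_000.0], t_end=500.0)
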