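"""Golden-rule rates, the two-step breakdown and the one-step snapshot protocol."""

import numpy as np
import pytest

from conftest import (
    DONOR_STRENGTH_DEBYE,
    DONOR_TILT_DEG,
    ETA,
    REFERENCE_TABLE,
    REFERENCE_TOTAL_K,
)
from memfret.constants import (
    COULOMB_METER_PER_AU,
    COULOMB_METER_PER_DEBYE,
    dipole_strength_au2_to_SI,
)
from memfret.coupling import CouplingGeometry, MembraneFrameTDM, rotational_average_V2
from memfret.rates import (
    AcceptorState,
    SnapshotRecord,
    fret_rate,
    merge_degenerate_states,
    one_step_total,
    read_snapshots,
    two_step_total,
    write_snapshots,
)
from memfret.spectra import overlap_gaussian_pair
from memfret.tdm import TransitionDipole


def _debye_to_au2(mu_debye: float) -> float:
    return (mu_debye * COULOMB_METER_PER_DEBYE / COULOMB_METER_PER_AU) ** 2


def test_fret_rate_reproduces_published_rows():
    """Plugging the printed |V|² and J columns into the golden-rule expression
    reproduces every printed k_FRET within 2%."""
    for state, row in REFERENCE_TABLE.items():
        assert fret_rate(row["V2"], row["J"]) == pytest.approx(row["k"], rel=0.02), state


def test_fret_rate_edges():
    assert fret_rate(1e-46, 0.0) == 0.0
    with pytest.raises(ValueError):
        fret_rate(-1.0, 1e-4)


def test_printed_rows_sum_to_overall_rate_and_lifetimes():
    k_sum = sum(row["k"] for row in REFERENCE_TABLE.values())
    assert k_sum == pytest.approx(REFERENCE_TOTAL_K, rel=1e-3)
    assert 1.0 / REFERENCE_TABLE["S5"]["k"] == pytest.approx(15.9e-9, rel=0.02)
    assert 1.0 / k_sum == pytest.approx(1.39e-9, rel=0.02)


def test_two_step_total_reproduces_published_breakdown(table_geometry, table_states):
    result = two_step_total(DONOR_STRENGTH_DEBYE, DONOR_TILT_DEG, table_states, table_geometry)
    assert result.k_total == pytest.approx(REFERENCE_TOTAL_K, rel=0.10)
    assert result.tau_total == pytest.approx(1.39e-9, rel=0.10)
    for state, row in REFERENCE_TABLE.items():
        assert result.table.loc[state, "k_fret_s"] == pytest.approx(row["k"], rel=0.10)
        assert result.table.loc[state, "V_cm"] == pytest.approx(row["V_cm"], rel=0.05)
    # totals are exact sums of the per-state rates
    assert result.k_total == pytest.approx(result.table["k_fret_s"].sum(), rel=1e-14)
    assert result.k_total * result.tau_total == pytest.approx(1.0, rel=1e-14)


def test_two_step_additivity_duplicated_state(table_geometry):
    s = AcceptorState("S6", 2.5, 29.6, 1.44e-4)
    single = two_step_total(12.3, 11.7, [s], table_geometry)
    double = two_step_total(12.3, 11.7, [s, s], table_geometry)
    assert double.k_total == pytest.approx(2 * single.k_total, rel=1e-12)


def test_two_step_zero_overlaps_zero_rate(table_geometry):
    states = [AcceptorState("S6", 2.5, 29.6, 0.0)]
    assert two_step_total(12.3, 11.7, states, table_geometry).k_total == 0.0


def test_two_step_missing_overlap_names_state(table_geometry):
    states = [AcceptorState("S6", 2.5, 29.6, None)]
    with pytest.raises(ValueError, match="S6"):
        two_step_total(12.3, 11.7, states, table_geometry)


def test_merge_degenerate_states_shares_strength_and_overlap():
    states = [
        AcceptorState("S7", 3.0, 49.6, 7.0e-5),
        AcceptorState("S8", 3.4, 29.6, 9.0e-5),
    ]
    merged = merge_degenerate_states(states, [("S7", "S8")])
    assert merged[0].strength_debye == merged[1].strength_debye == pytest.approx(3.2)
    assert merged[0].overlap_cm == merged[1].overlap_cm == pytest.approx(8.0e-5)
    # orientations stay distinct
    assert (merged[0].tilt_deg, merged[1].tilt_deg) == (49.6, 29.6)


def _donor_snapshot(frame, depth, tilt_deg, strength_au2, energy_ev, azimuth_deg=0.0):
    t = np.radians(tilt_deg)
    az = np.radians(azimuth_deg)
    direction = np.array([np.cos(t) * np.cos(az), np.cos(t) * np.sin(az), np.sin(t)])
    tdm = TransitionDipole("S1->S0", direction * np.sqrt(strength_au2),
                           vertical_energy_ev=energy_ev)
    return SnapshotRecord("donor", frame, depth, {"S1->S0": tdm}, role="donor")


def _acceptor_snapshot(frame, depth, states):
    transitions = {
        label: TransitionDipole(
            label,
            np.array([np.cos(np.radians(t)), 0.0, np.sin(np.radians(t))]) * np.sqrt(s),
            vertical_energy_ev=e,
        )
        for label, (s, t, e) in states.items()
    }
    return SnapshotRecord("acceptor", frame, depth, transitions)


def test_one_step_single_pair_equals_hand_composed_chain():
    """With one donor and one acceptor snapshot the one-step result must equal
    the explicit coupling → overlap → rate composition (and hence the two-step
    protocol fed the same inputs) — the oracle equivalence of the protocols."""
    mu_d_au2 = _debye_to_au2(12.3)
    mu_a_au2 = _debye_to_au2(3.2)
    e_d, e_a = 2.2, 2.35
    donor = _donor_snapshot(0, 13.3, 11.7, mu_d_au2, e_d)
    acceptor = _acceptor_snapshot(0, 20.1, {"S8": (mu_a_au2, 29.6, e_a)})

    res = one_step_total([donor], [acceptor], eta=ETA)

    geom = CouplingGeometry(33.4, ETA)
    v2 = rotational_average_V2(
        MembraneFrameTDM.from_debye(12.3, 11.7),
        MembraneFrameTDM.from_debye(3.2, 29.6),
        geom,
    )
    j = overlap_gaussian_pair(e_d, 0.05, e_a, 0.2)
    expected = fret_rate(v2, j)
    assert res.k_mean == pytest.approx(expected, rel=1e-6)

    two_step = two_step_total(12.3, 11.7, [AcceptorState("S8", 3.2, 29.6, j)], geom)
    assert res.k_mean == pytest.approx(two_step.k_total, rel=1e-6)


def test_one_step_identical_snapshots_mean_equals_single_pair():
    donor = _donor_snapshot(0, 13.3, 11.7, 23.8, 2.2)
    acceptor = _acceptor_snapshot(0, 20.1, {"S1": (3.0, 29.6, 2.3)})
    single = one_step_total([donor], [acceptor])
    many = one_step_total([donor] * 5, [acceptor] * 4)
    assert many.n_pairs == 20
    assert many.k_mean == pytest.approx(single.k_mean, rel=1e-12)


def test_one_step_r6_scaling_of_depths():
    donors = [_donor_snapshot(i, d, 11.7, 23.8, 2.2) for i, d in enumerate([12.0, 14.0])]
    acceptors = [_acceptor_snapshot(j, d, {"S1": (3.0, 29.6, 2.3)})
                 for j, d in enumerate([18.0, 22.0])]
    base = one_step_total(donors, acceptors)
    s = 1.3
    donors_s = [_donor_snapshot(i, s * d, 11.7, 23.8, 2.2)
                for i, d in enumerate([12.0, 14.0])]
    acceptors_s = [_acceptor_snapshot(j, s * d, {"S1": (3.0, 29.6, 2.3)})
                   for j, d in enumerate([18.0, 22.0])]
    scaled = one_step_total(donors_s, acceptors_s)
    np.testing.assert_allclose(scaled.pair_rates, base.pair_rates / s**6, rtol=1e-10)


def test_one_step_additivity_over_states():
    donor = [_donor_snapshot(0, 13.3, 11.7, 23.8, 2.2)]
    both = one_step_total(donor, [_acceptor_snapshot(0, 20.1, {
        "S1": (3.0, 29.6, 2.3), "S2": (1.5, 49.6, 2.5)})])
    s1 = one_step_total(donor, [_acceptor_snapshot(0, 20.1, {"S1": (3.0, 29.6, 2.3)})])
    s2 = one_step_total(donor, [_acceptor_snapshot(0, 20.1, {"S2": (1.5, 49.6, 2.5)})])
    assert both.k_mean == pytest.approx(s1.k_mean + s2.k_mean, rel=1e-12)


def test_one_step_heavy_tailed_distances_beat_mean_distance(rng):
    """Jensen check: with heavy-tailed pair distances the mean of per-pair
    rates strictly exceeds the rate at the mean distance (r⁻⁶ convexity) —
    the systematic error of averaging distances first."""
    depths_d = 10.0 + rng.pareto(2.5, size=20) * 4.0
    depths_a = 14.0 + rng.pareto(2.5, size=20) * 4.0
    donors = [_donor_snapshot(i, d, 11.7, 23.8, 2.2) for i, d in enumerate(depths_d)]
    acceptors = [_acceptor_snapshot(j, d, {"S1": (3.0, 29.6, 2.3)})
                 for j, d in enumerate(depths_a)]
    per_pair = one_step_total(donors, acceptors)

    mean_r = depths_d.mean() + depths_a.mean()
    donors_m = [_donor_snapshot(0, depths_d.mean(), 11.7, 23.8, 2.2)]
    acceptors_m = [_acceptor_snapshot(0, depths_a.mean(), {"S1": (3.0, 29.6, 2.3)})]
    at_mean = one_step_total(donors_m, acceptors_m)
    assert mean_r > 21.0
    assert per_pair.k_mean > at_mean.k_mean


def test_one_step_per_state_means_are_means_of_pair_values():
    donors = [_donor_snapshot(i, d, 11.7, 23.8, 2.0 + 0.1 * i) for i, d in enumerate([12.0, 15.0])]
    acceptors = [_acceptor_snapshot(j, d, {"S1": (3.0, 29.6, 2.3), "S2": (1.0, 49.6, 2.6)})
                 for j, d in enumerate([18.0, 24.0])]
    res = one_step_total(donors, acceptors)
    # total mean rate equals the sum over states of the per-state mean rates
    assert res.per_state["mean_k_s"].sum() == pytest.approx(res.k_mean, rel=1e-12)
    # and is NOT the rate recomposed from averaged factors
    recomposed = fret_rate(res.per_state["mean_V2_J2"].to_numpy(),
                           res.per_state["mean_J_cm"].to_numpy()).sum()
    assert recomposed != pytest.approx(res.k_mean, rel=1e-3)


def test_one_step_missing_state_raises():
    donor = [_donor_snapshot(0, 13.3, 11.7, 23.8, 2.2)]
    acceptor = [_acceptor_snapshot(0, 20.1, {"S1": (3.0, 29.6, 2.3)})]
    with pytest.raises(ValueError, match="S9"):
        one_step_total(donor, acceptor, state_labels=["S9"])


def test_donor_snapshot_requires_single_emissive_transition():
    tdm = TransitionDipole("S1->S0", np.array([1.0, 0, 0]), vertical_energy_ev=2.2)
    with pytest.raises(ValueError, match="exactly one"):
        SnapshotRecord("donor", 0, 13.3, {"a": tdm, "b": tdm}, role="donor")


def test_snapshot_table_round_trip(tmp_path):
    donor = _donor_snapshot(3, 13.3, 11.7, 23.8, 2.2, azimuth_deg=40.0)
    acceptor = _acceptor_snapshot(5, 20.1, {"S1": (3.0, 29.6, 2.3), "S2": (1.0, 49.6, 2.6)})
    path = tmp_path / "snaps.csv"
    write_snapshots(path, [donor, acceptor])
    back = read_snapshots(path)
    by_role = {s.role: s for s in back}
    np.testing.assert_allclose(
        by_role["donor"].emission.vector_au, donor.emission.vector_au, rtol=1e-12
    )
    assert by_role["acceptor"].transitions["S2"].vertical_energy_ev == pytest.approx(2.6)
    assert by_role["acceptor"].depth_angstrom == pytest.approx(20.1)
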