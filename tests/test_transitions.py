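import numpy as np
import pytest

from supramol import synthetic
from supramol.clustering import AssemblyPartition, ClusteringParams, MembershipTrajectory
from supramol.transitions import (
    TransitionAnalysisConfig,
    assembly_transition_matrix,
    classify_event,
    classify_mechanisms,
    compute_transition_matrices,
    interconnection_graph,
    localize_exchange,
    monomer_transition_matrix,
    probability_matrix,
)


def part(t, labels, edges=()):
    labels = np.asarray(labels)
    e = np.array(sorted(tuple(sorted(x)) for x in edges), dtype=int)
    if e.size == 0:
        e = np.zeros((0, 2), dtype=int)
    return AssemblyPartition(t, labels, np.bincount(labels), e)


class TestMonomerMatrix:
    def test_direct_merge_counts(self):
        # {1,2} + {3,4,5} -> one 5-mer: two monomers move 2->5, three 3->5
        frames = [part(0.0, [0, 0, 1, 1, 1]), part(1.0, [0] * 5)]
        raw = monomer_transition_matrix(MembershipTrajectory(frames))
        assert raw[1, 4] == 2 and raw[2, 4] == 3
        assert raw.sum() == 5

    def test_static_trajectory_is_diagonal(self):
        frames = [part(float(t), [0] * 25) for t in range(10)]
        raw = monomer_transition_matrix(MembershipTrajectory(frames))
        assert raw[24, 24] == 25 * 9
        off = raw.copy()
        np.fill_diagonal(off, 0)
        assert off.sum() == 0

    def test_lag_must_divide_sampling(self, kmc_stationary):
        _, stationary, _, _ = kmc_stationary
        cfg = TransitionAnalysisConfig(delta_tau=0.05)  # 2.5x sample_dt
        with pytest.raises(ValueError, match="multiple"):
            monomer_transition_matrix(stationary, cfg)

    def test_stationary_raw_matrix_is_symmetric(self, kmc_stationary):
        """Detailed balance at equilibrium: binding events (upper triangle)
        balance unbinding events (lower triangle) within sampling error."""
        _, stationary, _, _ = kmc_stationary
        raw = monomer_transition_matrix(stationary)
        asym = np.abs(raw - raw.T).sum() / raw.sum()
        assert asym < 0.05


class TestProbabilityMatrix:
    def test_row_normalisation_example(self):
        prob = probability_matrix(np.array([[6, 2], [2, 0]]))
        np.testing.assert_allclose(prob, [[0.75, 0.25], [1.0, 0.0]])

    def test_zero_rows_flagged_nan(self):
        prob = probability_matrix(np.array([[1, 1], [0, 0]]))
        assert np.isnan(prob[1]).all()
        assert prob[0].sum() == 1.0

    def test_symmetric_raw_with_equal_rows_stays_symmetric(self):
        raw = np.array([[3, 2], [2, 3]])
        prob = probability_matrix(raw)
        np.testing.assert_allclose(prob, prob.T)

    def test_rows_sum_to_one_on_kmc(self, kmc_stationary):
        _, stationary, _, _ = kmc_stationary
        raw = monomer_transition_matrix(stationary)
        prob = probability_matrix(raw)
        occupied = raw.sum(axis=1) > 0
        np.testing.assert_allclose(prob[occupied].sum(axis=1), 1.0, atol=1e-12)


class TestAssemblyMatrix:
    def test_binary_merge_counted_once_per_partner(self):
        # merge 2+3 -> 5: raw[2,5] = 2 monomers, raw[3,5] = 3 monomers
        raw = np.zeros((5, 5))
        raw[1, 4] = 2
        raw[2, 4] = 3
        asm = assembly_transition_matrix(raw)
        assert asm[1, 4] == 1.0 and asm[2, 4] == 1.0

    def test_fragmentation_side(self):
        # 5 -> 2+3: raw[5,2] = 2, raw[5,3] = 3 (lower triangle, divide by j)
        raw = np.zeros((5, 5))
        raw[4, 1] = 2
        raw[4, 2] = 3
        asm = assembly_transition_matrix(raw)
        assert asm[4, 1] == 1.0 and asm[4, 2] == 1.0

    def test_diagonal_untouched(self):
        raw = np.diag([5.0, 8.0, 9.0])
        np.testing.assert_array_equal(assembly_transition_matrix(raw), raw)

    def test_kmc_assembly_events_match_log(self, kmc_stationary, kmc_events_in_window):
        """Each binary event appears at two (i, j) entries, so the
        off-diagonal assembly-matrix total is twice the logged event count."""
        _, stationary, _, _ = kmc_stationary
        mats = compute_transition_matrices(stationary)
        off = mats.assembly.copy()
        np.fill_diagonal(off, 0)
        expected = 2 * len(kmc_events_in_window)
        assert off.sum() == pytest.approx(expected, rel=0.05)


class TestMechanismClassification:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [(1, 30, "green"), (2, 10, "yellow"), (10, 15, "red"), (25, 40, "blue")],
    )
    def test_partner_size_rules(self, p1, p2, expected):
        assert classify_event(p1, p2, A=21, E=4) == expected

    def test_monomer_additions_to_dimers_all_yellow(self):
        raw = np.zeros((4, 4))
        raw[0, 2] = 5   # monomer joins a dimer -> trimer
        raw[1, 2] = 10  # the dimer side of the same events
        rep = classify_mechanisms(assembly_transition_matrix(raw), A=21, E=4)
        assert rep.percentages["yellow"] == 100.0

    def test_merge_only_large_kernel_all_blue(self):
        params = synthetic.KMCParams(
            n_monomers=120, k_merge=0.5, k_frag=0.0, t_end=50.0,
            sample_dt=0.05, seed=9, initial_sizes=[10] * 12,
        )
        with pytest.warns(UserWarning, match="zero total rate"):
            _, log = synthetic.run_kmc(params)
        rep = classify_mechanisms(log, A=10, E=2)
        assert rep.percentages["blue"] == 100.0

    def test_matrix_and_log_classifications_agree(self, kmc_stationary,
                                                  kmc_events_in_window):
        _, stationary, _, _ = kmc_stationary
        cfg = TransitionAnalysisConfig()
        mats = compute_transition_matrices(stationary, None)
        rep_m = classify_mechanisms(mats.assembly, membership=stationary,
                                    config=cfg)
        rep_l = classify_mechanisms(kmc_events_in_window, A=rep_m.A, E=rep_m.E)
        for c in ("yellow", "green", "red", "blue"):
            assert rep_m.percentages[c] == pytest.approx(
                rep_l.percentages[c], abs=1.0
            )

    def test_percentages_sum_to_100(self, kmc_events_in_window):
        rep = classify_mechanisms(kmc_events_in_window, A=7, E=2)
        assert sum(rep.percentages.values()) == pytest.approx(100.0)
        assert rep.small_species_pct + rep.large_fragment_pct == pytest.approx(100.0)

    def test_raising_A_moves_mass_out_of_blue(self, kmc_events_in_window):
        """Monotone threshold property: a larger 'large fibre' cutoff can
        only shrink the blue class."""
        prev_blue = 101.0
        for A in (4, 6, 8, 12, 16):
            rep = classify_mechanisms(kmc_events_in_window, A=A, E=2)
            assert rep.percentages["blue"] <= prev_blue + 1e-12
            prev_blue = rep.percentages["blue"]

    def test_lag_robustness(self, kmc_stationary):
        """Class percentages at a 10x coarser lag keep the same trend
        (every class moves by less than 15 percentage points)."""
        _, stationary, _, _ = kmc_stationary
        base = compute_transition_matrices(
            stationary, TransitionAnalysisConfig(delta_tau=0.02))
        coarse = compute_transition_matrices(
            stationary, TransitionAnalysisConfig(delta_tau=0.2))
        rep_b = classify_mechanisms(base.assembly, membership=stationary)
        rep_c = classify_mechanisms(coarse.assembly, A=rep_b.A, E=rep_b.E)
        for c in ("yellow", "green", "red", "blue"):
            assert abs(rep_b.percentages[c] - rep_c.percentages[c]) < 15.0

    def test_thresholds_require_E_below_A(self):
        with pytest.raises(ValueError, match="E < A"):
            classify_mechanisms(np.eye(3), A=2, E=2)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="off-diagonal"):
            classify_mechanisms(np.diag([3.0, 4.0]), A=5, E=2)


class TestInterconnectionGraph:
    def test_single_entry_single_edge(self):
        mat = np.zeros((40, 40))
        mat[0, 31] = 3.0   # monomer <-> 32-mer traffic
        g = interconnection_graph(mat, "log2")
        assert list(g.edges(data="weight")) == [("1", "17-32", 3.0)]

    def test_symmetric_matrix_gives_reciprocal_edges(self):
        mat = np.zeros((10, 10))
        mat[0, 5] = mat[5, 0] = 2.0
        g = interconnection_graph(mat, "none")
        assert g.has_edge("1", "6") and g.has_edge("6", "1")
        assert g["1"]["6"]["weight"] == g["6"]["1"]["weight"]


class TestLocalizeExchange:
    def _fibre_frames(self, break_at_tip: bool):
        """A 6-mer chain that loses one monomer, at the tip or mid-fibre."""
        from supramol.synthetic import make_fixture
        from supramol.clustering import detect_assemblies

        fx0 = make_fixture("ideal_fibre", 6, 0.5, 22.0)
        fx1 = fx0.copy()
        nb = fx0.topology.n_beads
        who = 5 if break_at_tip else 2
        fx1.positions[who * nb:(who + 1) * nb] += 5.0  # teleport far away
        if not break_at_tip:
            # close the gap so the remaining five form one fibre again
            for m in (3, 4, 5):
                tgt = m - 1
                fx1.positions[m * nb:(m + 1) * nb] = \
                    fx0.positions[tgt * nb:(tgt + 1) * nb]
            fx1.positions[2 * nb:3 * nb] = fx0.positions[5 * nb:6 * nb] + 5.0
        p0 = detect_assemblies(fx0, frame_time=0.0)
        p1 = detect_assemblies(fx1, frame_time=1.0)
        return MembershipTrajectory([p0, p1]), [fx0, fx1]

    def test_tip_detachment_attributed_to_tip(self):
        membership, frames = self._fibre_frames(break_at_tip=True)
        res = localize_exchange(membership, frames)
        assert res["n_unbinding"] >= 1
        assert res["tip_fraction"] == 1.0

    def test_mid_fibre_extraction_attributed_to_bulk(self):
        membership, frames = self._fibre_frames(break_at_tip=False)
        res = localize_exchange(membership, frames)
        assert res["bulk_fraction"] > 0.5

    def test_requires_aligned_geometry(self, kmc_stationary):
        _, stationary, _, _ = kmc_stationary
        with pytest.raises(ValueError, match="align"):
            localize_exchange(stationary, frames=[])
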