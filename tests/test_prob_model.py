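import numpy as np
import pytest

from chaintrace import fixtures, prob_model
from chaintrace.path_solver import BackbonePath
from chaintrace.pdbio import read_atoms
from chaintrace.prob_model import (
    DecoyEnsemble,
    ProbabilisticModel,
    bracket_thresholds,
    connectivity_probability,
    correspond_and_average,
    default_noise_schedule,
    generate_decoys,
    write_probabilistic_pdb,
)
from chaintrace.pseudoatoms import PseudoatomSet, ThresholdError


def make_ensemble(coord_sets, orders, thresholds=None, noise_levels=None):
    decoys = []
    for coords, order in zip(coord_sets, orders):
        pa = PseudoatomSet(coords=np.asarray(coords, dtype=float),
                           n_target=len(coords))
        d = np.linalg.norm(np.diff(pa.coords[np.asarray(order)], axis=0), axis=1)
        decoys.append(
            (pa, BackbonePath(order=np.asarray(order), total_length=float(d.sum()),
                              source=pa))
        )
    return DecoyEnsemble(
        decoys=decoys,
        thresholds=np.asarray(thresholds if thresholds is not None else [0.5]),
        noise_levels=np.asarray(noise_levels if noise_levels is not None else [0.0]),
    )


# Points on a circular arc with 3.8 A chords: the chain ordering is the
# unique TSP optimum (collinear points would be degenerate).
def arc_chain(n, step_deg=22.5):
    radius = 3.8 / (2 * np.sin(np.deg2rad(step_deg / 2)))
    t = np.deg2rad(step_deg) * np.arange(n)
    return np.stack([radius * np.cos(t), radius * np.sin(t), np.zeros(n)], axis=1)


CHAIN5 = arc_chain(5)
CHAIN8 = arc_chain(8)


class TestSchedules:
    def test_default_noise_schedule(self):
        sched = default_noise_schedule()
        assert len(sched) == 20
        assert sched[0] == 0.0 and sched[-1] == 5.0
        np.testing.assert_allclose(np.diff(sched), sched[1] - sched[0])

    def test_bracket_expansion(self):
        np.testing.assert_allclose(
            bracket_thresholds((0.2, 0.4, 0.1)), [0.2, 0.3, 0.4]
        )
        np.testing.assert_allclose(bracket_thresholds((0.5, 0.5, 0.1)), [0.5])

    def test_bad_interval_rejected(self):
        with pytest.raises(ValueError):
            bracket_thresholds((0.1, 0.5, 0.0))


class TestGenerateDecoys:
    def test_three_by_twenty_gives_sixty(self, helix_system):
        grid = helix_system.map
        ens = generate_decoys(
            grid,
            threshold=0.35,
            noise_levels=default_noise_schedule(),
            nres=12,
            base_seed=0,
            time_cap=5,
        )
        assert len(ens) == 60
        assert len(ens.thresholds) == 3

    def test_five_thresholds_give_hundred(self, helix_system):
        grid = helix_system.map
        ens = generate_decoys(
            grid,
            bracket=(0.25, 0.45, 0.05),
            noise_levels=default_noise_schedule(),
            nres=12,
            base_seed=0,
            time_cap=5,
        )
        assert len(ens) == 100
        assert len(ens.thresholds) == 5

    def test_degenerate_single_decoy_matches_plain_run(self, helix_system):
        from chaintrace.path_solver import solve_path
        from chaintrace.pseudoatoms import seed_pseudoatoms

        grid = helix_system.map
        ens = generate_decoys(
            grid, bracket=(0.35, 0.35, 0.1), noise_levels=[0.0], nres=12,
            base_seed=0, time_cap=5,
        )
        assert len(ens) == 1
        pa = seed_pseudoatoms(grid, threshold=0.35, nres=12, method="kmeans", seed=0)
        plain = solve_path(pa, time_cap=5)
        np.testing.assert_array_equal(ens.decoys[0][1].order, plain.order)

    def test_offending_threshold_named(self, helix_system):
        with pytest.raises(ThresholdError, match="0.9"):
            generate_decoys(
                helix_system.map, bracket=(0.3, 0.9, 0.3), noise_levels=[0.0],
                nres=30,
            )

    def test_count_law(self, helix_system):
        ens = generate_decoys(
            helix_system.map, bracket=(0.3, 0.4, 0.05), noise_levels=[0.0, 1.0],
            nres=10, time_cap=5,
        )
        assert len(ens) == len(ens.thresholds) * len(ens.noise_levels) == 6


class TestCorrespondAndAverage:
    def test_identical_decoys_average_to_themselves(self):
        order = np.arange(5)
        ens = make_ensemble([CHAIN5] * 4, [order] * 4)
        model = correspond_and_average(ens)
        np.testing.assert_allclose(model.avg_coords, CHAIN5, atol=1e-12)

    def test_mirrored_decoys_average_to_truth(self):
        delta = np.array([0.0, 0.4, 0.0])
        order = np.arange(5)
        ens = make_ensemble([CHAIN5 + delta, CHAIN5 - delta], [order, order])
        model = correspond_and_average(ens)
        np.testing.assert_allclose(model.avg_coords, CHAIN5, atol=1e-9)

    def test_matching_cost_not_worse_than_identity(self, helix_system):
        grid = helix_system.map
        ens = generate_decoys(
            grid, threshold=0.35, noise_levels=[0.0, 1.0, 2.0], nres=10,
            base_seed=3, time_cap=5,
        )
        correspond_and_average(ens)
        ref = ens.decoys[ens.reference_index][0].coords
        for mapping, (pa, _) in zip(ens.correspondence, ens.decoys):
            matched = ((ref - pa.coords[mapping]) ** 2).sum()
            identity = ((ref - pa.coords) ** 2).sum()
            assert matched <= identity + 1e-9

    def test_reference_is_zero_noise_central_threshold(self, helix_system):
        ens = generate_decoys(
            helix_system.map, bracket=(0.3, 0.4, 0.05), noise_levels=[0.0, 1.0],
            nres=10, time_cap=5,
        )
        correspond_and_average(ens)
        n_noise = len(ens.noise_levels)
        assert ens.reference_index == (len(ens.thresholds) // 2) * n_noise


class TestConnectivityProbability:
    def test_identical_decoys_score_100(self):
        order = np.arange(5)
        ens = make_ensemble([CHAIN5] * 6, [order] * 6)
        model = correspond_and_average(ens)
        model = connectivity_probability(model, ens)
        np.testing.assert_allclose(model.probability, 100.0)

    def test_half_swapped_interior_neighbors_score_50(self):
        """4 decoys on identical coordinates; 2 swap the path positions of
        the distant interior nodes 2 and 5. Exhaustive neighbor check:

        order A = [0,1,2,3,4,5,6,7]: neighbors 2:{1,3}, 5:{4,6}
        order B = [0,1,5,3,4,2,6,7]: neighbors 2:{4,6}, 5:{1,3}
        Against avg (= A): nodes 2 and 5 share no neighbors with their
        decoy-B selves -> score 0 in half the decoys -> exactly 50%.
        Nodes 1,3,4,6 lose one of two neighbors in B -> 75%; termini keep
        theirs -> 100%.
        """
        A = np.arange(8)
        B = np.array([0, 1, 5, 3, 4, 2, 6, 7])
        ens = make_ensemble([CHAIN8] * 4, [A, A, B, B])
        model = correspond_and_average(ens)
        # the chain is the unique optimum (up to reversal, which leaves
        # unordered adjacency unchanged)
        assert list(model.avg_path.order) in (list(range(8)), list(range(7, -1, -1)))
        model = connectivity_probability(model, ens)
        np.testing.assert_allclose(model.probability[[2, 5]], 50.0)
        np.testing.assert_allclose(model.probability[[1, 3, 4, 6]], 75.0)
        np.testing.assert_allclose(model.probability[[0, 7]], 100.0)

    def test_probabilities_bounded(self, helix_system):
        ens = generate_decoys(
            helix_system.map, threshold=0.35, noise_levels=[0.0, 2.0, 4.0],
            nres=10, base_seed=1, time_cap=5,
        )
        model = connectivity_probability(correspond_and_average(ens), ens)
        assert np.all(model.probability >= 0.0)
        assert np.all(model.probability <= 100.0)

    def test_zero_noise_single_threshold_all_100(self, helix_system):
        ens = generate_decoys(
            helix_system.map, bracket=(0.35, 0.35, 0.1), noise_levels=[0.0] * 5,
            nres=12, time_cap=5,
        )
        model = connectivity_probability(correspond_and_average(ens), ens)
        np.testing.assert_allclose(model.probability, 100.0)

    def test_monotone_degradation_with_noise(self, helix_system):
        grid = helix_system.map

        def mean_prob(noise_max):
            ens = generate_decoys(
                grid, threshold=0.35, noise_levels=np.linspace(0, noise_max, 6),
                nres=15, base_seed=2, time_cap=5,
            )
            m = connectivity_probability(correspond_and_average(ens), ens)
            return m.probability.mean()

        assert mean_prob(5.0) <= mean_prob(1.0) + 1e-9

    def test_termini_less_confident_than_interior(self):
        tms, ims = [], []
        for seed in (1, 2, 3):
            system = fixtures.make_system(
                n_res=25, motif="random-walk", resolution=4.0, seed=seed
            )
            grid = system.map
            tau = 0.35 * float(grid.values.max())
            ens = generate_decoys(
                grid, threshold=tau, noise_levels=np.linspace(0, 2, 6),
                nres=25, base_seed=seed, time_cap=5,
            )
            m = connectivity_probability(correspond_and_average(ens), ens)
            order = m.avg_path.order
            tms.append(np.mean(m.probability[[int(order[0]), int(order[-1])]]))
            ims.append(np.mean(m.probability[order[1:-1].astype(int)]))
        assert np.mean(tms) <= np.mean(ims)


class TestWriteProbabilisticPdb:
    @pytest.fixture()
    def written_model(self, tmp_path):
        order = np.arange(5)
        ens = make_ensemble([CHAIN5] * 3, [order] * 3)
        model = connectivity_probability(correspond_and_average(ens), ens)
        out = tmp_path / "prob.pdb"
        write_probabilistic_pdb(model, out)
        return model, out

    def test_b_factor_field_formatting(self, written_model):
        _, out = written_model
        atom_lines = [l for l in out.read_text().splitlines() if l.startswith("ATOM")]
        assert len(atom_lines) == 5
        assert all(line[60:66] == "100.00" for line in atom_lines)

    def test_round_trip_probabilities(self, written_model):
        model, out = written_model
        atoms = read_atoms(out)
        probs = np.array([a.b_factor for a in atoms])
        np.testing.assert_allclose(np.sort(probs), np.sort(model.probability),
                                   atol=0.005)

    def test_strict_column_layout(self, written_model):
        _, out = written_model
        for line in out.read_text().splitlines():
            if not line.startswith("ATOM"):
                continue
            assert line[12:16].strip() == "CA"
            assert line[17:20] == "ALA"
            assert line[21] == "A"
            int(line[22:26])           # residue number parses
            float(line[30:38])         # x
            float(line[38:46])         # y
            float(line[46:54])         # z
            float(line[54:60])         # occupancy
            float(line[60:66])         # B-factor
            assert line[76:78].strip() == "C"

    def test_unwritable_path_raises(self):
        order = np.arange(5)
        ens = make_ensemble([CHAIN5] * 2, [order] * 2)
        model = connectivity_probability(correspond_and_average(ens), ens)
        with pytest.raises(IOError):
            write_probabilistic_pdb(model, "/nonexistent-dir/x.pdb")

    def test_probability_required(self):
        model = ProbabilisticModel(
            avg_coords=CHAIN5,
            avg_path=BackbonePath(order=np.arange(5), total_length=0.0),
        )
        with pytest.raises(ValueError):
            write_probabilistic_pdb(model, "unused.pdb")


class TestValidation:
    def test_probability_range_enforced(self):
        with pytest.raises(ValueError):
            ProbabilisticModel(
                avg_coords=CHAIN5,
                avg_path=BackbonePath(order=np.arange(5), total_length=0.0),
                probability=np.array([0, 50, 101, 50, 0]),
            )

    def test_mismatched_node_counts_rejected(self):
        pa1 = PseudoatomSet(coords=CHAIN5, n_target=5)
        pa2 = PseudoatomSet(coords=CHAIN5[:4], n_target=4)
        p1 = BackbonePath(order=np.arange(5), total_length=0.0, source=pa1)
        p2 = BackbonePath(order=np.arange(4), total_length=0.0, source=pa2)
        with pytest.raises(ValueError):
            DecoyEnsemble(
                decoys=[(pa1, p1), (pa2, p2)],
                thresholds=np.array([0.5]),
                noise_levels=np.array([0.0]),
            )
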