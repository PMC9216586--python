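import numpy as np
import pytest

from ssforge.geometry import TorsionSet, build_backbone, measure_torsions
from ssforge.ranmod import (DEFAULT_REGIONS, Conformation, RanmodConfig,
                            SecondaryStructureClue, clash_filter,
                            connectivity_passes, evaluate_connectivity,
                            run_ranmod, sample_torsions)

PC16A_LIKE = "ACACAAAAACC"          # 11 residues, Cys at 2, 4, 10, 11
PC16A_PAIRING = [(2, 10), (4, 11)]  # interlocked connectivity
# seed whose first accepted conformation appears within 300 trials
QUICK_SEED, QUICK_TRIALS = 37, 300


def helix_box_contains(phi, psi):
    box = DEFAULT_REGIONS["helix-clue"][0]
    return box.contains(phi, psi)


class TestSampleTorsions:
    def test_full_length_helix_clue_constrains_every_residue(self):
        rng = np.random.default_rng(0)
        ts, names = sample_torsions("A" * 20,
                                    [SecondaryStructureClue(1, 20, "helix")], rng)
        assert all(helix_box_contains(t.phi, t.psi) for t in ts)
        assert set(names) == {"helix-clue"}

    def test_same_seed_reproduces_the_draw(self):
        a, _ = sample_torsions("ACGPA", rng=np.random.default_rng(5))
        b, _ = sample_torsions("ACGPA", rng=np.random.default_rng(5))
        assert [(t.phi, t.psi) for t in a] == [(t.phi, t.psi) for t in b]

    def test_glycine_reaches_positive_phi_but_alanine_does_not(self):
        rng = np.random.default_rng(1)
        gly_phi = [t.phi for _ in range(500)
                   for t in sample_torsions("G" * 20, rng=rng)[0]]
        ala_phi = [t.phi for _ in range(500)
                   for t in sample_torsions("A" * 20, rng=rng)[0]]
        assert sum(p > 0 for p in gly_phi) > 0
        assert sum(p > 100 for p in ala_phi) == 0

    def test_proline_phi_stays_in_its_narrow_box(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            ts, _ = sample_torsions("PPPP", rng=rng)
            assert all(-78.0 <= t.phi <= -48.0 for t in ts)

    def test_every_draw_lies_in_its_named_region(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            ts, names = sample_torsions("AGPCA", rng=rng)
            for t, name in zip(ts, names):
                boxes = [b for cls in DEFAULT_REGIONS.values() for b in cls
                         if b.name == name]
                assert any(b.contains(t.phi, t.psi) for b in boxes)

    def test_clue_out_of_range_raises(self):
        with pytest.raises(ValueError, match="outside sequence"):
            sample_torsions("AAAA", [SecondaryStructureClue(2, 9, "helix")],
                            np.random.default_rng(0))


class TestClashFilter:
    def test_extended_chain_passes(self):
        n = 12
        ts = [TorsionSet(phi=None if i == 0 else -120.0,
                         psi=None if i == n - 1 else 130.0) for i in range(n)]
        assert clash_filter(build_backbone("A" * n, ts), 3.5)

    def test_chain_folded_through_itself_fails(self):
        # frozen torsion set whose arms pass within 2.9 A of each other
        angles = [(-53.4, -39.3), (-54.0, -69.2), (-119.0, 165.0),
                  (-47.9, -66.7), (-68.5, -21.7), (-139.3, 116.9),
                  (-141.9, 108.7), (-60.7, -42.3), (-115.2, 120.2)]
        n = len(angles)
        ts = [TorsionSet(phi=p, psi=s) for p, s in angles]
        coords = build_backbone("A" * n, ts)
        ca = np.array([c["CA"] for c in coords])
        dmin = min(np.linalg.norm(ca[i] - ca[j])
                   for i in range(n) for j in range(i + 3, n))
        assert dmin < 3.5
        assert not clash_filter(coords, 3.5)

    def test_zero_threshold_always_passes(self):
        ts = [TorsionSet(phi=None, psi=-47.0), TorsionSet(phi=-57.0, psi=None)]
        assert clash_filter(build_backbone("AA", ts), 0.0)


def make_conformation(sequence, torsions, names=None):
    coords = build_backbone(sequence, torsions)
    return Conformation(sequence, torsions, names or ["?"] * len(sequence),
                        coords)


class TestEvaluateConnectivity:
    def test_accepted_trial_torsions_grade_within_accept_set(self):
        cfg = RanmodConfig(n_trials=QUICK_TRIALS, seed=QUICK_SEED, max_models=1)
        run = run_ranmod(PC16A_LIKE, PC16A_PAIRING, (), cfg)
        assert run.models, "frozen seed must reproduce its accepted trial"
        conf = run.models[0].conformation
        models = evaluate_connectivity(conf, PC16A_PAIRING, cfg)
        assert connectivity_passes(models, cfg.accept_grades)

    def test_extended_chain_fails_on_distance(self):
        n = 11
        ts = [TorsionSet(phi=None if i == 0 else -120.0,
                         psi=None if i == n - 1 else 130.0) for i in range(n)]
        conf = make_conformation(PC16A_LIKE, ts)
        models = evaluate_connectivity(conf, [(2, 10)])
        assert models == [None]

    def test_empty_pairing_passes_vacuously(self):
        ts = [TorsionSet(phi=None if i == 0 else -57.0,
                         psi=None if i == 10 else -47.0) for i in range(11)]
        conf = make_conformation(PC16A_LIKE, ts)
        assert connectivity_passes(evaluate_connectivity(conf, []))

    def test_non_cysteine_position_raises(self):
        ts = [TorsionSet(phi=None if i == 0 else -57.0,
                         psi=None if i == 10 else -47.0) for i in range(11)]
        conf = make_conformation(PC16A_LIKE, ts)
        with pytest.raises(ValueError, match="not cysteine"):
            evaluate_connectivity(conf, [(1, 10)])


class TestRunRanmod:
    def test_rerun_with_same_seed_is_bit_identical(self):
        cfg = RanmodConfig(n_trials=QUICK_TRIALS, seed=QUICK_SEED, max_models=5)
        a = run_ranmod(PC16A_LIKE, PC16A_PAIRING, (), cfg)
        b = run_ranmod(PC16A_LIKE, PC16A_PAIRING, (), cfg)
        assert a.summary == b.summary
        assert len(a.models) == len(b.models) >= 1
        for ma, mb in zip(a.models, b.models):
            assert ma.trial_index == mb.trial_index
            for ra, rb in zip(ma.conformation.coords, mb.conformation.coords):
                for k in ra:
                    assert np.array_equal(ra[k], rb[k])

    def test_emitted_models_are_valid(self):
        cfg = RanmodConfig(n_trials=QUICK_TRIALS, seed=QUICK_SEED, max_models=5)
        run = run_ranmod(PC16A_LIKE, PC16A_PAIRING, (), cfg)
        for m in run.models:
            assert clash_filter(m.conformation.coords, cfg.clash_min_ca)
            assert all(b is not None and b.grade in cfg.accept_grades
                       for b in m.bridge_models)
            measured = measure_torsions(m.conformation.coords)
            for i, (t, name) in enumerate(zip(measured,
                                              m.conformation.regions)):
                if t.phi is None or t.psi is None:
                    continue
                boxes = [b for cls in DEFAULT_REGIONS.values() for b in cls
                         if b.name == name]
                assert any(b.contains(t.phi, t.psi, tol=1e-6) for b in boxes)

    def test_accepted_count_non_decreasing_in_trials(self):
        counts = []
        for n in (100, 400, 1200):
            cfg = RanmodConfig(n_trials=n, seed=QUICK_SEED, max_models=3)
            counts.append(run_ranmod(PC16A_LIKE, PC16A_PAIRING, (), cfg
                                     ).summary["n_pass"])
        assert counts == sorted(counts)

    def test_single_failing_trial_yields_empty_model_list(self):
        cfg = RanmodConfig(n_trials=1, seed=0, max_models=3)
        run = run_ranmod(PC16A_LIKE, PC16A_PAIRING, (), cfg)
        assert run.models == []
        assert run.summary["n_trials"] == 1
        assert sum(run.summary["rejected"].values()) == 1

    def test_pairing_without_cysteines_raises(self):
        with pytest.raises(ValueError, match="no cysteine"):
            run_ranmod("AAAAAAAAAA", [(2, 8)], (),
                       RanmodConfig(n_trials=1, seed=0))

    def test_helix_clues_constrain_emitted_models(self):
        # clue residues of every accepted model must carry helix torsions
        seq = "A" * 14
        clues = [SecondaryStructureClue(3, 8, "helix")]
        cfg = RanmodConfig(n_trials=50, seed=2, max_models=5)
        run = run_ranmod(seq, [], clues, cfg)
        assert run.models, "no bridges requested: compact trials should pass"
        for m in run.models:
            measured = measure_torsions(m.conformation.coords)
            for pos in range(2, 8):
                t = measured[pos]
                if t.phi is not None and t.psi is not None:
                    assert helix_box_contains(t.phi, t.psi)

    def test_grade_d_cannot_be_accepted(self):
        with pytest.raises(ValueError):
            RanmodConfig(accept_grades=frozenset({"A", "D"}))
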