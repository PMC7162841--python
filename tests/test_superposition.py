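"""Kabsch superposition, protodomain alignment, and derived alignments."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from protosym.config import AnalysisConfig
from protosym.superpose import (
    AlignmentFailedError,
    Correspondence,
    DegenerateInputError,
    HelixUnit,
    UndefinedIdentityError,
    align_to_reference,
    align_units,
    derive_sequence_alignment,
    dp_helix_pair,
    kabsch_superpose,
    percent_identity,
)
from protosym.structure import Residue
from protosym.synthetic import BundleSpec, make_ideal_helix, make_pseudo_symmetric_domain
from protosym.protodomains import assign_tm_segments
from protosym.symmetry import rotation_to_angle_axis


def _unit_from_coords(coords, start=1, chain="A", aa="L"):
    res = [Residue(chain, start + i, "", aa, c) for i, c in enumerate(coords)]
    return HelixUnit(res, len(res) // 2)


class TestKabsch:
    def test_identical_clouds(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(12, 3))
        fit = kabsch_superpose(a, a)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(fit.rotation, np.eye(3), atol=1e-9)

    def test_rotation_recovered(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(10, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        b = a @ rot.T  # b is a rotated by +90°; superposing b onto a undoes it
        fit = kabsch_superpose(a, b)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-9)
        angle, axis = rotation_to_angle_axis(fit.rotation)
        assert angle == pytest.approx(90.0, abs=1e-6)
        assert abs(abs(axis[2]) - 1.0) < 1e-9

    def test_matches_numerical_optimizer_oracle(self):
        """Closed-form Kabsch equals an independent optimizer over rotations."""
        from scipy.optimize import minimize

        rng = np.random.default_rng(3)
        a = rng.normal(scale=4.0, size=(10, 3))
        rot = Rotation.random(random_state=np.random.RandomState(7)).as_matrix()
        b = (a + rng.normal(scale=0.4, size=a.shape)) @ rot.T + np.array([1.0, 2.0, 3.0])
        fit = kabsch_superpose(a, b)

        def cost(rotvec):
            r = Rotation.from_rotvec(rotvec).as_matrix()
            bb = b @ r.T
            bb = bb - bb.mean(axis=0) + a.mean(axis=0)
            return np.sqrt(((bb - a) ** 2).sum(axis=1).mean())

        best = min(
            (
                minimize(cost, x0, method="Nelder-Mead",
                         options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
                for x0 in [np.zeros(3), np.array([1.0, 1.0, 1.0]),
                           np.array([-2.0, 0.5, 1.5]), np.array([0.0, 3.0, 0.0])]
            ),
            key=lambda r: r.fun,
        )
        assert fit.rmsd <= best.fun + 0.05
        assert abs(fit.rmsd - best.fun) < 0.05

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        with pytest.raises(DegenerateInputError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_reflection_excluded(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(8, 3))
        b = a * np.array([1.0, 1.0, -1.0])  # mirrored cloud
        fit = kabsch_superpose(a, b)
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-9)
        assert fit.rmsd > 0.0

    def test_rmsd_symmetry_and_rigid_invariance(self):
        rng = np.random.default_rng(5)
        a = rng.normal(scale=3.0, size=(15, 3))
        b = a + rng.normal(scale=0.5, size=a.shape)
        r_ab = kabsch_superpose(a, b).rmsd
        r_ba = kabsch_superpose(b, a).rmsd
        assert r_ab == pytest.approx(r_ba, abs=1e-6)
        rot = Rotation.from_euler("xyz", [10, 70, -30], degrees=True).as_matrix()
        moved = a @ rot.T + np.array([3.0, -2.0, 8.0])
        assert kabsch_superpose(moved, b).rmsd == pytest.approx(r_ab, abs=1e-6)


class TestDPAlignment:
    @staticmethod
    def _brute_force(dist, d_cut, gap):
        """Exhaustive search over all monotone matchings, same objective."""
        n, m = dist.shape
        allowed = [(i, j) for i in range(n) for j in range(m) if dist[i, j] < d_cut]

        def score(pairs):
            if not pairs:
                return 0.0
            s = sum(d_cut - dist[i, j] for i, j in pairs)
            ia = [i for i, _ in pairs]
            jb = [j for _, j in pairs]
            s -= gap * ((ia[-1] - ia[0] + 1 - len(pairs))
                        + (jb[-1] - jb[0] + 1 - len(pairs)))
            return s

        best = 0.0
        stack = [([], 0)]
        while stack:
            chosen, start = stack.pop()
            best = max(best, score(chosen))
            for k in range(start, len(allowed)):
                i, j = allowed[k]
                if not chosen or (i > chosen[-1][0] and j > chosen[-1][1]):
                    stack.append((chosen + [(i, j)], k + 1))
        return best

    def test_dp_equals_exhaustive_search(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            n, m = rng.integers(3, 7, 2)
            dist = rng.uniform(0.0, 10.0, (n, m))
            pairs = dp_helix_pair(dist, 6.0, 3.0)
            got = 0.0
            if pairs:
                s = sum(6.0 - dist[i, j] for i, j in pairs)
                ia = [i for i, _ in pairs]
                jb = [j for _, j in pairs]
                got = s - 3.0 * ((ia[-1] - ia[0] + 1 - len(pairs))
                                 + (jb[-1] - jb[0] + 1 - len(pairs)))
            assert got == pytest.approx(self._brute_force(dist, 6.0, 3.0), abs=1e-9)

    def test_shifted_helix_register_selected(self):
        """A one-turn (4-residue) register shift is found by the DP stage."""
        coords = make_ideal_helix(20, np.zeros(3), np.array([0, 0, 1.0]))
        unit_a = _unit_from_coords(coords)
        # same helix, B's residues shifted by a full turn along the axis
        shifted = make_ideal_helix(20, np.array([0.0, 0.0, 4 * 1.5]),
                                   np.array([0, 0, 1.0]), phase=4 * 100.0)
        # B residue i sits where A residue i+4 does, but B's stated center
        # matches A's index: the seed register is wrong by one full turn
        unit_b = HelixUnit(
            [Residue("B", i + 1, "", "L", c) for i, c in enumerate(shifted)],
            10,
        )
        second_a = _unit_from_coords(coords + np.array([9.0, 0.0, 0.0]), chain="A")
        second_b = HelixUnit(
            [Residue("B", 100 + i, "", "L", c)
             for i, c in enumerate(shifted + np.array([9.0, 0.0, 0.0]))],
            10,
        )
        fit = align_units([unit_a, second_a], [unit_b, second_b], AnalysisConfig())
        assert fit.rmsd < 1e-6
        # the matched pairs realize the one-turn register shift
        i_a = [p[0].seq_number for p in fit.correspondence.pairs]
        i_b = [p[1].seq_number for p in fit.correspondence.pairs]
        shifts = {a - b for a, b in zip(i_a, i_b) if b < 100}
        assert shifts == {4}

    def test_refinement_never_increases_rmsd_at_sigma0(self):
        model, gt = make_pseudo_symmetric_domain(BundleSpec(seed=31))
        segs = assign_tm_segments(model, model.frame, "A")
        units = [
            HelixUnit(list(s.residues), s.h_center_index, s.axis) for s in segs
        ]
        pd1, pd2 = units[:3], units[3:]
        from protosym.superpose import _fit, _seed_pairs

        seed_pairs = []
        for ha, hb in zip(pd1, pd2):
            for ia, ib in _seed_pairs(ha, hb):
                seed_pairs.append((ha.residues[ia], hb.residues[ib]))
        seed_rmsd = _fit(seed_pairs).rmsd
        final = align_units(pd1, pd2, AnalysisConfig())
        assert final.rmsd <= seed_rmsd + 1e-9

    def test_sigma0_domain_aligns_exactly_with_gt_mapping(self, parallel_domain):
        model, gt = parallel_domain
        segs = assign_tm_segments(model, model.frame, "A")
        units = [HelixUnit(list(s.residues), s.h_center_index, s.axis) for s in segs]
        fit = align_units(units[:3], units[3:], AnalysisConfig())
        assert fit.rmsd < 1e-6
        for ra, rb in fit.correspondence.pairs:
            # generator numbering: pd2 helices start exactly 120 later
            assert rb.seq_number - ra.seq_number == 120

    def test_helix_count_mismatch_rejected(self, parallel_domain):
        model, _ = parallel_domain
        segs = assign_tm_segments(model, model.frame, "A")
        units = [HelixUnit(list(s.residues), s.h_center_index) for s in segs]
        with pytest.raises(AlignmentFailedError):
            align_units(units[:2], units[3:], AnalysisConfig())


class TestSequenceAlignment:
    def _toy_units(self):
        coords = make_ideal_helix(6, np.zeros(3), np.array([0, 0, 1.0]))
        a = HelixUnit([Residue("A", i + 1, "", aa, c)
                       for i, (aa, c) in enumerate(zip("ACDEFG", coords))], 3)
        b = HelixUnit([Residue("B", i + 1, "", aa, c)
                       for i, (aa, c) in enumerate(zip("AYDEFG", coords))], 3)
        return a, b

    def test_full_correspondence_gapless(self):
        a, b = self._toy_units()
        corr = Correspondence(tuple(zip(a.residues, b.residues)))
        row_a, row_b = derive_sequence_alignment(corr, [a], [b])
        assert row_a == "ACDEFG"
        assert row_b == "AYDEFG"

    def test_skipped_residue_becomes_gap(self):
        a, b = self._toy_units()
        pairs = [(a.residues[i], b.residues[j])
                 for i, j in [(0, 0), (1, 1), (3, 2), (4, 3), (5, 4)]]
        row_a, row_b = derive_sequence_alignment(Correspondence(tuple(pairs)), [a], [b])
        assert row_a == "ACDEFG-"
        assert row_b == "AY-DEFG"
        assert row_a.count("-") == 1 and row_b.count("-") == 1

    def test_fasta_round_trip_preserves_correspondence(self, tmp_path):
        a, b = self._toy_units()
        pairs = [(a.residues[i], b.residues[j])
                 for i, j in [(0, 0), (1, 1), (3, 2), (4, 3), (5, 4)]]
        row_a, row_b = derive_sequence_alignment(Correspondence(tuple(pairs)), [a], [b])
        p = tmp_path / "aln.fasta"
        p.write_text(f">a\n{row_a}\n>b\n{row_b}\n")
        from Bio import SeqIO

        back = {r.id: str(r.seq) for r in SeqIO.parse(str(p), "fasta")}
        # reconstruct matched index pairs from shared columns
        ia = ib = 0
        got = []
        for ca, cb in zip(back["a"], back["b"]):
            if ca != "-" and cb != "-":
                got.append((ia, ib))
            if ca != "-":
                ia += 1
            if cb != "-":
                ib += 1
        assert got == [(0, 0), (1, 1), (3, 2), (4, 3), (5, 4)]

    @pytest.mark.parametrize(
        "rows, expected",
        [(("ACDE", "ACDE"), 100.0), (("AC-D", "AY-D"), 200.0 / 3)],
    )
    def test_percent_identity(self, rows, expected):
        assert percent_identity(rows) == pytest.approx(expected, abs=1e-9)

    def test_percent_identity_undefined(self):
        with pytest.raises(UndefinedIdentityError):
            percent_identity(("A---", "-CDE"))


class TestAlignToReference:
    def _domain_units(self, sigma, seed):
        model, _ = make_pseudo_symmetric_domain(
            BundleSpec(noise_sigma=sigma, seed=seed)
        )
        segs = assign_tm_segments(model, model.frame, "A")
        return [HelixUnit(list(s.residues), s.h_center_index, s.axis)
                for s in segs[:3]]

    def test_identical_copies_rmsd_zero(self):
        u = self._domain_units(0.0, 41)
        entries = align_to_reference([("ref", u), ("c1", u), ("c2", u)])
        assert all(e.rmsd == pytest.approx(0.0, abs=1e-9) for e in entries)

    def test_reference_row_is_identity(self):
        u = self._domain_units(0.0, 41)
        entries = align_to_reference([("ref", u), ("copy", u)])
        row_a, row_b = entries[1].alignment
        assert row_a == row_b
        assert percent_identity((row_a, row_b)) == pytest.approx(100.0)

    def test_rmsd_ordering_follows_noise(self):
        wins = 0
        for seed in range(20):
            ref = self._domain_units(0.0, 100 + seed)
            noisy1 = self._domain_units(0.3, 100 + seed)
            noisy2 = self._domain_units(0.6, 100 + seed)
            entries = align_to_reference([("ref", ref), ("a", noisy1), ("b", noisy2)])
            if entries[1].rmsd < entries[2].rmsd:
                wins += 1
        assert wins >= 16  # Monte-Carlo: σ=0.3 beats σ=0.6 nearly always
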