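"""Pair and complex scoring, the shuffled background, Z score and calls."""

import numpy as np
import pytest

from ppiscore.contacts import ResiduePairContact, find_contacts
from ppiscore.errors import (
    DegenerateBackgroundError,
    NoInterfaceError,
    ParameterError,
)
from ppiscore.potential import MODES, N_AA, Potential
from ppiscore.scoring import (
    BINDER,
    NON_BINDER,
    BackgroundDistribution,
    background_distribution,
    classify,
    normalize_score,
    raw_score,
    score_complex,
    score_pair,
    z_score,
)
from ppiscore.structure import Atom, Residue
from ppiscore.synth import FixtureSpec, make_complex


def _pair(aa_i="A", aa_j="C", **counts):
    res_i = Residue("A", 1, "", aa_i, [Atom("CA", "C", np.zeros(3), True)])
    res_j = Residue("B", 1, "", aa_j, [Atom("CA", "C", np.ones(3), True)])
    return ResiduePairContact(res_i=res_i, res_j=res_j, d_min=1.7, **counts)


@pytest.fixture
def hand_potential():
    """Small hand-filled potential with a known arithmetic answer."""
    w = {m: np.zeros((N_AA, N_AA)) for m in MODES}
    w["MM"][0, 1] = w["MM"][1, 0] = -2.0  # (A, C)
    w["SS"][0, 1] = w["SS"][1, 0] = -1.0
    g = {
        ("MM", "A", "C"): {1: 1.0, 2: 0.5},
        ("SS", "A", "C"): {3: 1.0},
    }
    return Potential(w=w, g=g, kappa=1.0)


class TestScorePair:
    def test_zero_matrices_score_zero(self, zero_potential):
        assert score_pair(_pair(n_ss=4), zero_potential) == 0.0

    def test_modal_ss_contact_gets_full_weight(self, hand_potential):
        assert score_pair(_pair(n_ss=3), hand_potential) == pytest.approx(-1.0)

    def test_hand_summed_mixed_modes(self, hand_potential):
        # MM at n=2 -> -2.0 * 0.5; SS at n=3 -> -1.0 * 1.0; total -2.0
        c = _pair(n_mm=2, n_ss=3)
        assert score_pair(c, hand_potential) == pytest.approx(-2.0)

    def test_unseen_count_uses_floor(self, hand_potential):
        # SS at n=1 is unseen -> -1.0 * 0.1
        assert score_pair(_pair(n_ss=1), hand_potential) == pytest.approx(-0.1)

    def test_clash_replaces_score_with_penalty(self, hand_potential):
        c = _pair(n_mm=2, n_ss=3, n_clash=2)
        assert score_pair(c, hand_potential) == pytest.approx(2.0)  # kappa * 2


class TestRawScore:
    def test_sum_and_count(self, dimer, random_potential):
        iface = find_contacts(dimer.structure, 4)
        S, N = raw_score(iface, random_potential)
        assert N == len(iface)
        resummed = sum(score_pair(c, random_potential) for c in iface.pairs)
        assert S == pytest.approx(resummed, abs=1e-9)

    def test_additive_over_disjoint_interfaces(self, random_potential):
        fix = make_complex(FixtureSpec(n_chains=3, seed=4))
        iface = find_contacts(fix.structure, 4)
        S_all, N_all = raw_score(iface, random_potential)
        parts = [raw_score(iface.subset(cp), random_potential)
                 for cp in iface.interfaces]
        assert N_all == sum(n for _, n in parts)
        assert S_all == pytest.approx(sum(s for s, _ in parts), abs=1e-9)

    def test_empty_interface_raises(self, zero_potential):
        fix = make_complex(FixtureSpec(seed=1, inter_chain_gap=10.0))
        iface = find_contacts(fix.structure, 4)
        with pytest.raises(NoInterfaceError):
            raw_score(iface, zero_potential)


class TestNormalize:
    @pytest.mark.parametrize(
        "S,N,expected",
        [(-2053.27, 124, -16.56), (-1243.68, 123, -10.11), (0.0, 17, 0.0),
         (-3.0, 3, -1.0)],
    )
    def test_values(self, S, N, expected):
        assert normalize_score(S, N) == pytest.approx(expected, abs=0.005)

    def test_zero_pairs_rejected(self):
        with pytest.raises(ParameterError):
            normalize_score(-1.0, 0)


class TestBackground:
    def test_zero_potential_gives_zero_moments(self, dimer, zero_potential):
        iface = find_contacts(dimer.structure, 4)
        bg = background_distribution(iface, zero_potential, 200, seed=0)
        assert bg.mu == 0.0 and bg.sigma == 0.0

    def test_single_type_composition_degenerates_to_native(
        self, random_potential
    ):
        fix = make_complex(FixtureSpec(seed=8, composition={"W": 1.0}))
        iface = find_contacts(fix.structure, 4)
        bg = background_distribution(iface, random_potential, 500, seed=1,
                                     composition={"W": 1.0})
        S, _ = raw_score(iface, random_potential)
        assert bg.sigma == 0.0
        assert bg.mu == pytest.approx(S, abs=1e-9)

    def test_seed_reproducibility_and_mc_error(self, dimer, random_potential):
        iface = find_contacts(dimer.structure, 4)
        bg1 = background_distribution(iface, random_potential, 10_000, seed=1)
        bg1b = background_distribution(iface, random_potential, 10_000, seed=1)
        assert (bg1.mu, bg1.sigma) == (bg1b.mu, bg1b.sigma)
        bg2 = background_distribution(iface, random_potential, 10_000, seed=2)
        # independent Monte-Carlo runs agree within 3 standard errors
        se = 3 * max(bg1.sigma, bg2.sigma) / np.sqrt(10_000)
        assert abs(bg1.mu - bg2.mu) <= 2 * se

    def test_too_few_samples_rejected(self, dimer, zero_potential):
        iface = find_contacts(dimer.structure, 4)
        with pytest.raises(ParameterError):
            background_distribution(iface, zero_potential, 10)


class TestZScore:
    @pytest.mark.parametrize("S,expected", [(5.0, 0.0), (3.0, 1.0), (9.0, -2.0)])
    def test_sign_convention(self, S, expected):
        bg = BackgroundDistribution(mu=5.0, sigma=2.0, n_samples=100, seed=0)
        assert z_score(S, bg) == pytest.approx(expected)

    def test_degenerate_background_raises(self):
        bg = BackgroundDistribution(mu=0.0, sigma=0.0, n_samples=100, seed=0)
        with pytest.raises(DegenerateBackgroundError, match="sigma"):
            z_score(1.0, bg)


class TestClassify:
    @pytest.mark.parametrize(
        "Z,expected",
        [(2.40, BINDER), (1.5, BINDER), (1.49, NON_BINDER), (0.0, NON_BINDER)],
    )
    def test_cutoff_at_4A(self, Z, expected):
        assert classify(Z, 4) == expected


class TestScoreComplex:
    def test_dimer_whole_equals_single_interface(self, dimer, random_potential):
        rep = score_complex(dimer.structure, random_potential,
                            n_samples=1000, seed=0)
        assert list(rep.per_interface) == ["A:B"]
        sub = rep.per_interface["A:B"]
        assert rep.N == sub.N
        assert rep.S == pytest.approx(sub.S, abs=1e-9)

    def test_trimer_pairs_sum_over_interfaces(self, random_potential):
        fix = make_complex(FixtureSpec(n_chains=3, seed=12))
        rep = score_complex(fix.structure, random_potential,
                            n_samples=1000, seed=0)
        assert set(rep.per_interface) == {"A:B", "B:C"}
        assert rep.N == sum(r.N for r in rep.per_interface.values())
        assert rep.S == pytest.approx(
            sum(r.S for r in rep.per_interface.values()), abs=1e-9
        )

    def test_same_seed_gives_identical_report(self, dimer, random_potential):
        r1 = score_complex(dimer.structure, random_potential,
                           n_samples=500, seed=3)
        r2 = score_complex(dimer.structure, random_potential,
                           n_samples=500, seed=3)
        assert r1.summary_dict() == r2.summary_dict()

    def test_z_invariant_under_weight_rescaling(self, dimer, random_potential):
        rep = score_complex(dimer.structure, random_potential,
                            n_samples=2000, seed=5)
        scaled = Potential(
            w={m: 3.0 * random_potential.w[m] for m in MODES},
            g=random_potential.g, kappa=random_potential.kappa,
        )
        rep_scaled = score_complex(dimer.structure, scaled,
                                   n_samples=2000, seed=5)
        assert rep_scaled.Z == pytest.approx(rep.Z, rel=1e-9)

    def test_invariant_under_rigid_motion(self, dimer, random_potential, tmp_path):
        # rotate + translate the PDB text through gemmi-free arithmetic:
        # re-parse, transform coordinates, rebuild, rescore
        from ppiscore.structure import Chain, Structure

        rng = np.random.default_rng(7)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        t = rng.normal(scale=15.0, size=3)
        s = dimer.structure
        moved = Structure(
            s.id,
            [
                Chain(
                    c.chain_id,
                    [
                        Residue(
                            r.chain_id, r.seq_id, r.icode, r.aa,
                            [Atom(a.name, a.element, q @ a.coord + t,
                                  a.is_backbone) for a in r.atoms],
                        )
                        for r in c.residues
                    ],
                )
                for c in s.chains
            ],
        )
        r1 = score_complex(s, random_potential, n_samples=500, seed=2)
        r2 = score_complex(moved, random_potential, n_samples=500, seed=2)
        assert r2.S == pytest.approx(r1.S, abs=1e-9)
        assert r2.Z == pytest.approx(r1.Z, abs=1e-6)

    def test_no_interface_raises(self, random_potential):
        fix = make_complex(FixtureSpec(seed=1, inter_chain_gap=10.0))
        with pytest.raises(NoInterfaceError):
            score_complex(fix.structure, random_potential, n_samples=200)

    def test_classification_flips_with_planted_enrichment(self):
        """Stronger planted favourable composition raises Z monotonically
        past the 1.5 cutoff."""
        import warnings as _w

        from ppiscore.potential import derive_potential
        from ppiscore.synth import make_corpus

        comp = {aa: 0.25 for aa in "DEKR"}
        favourable = [("E", "R", "SS", 3.0), ("D", "K", "SS", 3.0)]
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            pot = derive_potential(
                make_corpus(
                    FixtureSpec(chain_lengths=[24, 24], composition=comp,
                                planted_enrichments=favourable),
                    120, seed=21,
                ),
                d=4,
            )
        z_values = []
        for fold in (1.0, 2.0, 3.0):
            planted = [(a, b, m, fold) for a, b, m, _ in favourable]
            fix = make_complex(
                FixtureSpec(seed=31, chain_lengths=[20, 20], composition=comp,
                            planted_enrichments=planted),
            )
            rep = score_complex(fix.structure, pot, n_samples=3000, seed=4)
            z_values.append(rep.Z)
        assert z_values[0] < 1.5 <= z_values[-1]
        assert z_values == sorted(z_values)
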