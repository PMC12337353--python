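import numpy as np
import pytest

from panlv import (
    Characteristics,
    CommunityState,
    GlobalExtinctionError,
    SimParams,
    build_interaction,
    build_space,
    demographic_step,
    hgt_step_bacteria,
    hgt_step_phage,
    per_capita_fitness,
    regulate,
    run,
)
from panlv.stochastic_dynamics import sample_gene_transfers


@pytest.fixture(scope="module")
def space10():
    return build_space(10, 2)


def uniform_state(space, n_per_strain, t=0.0):
    K = space.K
    return CommunityState(
        B=np.full(K, n_per_strain), V=np.full(K, n_per_strain), t=t
    )


class TestSimParams:
    def test_ratio_parameterization(self):
        p = SimParams(NB_target=1000, s=4e-3, rho_s=2.0, r=1e-3, rho_r=0.5, rho_n=2.0)
        assert p.omega == pytest.approx(8e-3)
        assert p.rB == pytest.approx(1e-3)
        assert p.rV == pytest.approx(5e-4)
        assert p.NV_target == 2000

    def test_direct_fields_win(self):
        p = SimParams(NB_target=1000, omega=1e-2, rV=3e-4, NV_target=500, rB=1e-3)
        assert p.omega == 1e-2 and p.rV == 3e-4 and p.NV_target == 500

    def test_dt_bound_enforced(self):
        with pytest.raises(ValueError):
            SimParams(NB_target=1000, s=0.05, dt=3.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            SimParams(NB_target=1000, rB=-1e-3)

    def test_bad_phage_mode(self):
        with pytest.raises(ValueError):
            SimParams(NB_target=1000, phage_hgt_mode="sideways")

    def test_characteristics(self):
        p = SimParams(NB_target=900, NV_target=1800)
        ch = Characteristics.from_params(p, K=45)
        assert ch.n_B_star == pytest.approx(20.0)
        assert ch.n_V_star == pytest.approx(40.0)


class TestPerCapitaFitness:
    def test_fixed_points(self, space10):
        p = SimParams(NB_target=4500, NV_target=4500)
        M = build_interaction(space10, "matched")
        st = uniform_state(space10, 100)  # = n* exactly
        fB, fV = per_capita_fitness(st, p, M)
        assert np.allclose(fB, 0.0)
        assert np.allclose(fV, 0.0)

    def test_no_phage_gives_pure_growth(self, space10):
        p = SimParams(NB_target=4500, s=5e-3)
        M = build_interaction(space10, "matched")
        st = CommunityState(B=np.full(45, 100), V=np.zeros(45))
        fB, _ = per_capita_fitness(st, p, M)
        assert np.allclose(fB, p.s)

    def test_signs_off_fixed_point(self, space10):
        p = SimParams(NB_target=4500)
        M = build_interaction(space10, "matched")
        B = np.full(45, 100)
        V = np.full(45, 100)
        V[0] = 300  # overloaded bacterium
        B[1] = 300  # abundant host for phage 1
        st = CommunityState(B=B, V=V)
        fB, fV = per_capita_fitness(st, p, M)
        assert fB[0] < 0 and fV[1] > 0


class TestDemographicStep:
    def test_zero_fitness_zero_drift(self, rng, space10):
        st = uniform_state(space10, 200)
        zeros = np.zeros(45)
        n_rep = 1000
        deltas = np.empty(n_rep)
        for i in range(n_rep):
            out = demographic_step(st, zeros, zeros, 1.0, rng)
            deltas[i] = out.B.sum() - st.B.sum()
        # total variance ~ turnover * 2 * N per step
        sigma = np.sqrt(2 * 0.5 * st.B.sum() / n_rep)
        assert abs(deltas.mean()) < 3 * sigma

    def test_extinct_strain_gets_no_events(self, rng, space10):
        st = uniform_state(space10, 50)
        st.B[3] = 0
        f = np.full(45, 0.01)
        for _ in range(50):
            out = demographic_step(st, f, f, 1.0, rng)
            assert out.B[3] == 0
            st = CommunityState(B=out.B, V=out.V)
            st.B[3] = 0  # keep others evolving, strain 3 must stay 0 anyway

    def test_exponential_mean_growth(self, rng):
        # single strain, constant fitness s, no phage: mean ~ e^{st}
        space = build_space(2, 2)
        s, t_total = 0.01, 150
        n0 = 200
        n_rep = 400
        finals = np.empty(n_rep)
        f = np.array([s])
        for i in range(n_rep):
            st = CommunityState(B=np.array([n0]), V=np.array([n0]))
            for _ in range(t_total):
                st = demographic_step(st, f, np.zeros(1), 1.0, rng)
            finals[i] = st.B[0]
        expected = n0 * np.exp(s * t_total)
        sem = finals.std() / np.sqrt(n_rep)
        # allow the O(s^2 t) discretization bias of the per-generation leap
        assert abs(finals.mean() - expected) < 3 * sem + 0.01 * expected

    def test_nonnegative(self, rng, space10):
        st = uniform_state(space10, 2)
        f = np.full(45, -0.09)
        for _ in range(200):
            st = demographic_step(st, f, f, 1.0, rng)
            assert (st.B >= 0).all() and (st.V >= 0).all()


class TestRegulate:
    def test_already_on_target_unchanged(self, rng, space10):
        p = SimParams(NB_target=4500, NV_target=4500)
        st = uniform_state(space10, 100)
        out = regulate(st, p, rng)
        assert (out.B == st.B).all() and (out.V == st.V).all()

    def test_exact_totals(self, rng, space10):
        p = SimParams(NB_target=4500, NV_target=9000)
        st = uniform_state(space10, 117)
        out = regulate(st, p, rng)
        assert out.B.sum() == 4500 and out.V.sum() == 9000

    def test_frequency_preservation(self, rng):
        # two strains at 60/40, removal of 10 out of 100: frequencies kept
        space = build_space(3, 2)
        p = SimParams(NB_target=90, NV_target=90)
        n_rep = 1000
        fracs = np.empty(n_rep)
        for i in range(n_rep):
            st = CommunityState(B=np.array([60, 40, 0]), V=np.array([30, 30, 30]))
            out = regulate(st, p, rng)
            fracs[i] = out.B[0] / out.B.sum()
        sigma = np.sqrt(0.6 * 0.4 / 90 / n_rep)  # generous binomial scale
        assert abs(fracs.mean() - 0.6) < 3 * sigma + 0.005

    def test_zero_strain_never_gains(self, rng):
        space = build_space(3, 2)
        p = SimParams(NB_target=200, NV_target=200)
        for _ in range(100):
            st = CommunityState(B=np.array([90, 60, 0]), V=np.array([100, 50, 0]))
            out = regulate(st, p, rng)
            assert out.B[2] == 0 and out.V[2] == 0

    def test_global_extinction_raises(self, rng, space10):
        p = SimParams(NB_target=4500)
        st = CommunityState(B=np.zeros(45), V=np.full(45, 10))
        with pytest.raises(GlobalExtinctionError):
            regulate(st, p, rng)


class TestHgtSteps:
    def test_rate_zero_is_identity(self, rng, space10):
        p = SimParams(NB_target=4500, rB=0.0, rV=0.0)
        st = uniform_state(space10, 100)
        out = hgt_step_bacteria(st, p, space10, 1.0, rng)
        assert out.B is st.B
        out = hgt_step_phage(st, p, space10, 1.0, rng)
        assert out.V is st.V

    def test_mode_off_is_identity(self, rng, space10):
        p = SimParams(NB_target=4500, rV=1e-2, phage_hgt_mode="off")
        st = uniform_state(space10, 100)
        out = hgt_step_phage(st, p, space10, 1.0, rng)
        assert out.V is st.V

    def test_total_conserved(self, rng, space10):
        p = SimParams(NB_target=4500, r=5e-2)
        st = uniform_state(space10, 100)
        for _ in range(20):
            st = hgt_step_bacteria(st, p, space10, 1.0, rng)
            st = hgt_step_phage(st, p, space10, 1.0, rng)
            assert st.B.sum() == 4500 and st.V.sum() == 4500
            assert (st.B >= 0).all() and (st.V >= 0).all()

    def test_directed_transfer_example(self, rng):
        # recipient CD + gene B from donor AB (replacing C) -> one CD moves to BD
        space = build_space(4, 2)
        cd = space.index_of[(2, 3)]
        ab = space.index_of[(0, 1)]
        bd = space.index_of[(1, 3)]
        rec = np.array([cd])
        prod = space.hgt_product_index(rec, np.array([0]), np.array([1]))
        assert prod[0] == bd
        from panlv.stochastic_dynamics import _apply_moves

        B = np.zeros(space.K, dtype=np.int64)
        B[cd], B[ab] = 5, 5
        out = _apply_moves(B, rec, prod)
        assert out[cd] == 4 and out[bd] == 1 and out.sum() == 10

    def test_transfer_event_rate(self, rng):
        # expected transfers per unit time = r * N; with mass on AB and CD
        # only, every transfer lands in an empty genotype and is countable
        space = build_space(4, 2)
        N = 4500
        B = np.zeros(space.K, dtype=np.int64)
        B[space.index_of[(0, 1)]] = N // 2
        B[space.index_of[(2, 3)]] = N // 2
        p = SimParams(NB_target=N, r=2e-2)
        lam = p.rB * N * 1.0
        moved = []
        st = CommunityState(B=B, V=B.copy())
        for _ in range(500):
            out = hgt_step_bacteria(st, p, space, 1.0, rng)
            delta = out.B - st.B
            moved.append(delta[delta > 0].sum())
        sigma = np.sqrt(lam / 500)
        assert abs(np.mean(moved) - lam) < 3 * sigma

    def test_reappearance_probability_matches_enumeration(self, rng):
        # L=3, AB extinct, B = [0 AB, 10 AC, 5 BC]: per attempted transfer,
        # P(product == AB) = 1/9 by exhaustive enumeration of
        # (recipient, donor, gene, slot) combinations
        space = build_space(3, 2)
        B = np.array([0, 10, 5], dtype=np.int64)
        n = 40_000
        rec, prod = sample_gene_transfers(space, B, B, n, rng, collision="noop")
        p_hat = (prod == space.index_of[(0, 1)]).mean()
        expected = 1.0 / 9.0
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert abs(p_hat - expected) < 3 * sigma

    def test_interphage_donors_are_phages(self, rng):
        # bacterial gene pool lacks gene 0 entirely; interphage transfer can
        # still spread it among phages, from_bacteria cannot
        space = build_space(4, 2)
        V = np.full(space.K, 50, dtype=np.int64)
        B = np.zeros(space.K, dtype=np.int64)
        for k, (i, j) in enumerate(space.genotypes):
            if 0 not in (i, j):
                B[k] = 100
        n = 2000
        rec_ip, prod_ip = sample_gene_transfers(space, V, V, n, rng)
        rec_fb, prod_fb = sample_gene_transfers(space, V, B, n, rng)
        has0 = space.membership[:, 0].astype(bool)
        ok_ip = prod_ip >= 0
        ok_fb = prod_fb >= 0
        # phage donors can hand gene 0 to recipients lacking it ...
        assert (has0[prod_ip[ok_ip]] & ~has0[rec_ip[ok_ip]]).any()
        # ... bacterial donors (lacking gene 0 entirely) never can
        assert not (has0[prod_fb[ok_fb]] & ~has0[rec_fb[ok_fb]]).any()


class TestRun:
    def test_bit_identical_reproducibility(self, space10):
        p = SimParams(NB_target=2000, r=2e-3, T=300, seed=77)
        a = run(p, space10)
        b = run(p, space10)
        assert (a.B == b.B).all() and (a.V == b.V).all()
        assert (a.times == b.times).all()
        assert a.termination == b.termination
        assert (a.first_zero_B == b.first_zero_B).all()

    def test_conservation_every_sample(self, space10):
        p = SimParams(NB_target=2000, NV_target=3000, r=5e-3, T=500, seed=3)
        traj = run(p, space10)
        assert (traj.B.sum(axis=1) == 2000).all()
        assert (traj.V.sum(axis=1) == 3000).all()

    def test_gene_loss_absorbing(self, space10):
        # no mutation: once a bacterial gene is gone it stays gone
        p = SimParams(NB_target=300, r=2e-3, T=4000, seed=11)
        traj = run(p, space10)
        lost = np.isfinite(traj.gene_first_zero_B)
        assert lost.any()  # N < K guarantees early losses
        for ell in np.flatnonzero(lost):
            t0 = traj.gene_first_zero_B[ell]
            after = traj.times >= t0
            assert (traj.gene_B[after, ell] == 0).all()

    def test_genotype_loss_not_absorbing_with_hgt(self, space10):
        p = SimParams(NB_target=2000, r=1e-2, T=4000, seed=19)
        traj = run(p, space10)
        # some genotype hit zero and was later seen positive again
        revived = False
        for k in np.flatnonzero(np.isfinite(traj.first_zero_B)):
            t0 = traj.first_zero_B[k]
            if (traj.B[traj.times > t0, k] > 0).any():
                revived = True
                break
        assert revived

    def test_uniform_init_distributes_remainder(self, space10):
        p = SimParams(NB_target=4500 + 7, T=1, seed=2)
        traj = run(p, space10)
        assert traj.B[0].sum() == 4507
        assert traj.B[0].min() >= 100 and traj.B[0].max() <= 102

    def test_stop_on_first_gene_loss(self, space10):
        p = SimParams(NB_target=300, r=0.0, T=50_000, seed=23)
        traj = run(p, space10, stop_when="first_gene_loss")
        assert traj.termination in ("first_gene_loss", "global_extinction_bacteria",
                                    "global_extinction_phage")
        if traj.termination == "first_gene_loss":
            assert traj.t_end == traj.gene_first_zero_B.min()
            assert traj.t_end < 50_000

    def test_global_extinction_recorded_not_raised(self):
        space = build_space(2, 2)
        p = SimParams(
            NB_target=30, NV_target=30, T=50_000, seed=1,
            regulate_populations=False,
        )
        traj = run(p, space)
        assert traj.termination.startswith("global_extinction")
        assert traj.t_end < 50_000

    def test_small_N_warns(self, space10):
        p = SimParams(NB_target=10, T=1, seed=0)
        with pytest.warns(UserWarning):
            run(p, space10)

    def test_wright_fisher_fixation_small(self):
        # no phage, no HGT: fixation probability ~ initial frequency
        space = build_space(3, 2)
        N = 300
        init_counts = np.array([180, 120, 0])
        fixed_first = 0
        n_rep = 60
        for seed in range(n_rep):
            p = SimParams(
                NB_target=N, NV_target=N, r=0.0, T=100_000, seed=seed,
            )
            init = CommunityState(B=init_counts.copy(), V=np.full(3, 100))
            # V plays no role: kill phage influence by zeroing omega coupling
            init.V[:] = 0
            traj = run(p, space, init=init, stop_when="bacterial_fixation")
            assert traj.termination == "bacterial_fixation"
            winner = int(np.argmax(traj.B[-1]))
            fixed_first += winner == 0
        p_hat = fixed_first / n_rep
        sigma = np.sqrt(0.6 * 0.4 / n_rep)
        assert abs(p_hat - 0.6) < 3 * sigma


class TestPermutationEquivariance:
    def test_relabeled_runs_statistically_indistinguishable(self):
        # relabeling genes (and permuting the init accordingly) must leave
        # summary distributions unchanged; matched seeds not required
        from scipy import stats as sps

        space = build_space(5, 2)
        perm = np.array([3, 0, 4, 1, 2])
        sigma = np.array(
            [
                space.index_of[tuple(sorted((perm[i], perm[j])))]
                for (i, j) in space.genotypes
            ]
        )
        base = np.tile([40, 60, 80, 100, 120], 2)
        relabeled = np.zeros_like(base)
        relabeled[sigma] = base
        pooled = {"plain": [], "relabeled": []}
        for rep in range(3):
            for tag, counts in [("plain", base), ("relabeled", relabeled)]:
                p = SimParams(
                    NB_target=800, NV_target=800, r=5e-3, T=5000,
                    seed=100 * rep + (7 if tag == "plain" else 8),
                    record_every=250,  # >= 1/s so snapshots decorrelate
                )
                init = CommunityState(B=counts.copy(), V=counts.copy())
                traj = run(p, space, init=init)
                burn = traj.times > 1000
                pooled[tag].append(traj.B[burn].ravel())
        ks = sps.ks_2samp(
            np.concatenate(pooled["plain"]), np.concatenate(pooled["relabeled"])
        )
        assert ks.pvalue > 1e-3


class TestMeanDynamicsMatchDeterministic:
    def test_one_step_expected_change(self, rng, space10):
        # E[dB] = fB * B * dt for one step, matching the deterministic
        # right-hand side of the pair dynamics to O(dt^2)
        p = SimParams(NB_target=4500, NV_target=4500)
        M = build_interaction(space10, "matched")
        B = rng.integers(50, 150, size=45)
        V = rng.integers(50, 150, size=45)
        st = CommunityState(B=B, V=V)
        fB, fV = per_capita_fitness(st, p, M)
        n_rep = 3000
        dB = np.zeros(45)
        for _ in range(n_rep):
            out = demographic_step(st, fB, fV, 1.0, rng)
            dB += out.B - st.B
        dB /= n_rep
        expected = fB * st.B
        scale = np.sqrt((2 * 0.5 + np.abs(fB)) * st.B / n_rep)
        assert (np.abs(dB - expected) < 4 * scale + 0.02).all()
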