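"""Life-cycle phases: fitness, reproduction, competition, dispersal,
immigration — unit behaviour plus per-individual oracle equivalence.

The package implements count-aggregated dynamics (Poisson/binomial/
multinomial draws per (patch, species) pair).  The oracle functions here
simulate every individual literally, one random draw per organism, and the
equivalence tests check that both implementations agree in mean and
variance over thousands of replicate draws on small fixed states.
"""

import math

import numpy as np
import pytest
from scipy import stats

from heteroscape import (
    DemographicParams,
    ImmigrantTraitConfig,
    SpeciesRegistry,
    compete,
    disperse,
    expected_fertility,
    immigrate,
    reproduce,
    survival_probability,
)
from heteroscape.lifecycle import MOORE_OFFSETS


def _arr(*vals, dtype=np.int64):
    return np.array(vals, dtype=dtype)


# ---------------------------------------------------------------------------
# Fitness (expected fecundity)
# ---------------------------------------------------------------------------


class TestExpectedFertility:
    def test_perfect_specialist_approaches_r0(self, registry, params):
        sid = registry.add_species(t_opt=0.3, t_tol=1e-6, h_opt=-0.2, h_tol=1e-6)
        fert = expected_fertility(registry[sid], 0.3, -0.2, params)
        assert fert == pytest.approx(15.0, rel=1e-9)

    def test_mismatch_equal_to_tolerance_costs_factor_e(self, registry, params):
        """(t_eff - t_opt) = t_tol multiplies fecundity by exactly e^-1."""
        sid = registry.add_species(t_opt=0.0, t_tol=0.8, h_opt=0.0, h_tol=1.3)
        matched = expected_fertility(registry[sid], 0.0, 0.0, params)
        mismatched = expected_fertility(registry[sid], 0.8, 0.0, params)
        assert mismatched / matched == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_unit_mismatch_unit_tolerance_value(self, registry, params):
        """Direct evaluation: 15 * e^-1 * e^(-1/18) * e^(-1/18)."""
        sid = registry.add_species(t_opt=0.0, t_tol=1.0, h_opt=0.5, h_tol=1.0)
        fert = expected_fertility(registry[sid], 1.0, 0.5, params)
        assert fert == pytest.approx(15.0 * math.exp(-1.0 - 1.0 / 9.0), rel=1e-12)
        assert fert == pytest.approx(4.938, abs=5e-4)

    def test_fertility_bounded_by_r0(self, registry, params):
        rng = np.random.default_rng(3)
        ids = registry.draw_initial_traits(1.0, rng, n=200)
        for sid in ids[:50]:
            f = expected_fertility(registry[int(sid)], 0.4, -1.0, params)
            assert 0.0 < f <= params.r0

    def test_non_positive_tolerance_rejected(self, params):
        with pytest.raises(ValueError):
            DemographicParams(r0=15, k=150, alpha=-1)


# ---------------------------------------------------------------------------
# Beverton–Holt survival
# ---------------------------------------------------------------------------


class TestSurvival:
    def test_no_competition_means_certain_survival(self, params):
        assert survival_probability(0, params) == 1.0

    def test_survivors_equal_k_at_full_offspring_pool(self, params):
        """At L0 = R0*K = 2250 survival is 1/15, so E[survivors] = K = 150."""
        l0 = params.r0 * params.k
        s = survival_probability(l0, params)
        assert s == pytest.approx(1.0 / 15.0, rel=1e-12)
        assert l0 * s == pytest.approx(150.0, rel=1e-12)

    def test_expected_survivors_saturate_at_inverse_a(self, params):
        l0 = 1e12
        assert l0 * survival_probability(l0, params) == pytest.approx(
            1.0 / params.a, rel=1e-6
        )
        assert 1.0 / params.a == pytest.approx(2250.0 / 14.0, rel=1e-12)

    def test_monotone_decreasing_in_l0(self, params):
        l0 = np.arange(0, 5000, 50)
        s = survival_probability(l0, params)
        assert np.all(np.diff(s) < 0)

    def test_negative_l0_rejected(self, params):
        with pytest.raises(ValueError):
            survival_probability(-1, params)


# ---------------------------------------------------------------------------
# Reproduction
# ---------------------------------------------------------------------------


class TestReproduce:
    def test_empty_patch_stays_empty(self, registry, params, rng):
        empty = np.empty(0, dtype=np.int64)
        env = np.zeros(4)
        p, s, c = reproduce(empty, empty, empty, registry, env, env, params, rng)
        assert len(p) == 0

    def test_offspring_mean_matches_poisson_aggregation(self, registry, params):
        """150 parents with fecundity f leave ~Poisson(150 f) offspring."""
        sid = registry.add_species(t_opt=0.0, t_tol=1.0, h_opt=0.0, h_tol=1.0)
        fert = expected_fertility(registry[sid], 0.0, 0.0, params)
        env = np.zeros(1)
        rng = np.random.default_rng(11)
        totals = []
        for _ in range(1000):
            _, _, c = reproduce(
                _arr(0), _arr(sid), _arr(150), registry, env, env, params, rng
            )
            totals.append(c.sum())
        expected = 150 * fert
        se = math.sqrt(expected / 1000)
        assert np.mean(totals) == pytest.approx(expected, abs=4 * se)

    def test_hopeless_maladaptation_yields_no_offspring(self, registry, params, rng):
        sid = registry.add_species(t_opt=100.0, t_tol=0.1)
        env = np.zeros(1)
        _, _, c = reproduce(
            _arr(0), _arr(sid), _arr(1000), registry, env, env, params, rng
        )
        assert c.sum() == 0


# ---------------------------------------------------------------------------
# Competition
# ---------------------------------------------------------------------------


class TestCompete:
    def test_empty_pool(self, params, rng):
        empty = np.empty(0, dtype=np.int64)
        p, s, c = compete(empty, empty, empty, params, 4, rng)
        assert len(p) == 0

    def test_single_species_regulated_to_k(self, params):
        """A full offspring pool L0 = 2250 leaves on average K = 150 survivors."""
        rng = np.random.default_rng(5)
        totals = [
            compete(_arr(0), _arr(0), _arr(2250), params, 1, rng)[2].sum()
            for _ in range(1000)
        ]
        se = math.sqrt(2250 * (1 / 15) * (14 / 15) / 1000)
        assert np.mean(totals) == pytest.approx(150.0, abs=4 * se)

    def test_species_survive_in_proportion_to_offspring(self, params):
        """Equal survival probability: a 2:1 offspring ratio stays 2:1."""
        rng = np.random.default_rng(6)
        tot_a, tot_b = 0, 0
        for _ in range(1000):
            p, s, c = compete(
                _arr(0, 0), _arr(0, 1), _arr(1500, 750), params, 1, rng
            )
            cmap = dict(zip(s.tolist(), c.tolist()))
            tot_a += cmap.get(0, 0)
            tot_b += cmap.get(1, 0)
        # p = 1/(1 + a*2250) = 1/15: E_A = 100, E_B = 50 per draw
        assert tot_a / 1000 == pytest.approx(100.0, rel=0.05)
        assert tot_b / 1000 == pytest.approx(50.0, rel=0.05)

    def test_survivor_species_subset_of_offspring(self, params, rng):
        p, s, c = compete(
            np.zeros(30, dtype=np.int64),
            np.arange(30, dtype=np.int64),
            np.full(30, 200, dtype=np.int64),
            params,
            1,
            rng,
        )
        assert set(s.tolist()) <= set(range(30))
        assert np.all(c >= 1)

    def test_patches_compete_independently(self, params, rng):
        """L0 is per patch: a crowded patch does not suppress an empty one."""
        p, s, c = compete(
            _arr(0, 1), _arr(0, 1), _arr(100000, 10), params, 2, rng
        )
        cmap = dict(zip(p.tolist(), c.tolist()))
        assert cmap.get(1, 0) >= 8  # patch 1 has L0=10, survival ~0.94


# ---------------------------------------------------------------------------
# Dispersal
# ---------------------------------------------------------------------------


class TestDisperse:
    def test_sedentary_species_never_move(self, registry, rng):
        sid = registry.add_species(p_disp=0.0)
        p, s, c = disperse(
            _arr(7), _arr(sid), _arr(500), registry, 20, 20, rng
        )
        assert p.tolist() == [7] and c.tolist() == [500]

    def test_population_conserved(self, registry, rng):
        ids = [
            registry.add_species(p_disp=pd, p_global=pg)
            for pd, pg in [(0.3, 0.5), (1.0, 1.0), (0.9, 0.0)]
        ]
        patch = _arr(0, 5, 399)
        counts = _arr(1000, 2000, 3000)
        p, s, c = disperse(patch, _arr(*ids), counts, registry, 20, 20, rng)
        assert c.sum() == 6000
        assert np.all(c >= 1)

    def test_neighbour_targets_uniform_over_moore_neighbourhood(self, registry):
        """80,000 forced nearest-neighbour dispersers from one corner patch
        spread 1/8 each over the 8 toroidally wrapped neighbours."""
        sid = registry.add_species(p_disp=1.0, p_global=0.0)
        rng = np.random.default_rng(13)
        p, s, c = disperse(_arr(0), _arr(sid), _arr(80_000), registry, 20, 20, rng)
        landed = dict(zip(p.tolist(), c.tolist()))
        expected_targets = {
            int(((0 + dy) % 20) * 20 + (0 + dx) % 20) for dx, dy in MOORE_OFFSETS
        }
        assert set(landed) == expected_targets
        assert 19 * 20 + 19 in landed  # offset (-1,-1) wraps to (19,19)
        chi = stats.chisquare(list(landed.values()))
        assert chi.pvalue > 0.001

    def test_global_targets_never_natal_and_roughly_uniform(self, registry):
        sid = registry.add_species(p_disp=1.0, p_global=1.0)
        rng = np.random.default_rng(17)
        natal = 5 * 20 + 5
        p, s, c = disperse(
            _arr(natal), _arr(sid), _arr(79_800), registry, 20, 20, rng
        )
        landed = dict(zip(p.tolist(), c.tolist()))
        assert natal not in landed
        assert len(landed) == 399
        chi = stats.chisquare(list(landed.values()))
        assert chi.pvalue > 0.001

    def test_dispersal_probability_splits_binomially(self, registry):
        sid = registry.add_species(p_disp=0.25, p_global=0.0)
        rng = np.random.default_rng(19)
        stayed = []
        for _ in range(500):
            p, s, c = disperse(_arr(0), _arr(sid), _arr(400), registry, 20, 20, rng)
            stayed.append(dict(zip(p.tolist(), c.tolist())).get(0, 0))
        se = math.sqrt(400 * 0.25 * 0.75 / 500)
        assert np.mean(stayed) == pytest.approx(300.0, abs=4 * se)


# ---------------------------------------------------------------------------
# Immigration
# ---------------------------------------------------------------------------


class TestImmigrate:
    def test_zero_rate_means_no_immigrants(self, registry, rng):
        cfg = ImmigrantTraitConfig(e_immi=0.0)
        p, s, c = immigrate(400, 0.3, cfg, registry, rng)
        assert len(p) == 0 and registry.n_species == 0

    def test_mean_arrivals_per_patch(self, registry):
        """Poisson(2.5) per patch: mean over 400 patches x 50 steps."""
        cfg = ImmigrantTraitConfig()
        rng = np.random.default_rng(23)
        total = 0
        for _ in range(50):
            p, s, c = immigrate(400, 0.3, cfg, registry, rng)
            assert np.all(c == 1)
            total += len(p)
        per_patch_step = total / (400 * 50)
        se = math.sqrt(2.5 / (400 * 50))
        assert per_patch_step == pytest.approx(2.5, abs=4 * se)

    def test_every_immigrant_founds_a_new_species(self, registry, rng):
        cfg = ImmigrantTraitConfig()
        before = registry.draw_initial_traits(1.0, rng, n=5)
        p, s, c = immigrate(100, 1.0, cfg, registry, rng)
        assert len(np.intersect1d(s, before)) == 0
        assert len(np.unique(s)) == len(s)
        assert registry.n_species == 5 + len(s)


# ---------------------------------------------------------------------------
# Per-individual oracle equivalence
# ---------------------------------------------------------------------------


def indiv_reproduce(counts: dict, ferts: dict, rng) -> dict:
    """One Poisson draw per parent, literally."""
    out = {}
    for sid, n in counts.items():
        total = int(rng.poisson(ferts[sid], size=n).sum())
        if total:
            out[sid] = total
    return out


def indiv_compete(counts: dict, params, rng) -> dict:
    """One Bernoulli trial per offspring with the shared survival probability."""
    l0 = sum(counts.values())
    p = float(survival_probability(l0, params))
    out = {}
    for sid, n in counts.items():
        surv = int((rng.random(n) < p).sum())
        if surv:
            out[sid] = surv
    return out


def indiv_disperse_from_patch(n: int, natal: int, p_disp, p_global, width, height, rng):
    """Literal per-individual dispersal from one patch; returns patch->count."""
    out: dict[int, int] = {}
    x, y = natal % width, natal // width
    n_patches = width * height
    for _ in range(n):
        if rng.random() > p_disp:
            target = natal
        elif rng.random() <= p_global:
            target = natal
            while target == natal:
                target = int(rng.integers(0, n_patches))
        else:
            dx, dy = 0, 0
            while (dx, dy) == (0, 0):
                dx = int(rng.integers(-1, 2))
                dy = int(rng.integers(-1, 2))
            target = ((y + dy) % height) * width + (x + dx) % width
        out[target] = out.get(target, 0) + 1
    return out


N_REPS = 1500


def _moments(samples: list[float]) -> tuple[float, float]:
    a = np.asarray(samples, dtype=float)
    return a.mean(), a.var(ddof=1)


def test_aggregated_reproduction_matches_individual_oracle(registry, params):
    """Count-aggregated Poisson reproduction equals per-parent draws in
    mean and variance (both are Poisson(n*E_fert) exactly)."""
    sid_a = registry.add_species(t_opt=0.0, t_tol=1.0)
    sid_b = registry.add_species(t_opt=0.5, t_tol=0.7)
    counts = {sid_a: 40, sid_b: 25}
    ferts = {
        sid: expected_fertility(registry[sid], 0.2, 0.0, params)
        for sid in counts
    }
    env_t, env_h = np.array([0.2]), np.array([0.0])
    rng_agg = np.random.default_rng(101)
    rng_ind = np.random.default_rng(202)
    agg, ind = [], []
    patch = np.zeros(2, dtype=np.int64)
    species = _arr(sid_a, sid_b)
    nvec = _arr(40, 25)
    for _ in range(N_REPS):
        _, _, c = reproduce(
            patch, species, nvec, registry, env_t, env_h, params, rng_agg
        )
        agg.append(c.sum())
        ind.append(sum(indiv_reproduce(counts, ferts, rng_ind).values()))
    m_a, v_a = _moments(agg)
    m_i, v_i = _moments(ind)
    exp_mean = sum(n * ferts[s] for s, n in counts.items())
    se_mean = math.sqrt(exp_mean / N_REPS)
    assert m_a == pytest.approx(m_i, abs=6 * se_mean)
    assert v_a == pytest.approx(v_i, rel=0.25)


def test_aggregated_competition_matches_individual_oracle(params):
    counts = {0: 900, 1: 300}
    rng_agg = np.random.default_rng(303)
    rng_ind = np.random.default_rng(404)
    patch = np.zeros(2, dtype=np.int64)
    species = _arr(0, 1)
    nvec = _arr(900, 300)
    agg, ind = [], []
    for _ in range(N_REPS):
        _, _, c = compete(patch, species, nvec, params, 1, rng_agg)
        agg.append(c.sum())
        ind.append(sum(indiv_compete(counts, params, rng_ind).values()))
    m_a, v_a = _moments(agg)
    m_i, v_i = _moments(ind)
    p = float(survival_probability(1200, params))
    se_mean = math.sqrt(1200 * p * (1 - p) / N_REPS)
    assert m_a == pytest.approx(m_i, abs=6 * se_mean)
    assert v_a == pytest.approx(v_i, rel=0.25)


def test_aggregated_dispersal_matches_individual_oracle(registry):
    """Binomial/multinomial dispersal equals literal per-individual moves:
    per-destination means and variances agree over replicate draws."""
    sid = registry.add_species(p_disp=0.6, p_global=0.3)
    natal, width, height, n = 25, 10, 10, 120
    rng_agg = np.random.default_rng(505)
    rng_ind = np.random.default_rng(606)
    agg = np.zeros((N_REPS, width * height))
    ind = np.zeros((N_REPS, width * height))
    for r in range(N_REPS):
        p, s, c = disperse(
            _arr(natal), _arr(sid), _arr(n), registry, width, height, rng_agg
        )
        agg[r, p] = c
        for tgt, cnt in indiv_disperse_from_patch(
            n, natal, 0.6, 0.3, width, height, rng_ind
        ).items():
            ind[r, tgt] = cnt
    assert np.all(agg.sum(axis=1) == n) and np.all(ind.sum(axis=1) == n)
    mean_diff = np.abs(agg.mean(axis=0) - ind.mean(axis=0))
    # worst-case per-patch SE: natal patch keeps Binomial(120, 0.4)
    se_natal = math.sqrt(n * 0.4 * 0.6 / N_REPS)
    assert mean_diff.max() < 6 * se_natal
    # variances agree at the natal patch and pooled over neighbours
    assert agg[:, natal].var() == pytest.approx(ind[:, natal].var(), rel=0.25)
    neigh = [
        ((natal // width + dy) % height) * width + (natal % width + dx) % width
        for dx, dy in MOORE_OFFSETS
    ]
    assert agg[:, neigh].var() == pytest.approx(ind[:, neigh].var(), rel=0.25)
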