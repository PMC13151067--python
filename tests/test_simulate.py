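"""Selection simulator: round update rule, sequencing, determinism."""

import numpy as np
import pytest

from macropan.simulate import (
    RESINS,
    ClonePool,
    RoundSpec,
    default_config,
    generate_naive_library,
    reads_from_counts,
    run_campaign,
    run_round,
    sample_counts,
    sequence_pool,
    write_fastq,
)

from conftest import small_config


def two_clone_pool(abundance, kd, sigma=0.0, fitness=1.0):
    n = len(abundance)
    return ClonePool(
        dna=np.array(["TGT" * 14] * n, dtype=object),
        peptides=np.array([f"P{i}" for i in range(n)], dtype=object),
        abundance=np.asarray(abundance, dtype=float),
        kd=np.asarray(kd, dtype=float),
        stickiness=np.full((n, len(RESINS)), sigma, dtype=float),
        fitness=np.full(n, fitness, dtype=float),
    )


def spec(**overrides):
    base = dict(
        strategy="s", round_index=1, resin="streptavidin", target_ug=1.0,
        washes=0, negative_selection=False, depth=1000, i5="AAAA", i7="CCCC",
    )
    base.update(overrides)
    return RoundSpec(**base)


def noise_free_config(**overrides):
    params = dict(seed=0, amp_noise_tau=0.0, c0=0.0, q_ns=0.0, target_scale=1.0)
    params.update(overrides)
    return default_config(**params)


class TestRoundUpdate:
    def test_weights_proportional_to_occupancy(self):
        """a=(0.5,0.5) with occupancies (0.9,0.1), no washes, no noise
        renormalizes to (0.9,0.1)."""
        # KD chosen so that theta = T/(T+KD) is exactly 0.9 and 0.1 at T=1
        pool = two_clone_pool([0.5, 0.5], [1 / 9, 9.0])
        out = run_round(pool, spec(), noise_free_config())
        np.testing.assert_allclose(out.abundance, [0.9, 0.1], atol=1e-12)

    def test_nonbinder_without_stickiness_elutes_nothing(self):
        pool = two_clone_pool([0.5, 0.5], [1.0, np.inf])
        out = run_round(pool, spec(), noise_free_config())
        assert out.abundance[1] == 0.0

    def test_all_nonbinders_raises_empty_elution(self):
        from macropan.simulate import EmptyElutionError

        pool = two_clone_pool([0.5, 0.5], [np.inf, np.inf])
        with pytest.raises(EmptyElutionError):
            run_round(pool, spec(), noise_free_config())

    def test_binder_frequency_strictly_increases_over_schedule(self):
        """A 100 nM binder against background rises every round under the
        10/5/2/1 target and 8/8/10/10 wash schedule (noise-free)."""
        config = default_config(seed=0, amp_noise_tau=0.0, target_scale=1.0)
        pool = two_clone_pool([1e-4] + [0.9999 / 9] * 9, [100e-9] + [np.inf] * 9)
        freqs = [pool.abundance[0]]
        for r, (t, w) in enumerate(zip([10.0, 5.0, 2.0, 1.0], [8, 8, 10, 10])):
            pool = run_round(
                pool, spec(round_index=r + 1, target_ug=t, washes=w), config
            )
            freqs.append(pool.abundance[0])
        assert all(b > a for a, b in zip(freqs, freqs[1:]))

    def test_matches_closed_form_iteration(self):
        """Noise-free multi-round frequencies equal an independent
        closed-form iteration of the update rule to 1e-12."""
        rng = np.random.default_rng(42)
        n = 50
        kd = np.where(rng.random(n) < 0.2, rng.uniform(0.1, 10, n), np.inf)
        sigma = np.where(rng.random(n) < 0.3, rng.uniform(0, 0.9, n), 0.0)
        fitness = rng.uniform(0.5, 2.0, n)
        a = rng.dirichlet(np.ones(n))
        pool = ClonePool(
            dna=np.array(["TGT" * 14] * n, dtype=object),
            peptides=np.array([f"P{i}" for i in range(n)], dtype=object),
            abundance=a.copy(),
            kd=kd,
            stickiness=np.tile(sigma[:, None], (1, len(RESINS))),
            fitness=fitness,
        )
        config = default_config(
            seed=0, amp_noise_tau=0.0, c0=0.02, q_ns=0.5, k_neg=0.7, target_scale=1.0
        )
        schedule = [(10.0, 8, True), (5.0, 8, False), (2.0, 10, True)]

        # independent oracle: plain-python iteration of the stated formulas
        expected = a.copy()
        for target, washes, neg in schedule:
            weights = []
            for i in range(n):
                theta = 0.0 if np.isinf(kd[i]) else target / (target + kd[i])
                passed = (1 - sigma[i]) ** 0.7 if neg else 1.0
                capture = 1 - (1 - theta) * (1 - sigma[i]) * (1 - 0.02)
                retention = 0.5 + 0.5 * max(theta, sigma[i])
                weights.append(
                    expected[i] * passed * capture * retention**washes * fitness[i]
                )
            weights = np.array(weights)
            expected = weights / weights.sum()

        for r, (target, washes, neg) in enumerate(schedule):
            pool = run_round(
                pool,
                spec(round_index=r + 1, target_ug=target, washes=washes,
                     negative_selection=neg),
                config,
            )
        np.testing.assert_allclose(pool.abundance, expected, atol=1e-12)

    def test_mass_conserved_and_monotone_in_kd(self):
        """Eluted weight never exceeds input weight, and a weaker binder
        never elutes more than a stronger one at equal abundance."""
        kds = [0.01, 0.1, 1.0, 10.0, np.inf]
        pool = two_clone_pool([0.2] * 5, kds)
        config = noise_free_config(q_ns=0.3, c0=0.05)
        sp = spec(washes=5)
        target = sp.target_ug
        theta = np.where(np.isfinite(pool.kd), target / (target + pool.kd), 0.0)
        capture = 1 - (1 - theta) * (1 - 0.05)
        retention = 0.3 + 0.7 * theta
        eluted = pool.abundance * capture * retention**5
        assert np.all(eluted <= pool.abundance + 1e-15)
        assert np.all(np.diff(eluted) <= 1e-15)  # sorted weakest last


class TestNaiveLibrary:
    def test_all_clones_scaffold_valid(self, schema_12mer):
        config = small_config(seed=5, n_clones=200)
        pool = generate_naive_library(config)
        assert len(pool) == 200
        assert all(p.startswith("C") and p.endswith("C") for p in pool.peptides)
        assert abs(pool.abundance.sum() - 1) < 1e-9

    def test_planted_binder_count(self):
        config = small_config(seed=5, n_clones=200)
        pool = generate_naive_library(config)
        assert int(np.isfinite(pool.kd).sum()) == config.n_binders
        lo, hi = config.binder_kd_range
        finite = pool.kd[np.isfinite(pool.kd)]
        assert np.all((finite >= lo) & (finite <= hi))

    def test_same_seed_reproduces_pool(self):
        a = generate_naive_library(small_config(seed=7))
        b = generate_naive_library(small_config(seed=7))
        assert list(a.dna) == list(b.dna)
        np.testing.assert_array_equal(a.abundance, b.abundance)
        np.testing.assert_array_equal(a.kd, b.kd)


class TestSequencing:
    def test_multinomial_counts_within_3sd(self):
        pool = two_clone_pool([0.9, 0.1], [1.0, 2.0])
        rng = np.random.default_rng(0)
        counts = sample_counts(pool, 10_000, rng)
        for c, p in zip(counts, [0.9, 0.1]):
            sd = np.sqrt(10_000 * p * (1 - p))
            assert abs(c - 10_000 * p) <= 3 * sd

    def test_error_free_reads_match_clones_and_carry_indices(self):
        config = small_config(seed=2, n_clones=50, error_rate=0.0)
        pool = generate_naive_library(config)
        sp = list(config.campaigns["gsh"])[0]
        rng = np.random.default_rng(1)
        records = reads_from_counts(pool, sample_counts(pool, 500, rng), sp, config, rng)
        assert len(records) == 500
        dna_set = set(pool.dna)
        flank5, flank3 = config.schema.flank5, config.schema.flank3
        for title, seq, qual in records:
            assert f"1:N:0:{sp.i7}+{sp.i5}" in title
            assert seq.startswith(flank5) and seq.endswith(flank3)
            assert seq[len(flank5):-len(flank3)] in dna_set
            assert len(qual) == len(seq)

    def test_fixed_seed_fastq_bytes_identical(self, tmp_path):
        paths = []
        for name in ("a", "b"):
            config = small_config(seed=9, n_clones=100, depth=500)
            result = run_campaign(config, emit="fastq")
            path = tmp_path / f"{name}.fastq"
            write_fastq(result.reads[("gsh", 1)], path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]


class TestCampaign:
    def test_three_strategies_share_one_naive_pool(self, small_campaign):
        keys = set(small_campaign.pools)
        strategies = {k[0] for k in keys}
        assert strategies == {"strep_nhs", "gsh", "gsh_nhs"}
        assert len(small_campaign.manifest) == len(small_campaign.naive_pool)

    def test_manifest_carries_recovery_oracle_columns(self, small_campaign):
        for col in ("peptide", "dna", "kd_molar", "fitness", "sigma_GSH"):
            assert col in small_campaign.manifest.columns

    def test_gsh_sticky_clone_enriches_more_without_alternation(self):
        """A clone sticky on GSH only reaches a higher final frequency in
        the all-GSH strategy than in the resin-alternating one."""
        config = small_config(seed=13, n_clones=400, amp_noise_tau=0.0)
        result = run_campaign(config, emit="counts")
        truth = result.manifest
        sticky = (truth.sigma_GSH > 0.5) & ~np.isfinite(truth.kd_molar)
        assert sticky.any()
        idx = truth[sticky].sigma_GSH.idxmax()
        f_gsh = result.pools[("gsh", 4)].abundance[idx]
        f_alt = result.pools[("strep_nhs", 4)].abundance[idx]
        assert f_gsh > f_alt
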