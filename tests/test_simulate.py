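import math

import numpy as np
import pytest

import robucket as rb
from robucket import (
    AgentParams,
    CohortSpec,
    GenotypeProfile,
    ParamDist,
    Phase,
    SessionConfig,
    default_profiles,
    default_protocol,
    sample_agent,
    simulate_cohort,
    simulate_protocol,
    simulate_session,
)
from robucket.simulate import _SHARED_PARAMS


def flat_profile(label="test", **overrides):
    """Zero-dispersion profile: every agent equals the parameter means."""
    params = {
        "poke_rate_hz": ParamDist(0.076),
        "p_active_floor": ParamDist(0.5, 0.0, "logit_normal"),
        "p_active_ceiling": ParamDist(0.9, 0.0, "logit_normal"),
        "learning_midpoint_day": ParamDist(4.0),
        "learning_slope_days": ParamDist(1.0),
        "persistence": ParamDist(100.0),
        "disengaged_rate_hz": ParamDist(0.01),
        "disengaged_p_active": ParamDist(0.5, 0.0, "logit_normal"),
    }
    for k, v in overrides.items():
        params[k] = v
    return GenotypeProfile(label, params)


class TestSampleAgent:
    def test_zero_dispersion_returns_means(self, rng):
        agent = sample_agent(flat_profile(), rng)
        assert agent.poke_rate_hz == 0.076
        assert agent.persistence == 100.0
        assert agent.p_active_ceiling == 0.9

    def test_fixed_seed_reproducible(self):
        wt, _ = default_profiles()
        a1 = sample_agent(wt, np.random.default_rng(7))
        a2 = sample_agent(wt, np.random.default_rng(7))
        assert a1 == a2

    def test_lognormal_sample_mean_matches_profile_mean(self, rng):
        dist = ParamDist(0.076, 0.4)
        draws = np.array([dist.draw(rng) for _ in range(10_000)])
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert abs(draws.mean() - 0.076) < 3 * se

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            ParamDist(-1.0, 0.1)
        with pytest.raises(ValueError):
            ParamDist(1.2, 0.1, "logit_normal")
        with pytest.raises(ValueError):
            ParamDist(1.0, 0.1, "cauchy")


class TestSimulateSession:
    def test_fixed_seed_bit_identical_log(self, rng):
        agent = sample_agent(flat_profile(), rng)
        cfg = SessionConfig.for_phase(Phase.PR)
        l1 = simulate_session(agent, cfg, 12, np.random.default_rng(5), phase=Phase.PR)
        l2 = simulate_session(agent, cfg, 12, np.random.default_rng(5), phase=Phase.PR)
        assert l1 == l2

    def test_fr5_throughput_matches_poisson_expectation(self, rng):
        """At 0.076 Hz a fully engaged 60-min session averages ~274
        pokes (the calibration anchor for FR5 throughput)."""
        agent = sample_agent(flat_profile(), rng)
        cfg = SessionConfig.for_phase(Phase.FR5)
        totals = [
            rb.summarize(
                simulate_session(agent, cfg, 15, np.random.default_rng(1000 + i), phase=Phase.FR5)
            ).total_pokes
            for i in range(40)
        ]
        expected = 0.076 * 3600
        assert np.mean(totals) == pytest.approx(expected, rel=0.05)

    def test_infinite_persistence_never_disengages(self, rng):
        agent = sample_agent(
            flat_profile(persistence=ParamDist(math.inf), disengaged_rate_hz=ParamDist(0.0)),
            rng,
        )
        cfg = SessionConfig.for_phase(Phase.PR)
        log = simulate_session(agent, cfg, 15, np.random.default_rng(3), phase=Phase.PR)
        # breakpoint limited only by throughput: every counted active
        # poke contributed to the budget of the next requirement
        s = rb.summarize(log)
        budget = rb.cumulative_pokes_for(cfg.schedule, s.rewards + 1)
        counted_active = int(np.sum(log.poke_counted & (log.poke_well == 1)))
        assert budget > counted_active >= rb.cumulative_pokes_for(cfg.schedule, s.rewards)

    def test_disengagement_probability_recovers_persistence(self, rng):
        """With zero dispersion, the per-reward survival frequencies
        reproduce exp(-r/persistence) within binomial error. Residual
        post-disengagement poking is silenced so the logged breakpoint
        marks the disengagement itself."""
        m = 30.0
        agent = sample_agent(
            flat_profile(persistence=ParamDist(m), disengaged_rate_hz=ParamDist(0.0)), rng
        )
        cfg = SessionConfig.for_phase(Phase.PR)
        bps = np.array(
            [
                simulate_session(
                    agent, cfg, 20, np.random.default_rng(50_000 + i), phase=Phase.PR
                ).n_rewards
                for i in range(1500)
            ]
        )
        for k in (1, 3, 5):
            at_risk = np.sum(bps >= k)
            survived = np.sum(bps >= k + 1)
            p_hat = survived / at_risk
            r_next = rb.requirement_for(cfg.schedule, k)
            p_true = math.exp(-r_next / m)
            se = math.sqrt(p_true * (1 - p_true) / at_risk)
            assert abs(p_hat - p_true) < 4 * se, f"reward {k}: {p_hat} vs {p_true}"

    def test_fr_phase_skips_engagement_check(self, rng):
        # tiny persistence would disengage a PR agent almost instantly,
        # but fixed-ratio sessions never consult it
        agent = sample_agent(flat_profile(persistence=ParamDist(1e-6)), rng)
        cfg = SessionConfig.for_phase(Phase.FR5)
        log = simulate_session(agent, cfg, 15, np.random.default_rng(4), phase=Phase.FR5)
        assert rb.summarize(log).total_pokes > 150


class TestSimulateProtocol:
    def test_fixed_seed_identical_progress(self, rng):
        wt, _ = default_profiles()
        agent = sample_agent(wt, np.random.default_rng(11))
        _, p1, _ = simulate_protocol(agent, default_protocol(), 99)
        _, p2, _ = simulate_protocol(agent, default_protocol(), 99)
        assert p1 == p2

    def test_high_performer_passes_fr1_in_three_days(self, rng):
        agent = sample_agent(
            flat_profile(
                learning_midpoint_day=ParamDist(0.5),
                learning_slope_days=ParamDist(0.2),
                p_active_ceiling=ParamDist(0.95, 0.0, "logit_normal"),
            ),
            rng,
        )
        _, progress, _ = simulate_protocol(agent, default_protocol(), 21)
        assert progress.fr1_days_to_criteria == 3
        assert progress.fr5_sessions == 3

    def test_poor_discriminator_excluded_at_day_17(self, rng):
        agent = sample_agent(
            flat_profile(
                p_active_ceiling=ParamDist(0.7, 0.0, "logit_normal"),
                poke_rate_hz=ParamDist(0.004),
            ),
            rng,
        )
        logs, progress, _ = simulate_protocol(agent, default_protocol(), 23)
        assert progress.excluded
        assert progress.fr1_days_to_criteria is None
        assert len(logs) == 17

    def test_learning_day_accumulates_across_phases(self, rng):
        """Discrimination in PR is at ceiling because the learning-day
        counter keeps running after FR1."""
        wt, _ = default_profiles()
        agent = sample_agent(flat_profile(), rng)
        _, _, sums = simulate_protocol(agent, default_protocol(), 31)
        pr = [s for s in sums if s.phase is Phase.PR]
        ratios = [s.active_inactive_ratio for s in pr if s.active_inactive_ratio is not None]
        assert np.median(ratios) > 3.0


class TestSimulateCohort:
    def test_adding_mice_does_not_perturb_earlier_ones(self):
        wt, mut = default_profiles()
        small = simulate_cohort(CohortSpec(profiles=(wt,), n_per_genotype=(3,), seed=42))
        large = simulate_cohort(CohortSpec(profiles=(wt,), n_per_genotype=(5,), seed=42))
        merged = large.progress.iloc[:3].reset_index(drop=True)
        assert merged.equals(small.progress)

    def test_single_mouse_per_genotype_runs(self):
        wt, mut = default_profiles()
        res = simulate_cohort(CohortSpec(profiles=(wt, mut), n_per_genotype=(1, 1), seed=9))
        assert len(res.progress) == 2

    def test_breakpoint_monotone_in_persistence(self):
        """Mean stabilized breakpoint rises with the persistence scale
        (paired seeds across the three levels)."""
        means = []
        for m in (30.0, 100.0, 330.0):
            prof = flat_profile(label=f"m{m}", persistence=ParamDist(m))
            spec = CohortSpec(
                profiles=(prof,),
                n_per_genotype=(30,),
                protocol=default_protocol(phases=("PR",), start_day=12),
                seed=77,
            )
            res = simulate_cohort(spec)
            means.append(res.progress["breakpoint"].dropna().mean())
        assert means[0] < means[1] < means[2]

    def test_keep_logs_round_trip_through_event_io(self, tmp_path):
        import io as _io

        wt, _ = default_profiles()
        res = simulate_cohort(
            CohortSpec(profiles=(wt,), n_per_genotype=(1,), seed=3), keep_logs=True
        )
        assert res.logs
        buf = _io.StringIO()
        rb.write_log(res.logs[0], buf)
        buf.seek(0)
        assert rb.read_log(buf) == res.logs[0]
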