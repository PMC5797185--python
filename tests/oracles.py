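"""Independent brute-force oracles for cross-checking the package.

Everything here is written directly from the task rules in a naive
step-by-step style, deliberately sharing no code with the package.
"""

import math


def pr_requirement(n_rewards_earned, scale=5.0, rate=0.2):
    """Direct evaluation of the progressive-ratio formula with
    nearest-integer rounding (half away from zero)."""
    n = n_rewards_earned + 1
    x = scale * math.exp(n * rate) - scale
    rounded = int(x + 0.5) if x >= 0 else -int(-x + 0.5)
    return rounded if rounded > 1 else 1


def hand_session(pokes_ms, fixed_ratio=None, timeout_ms=1000, max_duration_ms=3_600_000, max_rewards=None):
    """Step-by-step hand simulation of one session.

    ``pokes_ms`` is a list of (t_ms, is_active) pairs in time order.
    Returns a dict with per-poke flag records, reward times, end time
    and end reason.
    """
    records = []
    reward_times = []
    pokes_toward_reward = 0
    window_closes_at = None
    end_time = max_duration_ms
    reason = "TIME_LIMIT"

    for t, is_active in pokes_ms:
        # session clock check first: a poke at or past the limit is gone
        if t >= max_duration_ms:
            break
        # is this poke inside an open timeout window?
        if window_closes_at is not None and t <= window_closes_at:
            records.append({"t": t, "active": is_active, "in_timeout": True, "counted": False})
            continue
        records.append({"t": t, "active": is_active, "in_timeout": False, "counted": True})
        if not is_active:
            continue
        # counted active poke: opens a fresh timeout window
        window_closes_at = t + timeout_ms
        pokes_toward_reward += 1
        if fixed_ratio is not None:
            needed = fixed_ratio
        else:
            needed = pr_requirement(len(reward_times))
        if pokes_toward_reward == needed:
            reward_times.append(t)
            pokes_toward_reward = 0
            if max_rewards is not None and len(reward_times) == max_rewards:
                end_time = t
                reason = "REWARD_CAP"
                break

    return {
        "records": records,
        "reward_times": reward_times,
        "end_time": end_time,
        "reason": reason,
        "leftover_progress": pokes_toward_reward,
    }


def welch_statistics(xs, ys):
    """Textbook Welch t, Welch–Satterthwaite df."""
    nx, ny = len(xs), len(ys)
    mx = sum(xs) / nx
    my = sum(ys) / ny
    vx = sum((x - mx) ** 2 for x in xs) / (nx - 1)
    vy = sum((y - my) ** 2 for y in ys) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df


def pooled_d(xs, ys):
    """Textbook Cohen's d with pooled SD."""
    nx, ny = len(xs), len(ys)
    mx = sum(xs) / nx
    my = sum(ys) / ny
    vx = sum((x - mx) ** 2 for x in xs) / (nx - 1)
    vy = sum((y - my) ** 2 for y in ys) / (ny - 1)
    sp = math.sqrt(((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2))
    return (mx - my) / sp
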