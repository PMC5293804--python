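"""Independent brute-force oracles used to validate the fast implementations.

These transliterate the scoring rules as plain frame-by-frame scans and the
ANOVA as explicit loops over marginal means; they share no code with the
package internals beyond numpy.
"""

import numpy as np
from scipy import stats as sps


def oracle_speed(positions: np.ndarray, dt_s: float) -> np.ndarray:
    n = positions.shape[0]
    v = np.zeros(n)
    for i in range(n):
        if i == 0:
            d = (positions[1] - positions[0]) / dt_s
        elif i == n - 1:
            d = (positions[-1] - positions[-2]) / dt_s
        else:
            d = (positions[i + 1] - positions[i - 1]) / (2 * dt_s)
        v[i] = float(np.sqrt(np.sum(d * d)))
    return v


def oracle_reach_displacement(positions, t_ms, grasp_end_ms, thr, speed=None):
    """First frame exceeding thr on all axes; per-axis post-peak candidates,
    the one closest in time to the grasp end wins."""
    n = positions.shape[0]
    dt_s = (t_ms[1] - t_ms[0]) / 1000.0
    v = oracle_speed(positions, dt_s) if speed is None else speed
    onset = None
    for i in range(1, n):
        step = np.abs(positions[i] - positions[i - 1])
        if step[0] > thr and step[1] > thr and step[2] > thr:
            onset = i
            break
    if onset is None:
        return None
    i_pk = int(np.argmax(v))
    if i_pk <= onset:
        return None
    candidates = []
    for axis in range(3):
        for i in range(i_pk + 1, n):
            if abs(positions[i, axis] - positions[i - 1, axis]) < thr:
                candidates.append(t_ms[i])
                break
    if not candidates:
        return None
    best = min(candidates, key=lambda tc: (abs(tc - grasp_end_ms), tc))
    if best <= t_ms[onset]:
        return None
    return (float(t_ms[onset]), float(best))


def oracle_reach_velocity(speed, t_ms, thr):
    """First and last frame with speed above the threshold."""
    onset = offset = None
    for i in range(len(speed)):
        if speed[i] > thr:
            onset = i
            break
    for i in range(len(speed) - 1, -1, -1):
        if speed[i] > thr:
            offset = i
            break
    if onset is None or offset is None or offset <= onset:
        return None
    return (float(t_ms[onset]), float(t_ms[offset]))


def oracle_grasp(aperture, t_ms, thr):
    """Onset: change from initial exceeds thr; offset: first post-maximum frame
    whose frame-to-frame change falls below thr."""
    n = len(aperture)
    onset = None
    for i in range(n):
        if abs(aperture[i] - aperture[0]) > thr:
            onset = i
            break
    if onset is None:
        return None
    i_max = int(np.argmax(aperture))
    if i_max <= onset:
        return None
    offset = None
    for i in range(i_max + 1, n):
        if abs(aperture[i] - aperture[i - 1]) < thr:
            offset = i
            break
    if offset is None or offset <= onset:
        return None
    return (float(t_ms[onset]), float(t_ms[offset]))


def oracle_rm_anova(y: np.ndarray):
    """Two-way within-subject ANOVA from explicit marginal-mean loops.

    ``y`` has shape (subjects, factor A levels, factor B levels); returns a
    dict effect -> (F, df1, df2, MSE, p, eta_p2) for A, B and A x B, each
    tested against its subject-by-effect stratum.
    """
    n, A, B = y.shape
    grand = y.mean()
    mean_s = [y[s].mean() for s in range(n)]
    mean_a = [y[:, a, :].mean() for a in range(A)]
    mean_b = [y[:, :, b].mean() for b in range(B)]

    ss_a = n * B * sum((m - grand) ** 2 for m in mean_a)
    ss_b = n * A * sum((m - grand) ** 2 for m in mean_b)
    ss_ab = 0.0
    for a in range(A):
        for b in range(B):
            ss_ab += (y[:, a, b].mean() - mean_a[a] - mean_b[b] + grand) ** 2
    ss_ab *= n
    ss_as = 0.0
    for s in range(n):
        for a in range(A):
            ss_as += (y[s, a, :].mean() - mean_s[s] - mean_a[a] + grand) ** 2
    ss_as *= B
    ss_bs = 0.0
    for s in range(n):
        for b in range(B):
            ss_bs += (y[s, :, b].mean() - mean_s[s] - mean_b[b] + grand) ** 2
    ss_bs *= A
    ss_abs = 0.0
    for s in range(n):
        for a in range(A):
            for b in range(B):
                ss_abs += (
                    y[s, a, b]
                    - y[s, a, :].mean()
                    - y[s, :, b].mean()
                    - y[:, a, b].mean()
                    + mean_s[s]
                    + mean_a[a]
                    + mean_b[b]
                    - grand
                ) ** 2

    def result(ss_eff, df1, ss_err):
        df2 = (n - 1) * df1
        F = (ss_eff / df1) / (ss_err / df2)
        return (
            F, df1, df2, ss_err / df2, float(sps.f.sf(F, df1, df2)),
            ss_eff / (ss_eff + ss_err),
        )

    return {
        "A": result(ss_a, A - 1, ss_as),
        "B": result(ss_b, B - 1, ss_bs),
        "AB": result(ss_ab, (A - 1) * (B - 1), ss_abs),
    }


def random_reach_fixture(rng):
    """A randomized wrist trajectory covering moving/non-moving regimes."""
    n = int(rng.integers(30, 120))
    dt = float(rng.choice([1000.0 / 60.0, 5.0]))
    t = np.arange(n) * dt
    kind = rng.integers(4)
    if kind == 0:  # no motion at all
        pos = np.zeros((n, 3)) + rng.normal(0, 0.02, (n, 3))
    elif kind == 1:  # smooth bell-shaped motion
        m = int(rng.integers(10, n - 5))
        tau = np.clip((np.arange(n) - 5) / max(m, 1), 0, 1)
        arc = rng.uniform(50, 400) * (3 * tau**2 - 2 * tau**3)
        axes = rng.uniform(0.2, 1.0, 3)
        pos = arc[:, None] * (axes / np.linalg.norm(axes))[None, :]
        pos += rng.normal(0, rng.uniform(0, 0.3), (n, 3))
    elif kind == 2:  # random walk
        pos = np.cumsum(rng.normal(0, rng.uniform(0.05, 2.0), (n, 3)), axis=0)
    else:  # step motion with plateaus
        pos = np.zeros((n, 3))
        a, b = sorted(rng.integers(1, n - 1, size=2))
        pos[a:b] = np.cumsum(rng.uniform(0.2, 3.0, (b - a, 3)), axis=0)
        pos[b:] = pos[b - 1] if b > a else 0.0
    grasp_end = float(rng.uniform(t[0], t[-1]))
    return t, pos, grasp_end


def random_aperture_fixture(rng):
    n = int(rng.integers(20, 100))
    t = np.arange(n) * 1000.0 / 60.0
    kind = rng.integers(3)
    if kind == 0:
        ap = np.full(n, 5.0) + rng.normal(0, 0.05, n)
    elif kind == 1:
        peak = rng.uniform(0.2, 0.8)
        tau = np.arange(n) / (n - 1)
        tri = np.minimum(np.clip(tau / peak, 0, 1),
                         np.clip((1 - tau) / (1 - peak), 0, 1))
        ap = 5.0 + rng.uniform(20, 90) * tri + rng.normal(0, rng.uniform(0, 0.2), n)
    else:
        ap = 5.0 + np.abs(np.cumsum(rng.normal(0, rng.uniform(0.05, 1.0), n)))
    return t, ap
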