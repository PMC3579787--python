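"""Independent reference implementations used to check the package.

Everything here is deliberately written the slow, obvious way (explicit
loops, enumeration, numerical integration) and shares no code with the
implementation under test.
"""

import numpy as np
from scipy import integrate, stats


def oracle_minimum_threshold(counts):
    """Step-by-step Minimum-method threshold: explicit smoothing loop,
    explicit maxima scan, lowest-count valley, smallest-t tie break."""
    y = [float(v) for v in counts]
    n = len(y)

    def neighbors(j, ys):
        left = ys[j - 1] if j > 0 else ys[0]
        right = ys[j + 1] if j < n - 1 else ys[n - 1]
        return left, right

    iterations = 0
    while True:
        maxima = []
        for j in range(n):
            left, right = neighbors(j, y)
            if y[j] > left and y[j] > right:
                maxima.append(j)
        if len(maxima) == 2:
            break
        if iterations >= 10_000:
            return None
        new = []
        for j in range(n):
            left, right = neighbors(j, y)
            new.append((left + y[j] + right) / 3.0)
        y = new
        iterations += 1
    p1, p2 = maxima
    best_t, best_count = None, float("inf")
    for t in range(p1 + 1, p2):
        if y[t - 1] > y[t] <= y[t + 1] and y[t] < best_count:
            best_t, best_count = t, y[t]
    return best_t, iterations


def random_bimodal_histogram(rng):
    """Two Gaussian-ish lobes of random means/widths/heights plus clutter."""
    y = np.zeros(256)
    m1 = rng.integers(20, 100)
    m2 = rng.integers(140, 240)
    for m, sd, amp in ((m1, rng.uniform(3, 15), rng.uniform(500, 5000)),
                       (m2, rng.uniform(3, 15), rng.uniform(500, 5000))):
        j = np.arange(256)
        y += amp * np.exp(-0.5 * ((j - m) / sd) ** 2)
    y += rng.uniform(0, 5, 256)
    return np.rint(y)


def grow_pixel_tree(rng, n_pixels):
    """Random set of pixels whose 8-adjacency graph is a tree.

    Pixels are added one at a time; a candidate is accepted only if it is
    8-adjacent to exactly one existing pixel, which guarantees acyclicity.
    """
    pts = {(0, 0)}
    attempts = 0
    while len(pts) < n_pixels and attempts < 200 * n_pixels:
        attempts += 1
        base = list(pts)[rng.integers(len(pts))]
        dr, dc = rng.integers(-1, 2, 2)
        cand = (int(base[0] + dr), int(base[1] + dc))
        if cand in pts:
            continue
        touching = sum((cand[0] + a, cand[1] + b) in pts
                       for a in (-1, 0, 1) for b in (-1, 0, 1)
                       if (a, b) != (0, 0))
        if touching == 1:
            pts.add(cand)
    return pts


def pixel_set_to_mask(pts):
    pts = list(pts)
    rmin = min(p[0] for p in pts)
    cmin = min(p[1] for p in pts)
    rmax = max(p[0] for p in pts)
    cmax = max(p[1] for p in pts)
    mask = np.zeros((rmax - rmin + 1, cmax - cmin + 1), dtype=bool)
    for r, c in pts:
        mask[r - rmin, c - cmin] = True
    return mask


def enumerate_longest_path(pts):
    """Exhaustive endpoint-pair enumeration of the heaviest path.

    Adjacency: orthogonal weight 1, diagonal sqrt(2); diagonal edges whose
    orthogonal bridge pixel is present are dropped (same convention as the
    implementation — the convention itself is checked by hand examples).
    Returns (best_weight, total_weight, best_path).
    """
    pts = set(pts)
    adj = {p: [] for p in pts}
    total = 0.0
    for (r, c) in pts:
        for dr, dc in ((0, 1), (1, 0)):
            q = (r + dr, c + dc)
            if q in pts:
                adj[(r, c)].append((q, 1.0))
                adj[q].append(((r, c), 1.0))
                total += 1.0
        for dc in (-1, 1):
            q = (r + 1, c + dc)
            if q in pts and (r + 1, c) not in pts and (r, c + dc) not in pts:
                adj[(r, c)].append((q, np.sqrt(2.0)))
                adj[q].append(((r, c), np.sqrt(2.0)))
                total += np.sqrt(2.0)

    def walk(path, weight):
        """DFS over simple paths; trees are tiny so this is cheap."""
        best = (weight, list(path))
        for q, w in adj[path[-1]]:
            if q not in path:
                cand = walk(path + [q], weight + w)
                if cand[0] > best[0]:
                    best = cand
        return best

    endpoints = [p for p in pts if len(adj[p]) == 1] or list(pts)
    best_w, best_p = -1.0, None
    for e in endpoints:
        w, p = walk([e], 0.0)
        if w > best_w:
            best_w, best_p = w, p
    return best_w, total, best_p


def brute_moments(xs):
    """Loop-based central moments, skewness, excess kurtosis."""
    xs = list(map(float, xs))
    n = len(xs)
    mean = sum(xs) / n
    m2 = sum((x - mean) ** 2 for x in xs) / n
    m3 = sum((x - mean) ** 3 for x in xs) / n
    m4 = sum((x - mean) ** 4 for x in xs) / n
    return m2, m3, m4, m3 / m2**1.5, m4 / m2**2 - 3.0


def nct_cdf_by_integration(t, df, ncp):
    """Non-central t CDF via P(T<=t) = E_V[Phi(t*sqrt(V/df) - ncp)],
    V ~ chi2(df), computed with adaptive quadrature."""

    def integrand(v):
        return stats.norm.cdf(t * np.sqrt(v / df) - ncp) * stats.chi2.pdf(v, df)

    val, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    return val


def oracle_power_n(alpha, beta, effect):
    """Bisection on per-group n for the two-sided two-sample t-test using
    the integration-based non-central t CDF."""

    def power(n):
        df = 2 * (n - 1)
        ncp = effect * np.sqrt(n / 2.0)
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        return 1.0 - nct_cdf_by_integration(tcrit, df, ncp)

    lo, hi = 2.0, 1e6
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if power(mid) < 1 - beta:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
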