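"""Independent oracles used by the test suite.

These are deliberately plain, loop-based implementations kept separate from
the package so that each test compares two independently written routes to
the same quantity.
"""

import math
from itertools import product


def sgt_oracle(raw_counts):
    """Straightforward Gale-Sampson Simple Good-Turing proportions.

    Linear smoothing of log Z_r against log r, Turing estimates while they
    differ from the smoothed estimate by more than 1.96 standard deviations,
    unseen mass n1/N shared uniformly over zero-count features, final
    renormalization to 1.
    """
    raw = list(int(c) for c in raw_counts)
    total = sum(raw)
    pos = sorted(c for c in raw if c > 0)
    freq = {}
    for c in pos:
        freq[c] = freq.get(c, 0) + 1
    r_values = sorted(freq)
    n1 = freq.get(1, 0)
    if n1 == 0 or len(r_values) < 2:
        # add-pseudocount fallback
        props = [c + 0.1 for c in raw]
        s = sum(props)
        return [v / s for v in props]

    p0 = n1 / total
    # Z values
    z = {}
    for j, r in enumerate(r_values):
        q = r_values[j - 1] if j > 0 else 0
        t = r_values[j + 1] if j + 1 < len(r_values) else 2 * r - q
        z[r] = 2.0 * freq[r] / (t - q)
    # least squares of log z on log r
    xs = [math.log(r) for r in r_values]
    ys = [math.log(z[r]) for r in r_values]
    n = len(xs)
    xbar = sum(xs) / n
    ybar = sum(ys) / n
    slope = sum((x - xbar) * (y - ybar) for x, y in zip(xs, ys)) / sum(
        (x - xbar) ** 2 for x in xs
    )
    intercept = ybar - slope * xbar

    r_star = {}
    use_lgt = False
    for r in r_values:
        lgt = r * (1.0 + 1.0 / r) ** (slope + 1.0)
        if not use_lgt:
            if (r + 1) not in freq:
                use_lgt = True
            else:
                turing = (r + 1) * freq[r + 1] / freq[r]
                sd = math.sqrt(
                    (r + 1) ** 2 * (freq[r + 1] / freq[r] ** 2) * (1 + freq[r + 1] / freq[r])
                )
                if abs(turing - lgt) <= 1.96 * sd:
                    use_lgt = True
                else:
                    r_star[r] = turing
                    continue
        r_star[r] = lgt

    n_star = sum(freq[r] * r_star[r] for r in r_values)
    n_zero = sum(1 for c in raw if c == 0)
    props = []
    for c in raw:
        if c > 0:
            props.append((1.0 - p0) * r_star[c] / n_star)
        else:
            props.append(p0 / n_zero if n_zero else 0.0)
    s = sum(props)
    return [v / s for v in props]


def dm_pmf_oracle(counts, proportions, alpha):
    """Dirichlet-multinomial pmf via plain gamma functions."""
    t = sum(counts)
    value = math.gamma(t + 1) * math.gamma(alpha) / math.gamma(t + alpha)
    for x, p in zip(counts, proportions):
        value *= math.gamma(x + alpha * p) / (math.gamma(x + 1) * math.gamma(alpha * p))
    return value


def enumerate_count_vectors(n_features, total):
    """All non-negative integer vectors of given length summing to total."""
    for combo in product(range(total + 1), repeat=n_features):
        if sum(combo) == total:
            yield combo


def beta_binomial_pmf(x, t, a, b):
    """Beta-binomial pmf: the two-feature Dirichlet-multinomial marginal."""

    def beta(u, v):
        return math.gamma(u) * math.gamma(v) / math.gamma(u + v)

    return math.comb(t, x) * beta(x + a, t - x + b) / beta(a, b)


def bh_oracle(pvalues):
    """Step-up Benjamini-Hochberg adjusted values by the textbook recipe."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adjusted[i] = running
    return adjusted
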