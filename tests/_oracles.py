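"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive — brute-force loops, textbook
formulas, full design matrices — and stays independent of the code paths it
verifies.
"""

import numpy as np


def naive_sample_entropy(x, m=2, r_factor=0.2):
    """Brute-force O(N^2) template matching."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = np.std(x)
    if sd == 0:
        return 0.0
    r = r_factor * sd

    def count(mm):
        total = 0
        for i in range(n - mm):
            for j in range(i + 1, n - mm + 1):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    total += 1
        return total

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return -np.log(a / b)


def ancova_oracle(x, y, ids):
    """rmcorr by explicit least squares: y ~ participant dummies + x."""
    from scipy import stats as spstats
    uniq = np.unique(ids)
    D = np.column_stack([(ids == u).astype(float) for u in uniq] + [x])
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    ss_err = float(resid @ resid)
    D0 = D[:, :-1]
    beta0, *_ = np.linalg.lstsq(D0, y, rcond=None)
    ss_red = float((y - D0 @ beta0) @ (y - D0 @ beta0))
    ss_x = ss_red - ss_err
    r = np.sign(beta[-1]) * np.sqrt(ss_x / (ss_x + ss_err))
    df = len(y) - len(uniq) - 1
    t = r * np.sqrt(df / (1 - r ** 2))
    p = 2 * spstats.t.sf(abs(t), df)
    return r, df, p


def bh_oracle(p):
    """Textbook Benjamini-Hochberg step-up with monotonicity enforcement."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        val = min(p[i] * n / rank, prev)
        adj[i] = val
        prev = val
    return adj


def has_interior_isolated(s):
    """True if the binary sequence still contains a 0-1-0 or 1-0-1 pattern."""
    for i in range(1, len(s) - 1):
        if s[i - 1] == s[i + 1] != s[i]:
            return True
    return False
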