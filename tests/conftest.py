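import pytest

import cleavemap as cm


@pytest.fixture(scope="session")
def ref():
    return cm.default_reference(42)


@pytest.fixture(scope="session")
def profile(ref):
    return cm.default_profile(ref)


def brute_force_align(ref_seq: str, read: str):
    """Independent aligner oracle: scan every position on both strands.

    Returns (start, strand, n_hits) with the package's placement policy
    (+ strand preferred, leftmost within strand), or (None, None, 0).
    """
    from cleavemap._util import revcomp, to_dna

    read = to_dna(read)
    plus = [i for i in range(len(ref_seq) - len(read) + 1) if ref_seq[i : i + len(read)] == read]
    rc = revcomp(read)
    minus = [i for i in range(len(ref_seq) - len(rc) + 1) if ref_seq[i : i + len(rc)] == rc]
    n = len(plus) + len(minus)
    if plus:
        return plus[0], "+", n
    if minus:
        return minus[0], "-", n
    return None, None, 0


def max_pairs_exhaustive(seq: str, min_loop: int = 3, allow_gu: bool = True) -> int:
    """Exhaustive maximum-pairing oracle for short sequences (<= ~14 nt):
    plain recursion over all nested structures."""
    pairs = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
    if allow_gu:
        pairs |= {("G", "U"), ("U", "G")}
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        out = best(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in pairs:
                out = max(out, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return out

    return best(0, len(seq) - 1)


def welch_p_oracle(a, b):
    """Textbook Welch two-sided t: statistic, Welch-Satterthwaite df, p."""
    import numpy as np
    from scipy import stats

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return t, 2 * stats.t.sf(abs(t), df)
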