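"""Independent brute-force oracles used to validate the fast implementations.

Everything here works on plain Python strings/dicts/floats and never calls
into the package's compiled paths, so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def canonical_kmer(window: str) -> str | None:
    if any(c not in "ACGT" for c in window):
        return None
    rc = revcomp(window)
    return window if window <= rc else rc


def count_kmers_naive(seqs: list[str], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            canon = canonical_kmer(seq[i : i + k])
            if canon is not None:
                counts[canon] = counts.get(canon, 0) + 1
    return counts


def compress_naive(seq: str) -> str:
    out = []
    for c in seq:
        if not out or out[-1] != c:
            out.append(c)
    return "".join(out)


def hapmer_sets_naive(seqs1: list[str], seqs2: list[str], k: int) -> tuple[set, set]:
    s1 = set(count_kmers_naive(seqs1, k))
    s2 = set(count_kmers_naive(seqs2, k))
    return s1 - s2, s2 - s1


def locate_naive(seqs: dict[str, str], hapmers: set[str], k: int) -> list[tuple[str, int]]:
    out = []
    for sid, seq in seqs.items():
        for i in range(len(seq) - k + 1):
            canon = canonical_kmer(seq[i : i + k])
            if canon is not None and canon in hapmers:
                out.append((sid, i))
    return out


def ols_closed_form(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """(slope, intercept, r_squared, residual_sd) by the textbook formulas."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    sxy = ((x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    ss_res = (resid ** 2).sum()
    ss_tot = ((y - ybar) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    sd = np.sqrt(ss_res / (n - 2)) if n > 2 else 0.0
    return float(slope), float(intercept), float(r2), float(sd)


def studentized_loo(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Externally studentized residuals by literally refitting without each point."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    out = np.zeros(n)
    for i in range(n):
        keep = np.ones(n, bool)
        keep[i] = False
        slope, intercept, _, _ = ols_closed_form(x[keep], y[keep])
        resid = y[i] - intercept - slope * x[i]
        ss_res = ((y[keep] - intercept - slope * x[keep]) ** 2).sum()
        s2 = ss_res / (n - 1 - 2)
        xbar = x[keep].mean()
        sxx = ((x[keep] - xbar) ** 2).sum()
        se = np.sqrt(s2 * (1.0 + 1.0 / (n - 1) + (x[i] - xbar) ** 2 / sxx))
        out[i] = resid / se
    return out


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))
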