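"""Luria-Delbrueck fluctuation-test estimation (MSS maximum likelihood).

The number of mutant colonies per replicate culture follows the
Luria-Delbrueck distribution; its probabilities satisfy the Ma-Sandri-Sarkar
recursion

    p_0 = exp(-m),    p_k = (m / k) * sum_{i=0}^{k-1} p_i / (k - i + 1),

where m is the expected number of mutation events per culture.  m is
estimated by maximizing the replicate log likelihood, the 95% CI comes from
the profile likelihood (2 * delta lnL = 3.84), and the per-generation
mutation rate is mu = m / N_final (mutations per cell division under binary
growth from a small inoculum).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import chi2

__all__ = [
    "FluctuationAssay",
    "MLEResult",
    "mss_pmf",
    "mss_log_likelihood",
    "mss_mle",
    "rate_ratio_report",
]


@dataclass
class FluctuationAssay:
    """Replicate mutant counts from parallel cultures plated on selection."""

    mutant_counts: list[int]
    n_final: float                  # cells per culture at plating
    plated_fraction: float = 1.0
    n_initial: float = 1.0

    def __post_init__(self):
        counts = [int(c) for c in self.mutant_counts]
        if any(c < 0 for c in counts):
            raise ValueError("mutant counts must be non-negative")
        if len(counts) < 2:
            raise ValueError("need at least 2 replicates for estimation")
        if self.n_final < max(counts):
            raise ValueError("final population smaller than a mutant count")
        if not (0 < self.plated_fraction <= 1):
            raise ValueError("plated_fraction must be in (0, 1]")
        self.mutant_counts = counts


@dataclass
class MLEResult:
    m_hat: float                    # expected mutations per culture
    mu_hat: float                   # per-generation mutation rate
    ci95: tuple[float, float]       # CI for mu_hat
    log_likelihood: float
    m_ci95: tuple[float, float] = (0.0, 0.0)


def mss_pmf(m: float, k_max: int) -> np.ndarray:
    """Luria-Delbrueck mutant-count probabilities p_0..p_kmax via the MSS
    recursion.  The deficit 1 - sum(p) is the tail mass beyond k_max."""
    if m < 0:
        raise ValueError("m must be non-negative")
    if k_max < 0:
        raise ValueError("k_max must be non-negative")
    p = np.zeros(k_max + 1)
    p[0] = np.exp(-m)
    if k_max == 0:
        return p
    # p_k = (m/k) * sum_{i<k} p_i / (k - i + 1)
    inv = 1.0 / np.arange(2, k_max + 2)          # inv[j] = 1/(j+2)
    for k in range(1, k_max + 1):
        p[k] = (m / k) * np.dot(p[:k], inv[k - 1::-1])
    return p


def mss_log_likelihood(m: float, counts: np.ndarray, k_max: int | None = None,
                       k_cap: int = 2000) -> float:
    """Replicate log likelihood under the MSS distribution.

    Counts above ``k_cap`` are right-censored (jackpot cultures carry almost
    no information about m beyond "large", and the O(k^2) recursion would be
    prohibitive); a censored replicate contributes log P(K >= k_cap).
    """
    counts = np.asarray(counts, dtype=int)
    if k_max is None:
        k_max = int(counts.max()) * 4 + 50
    k_max = min(k_max, k_cap)
    censored = counts >= k_max
    p = mss_pmf(m, k_max)
    ll = 0.0
    if (~censored).any():
        probs = p[counts[~censored]]
        if (probs <= 0).any():
            return -np.inf
        ll += float(np.log(probs).sum())
    if censored.any():
        tail = max(1.0 - float(p[:-1].sum()), 1e-300)
        ll += int(censored.sum()) * np.log(tail)
    return ll


def _plating_correction(m_obs: float, f: float) -> float:
    """Correct m for partial plating: m = m_obs * (f - 1) / (f ln f)."""
    if f >= 1.0:
        return m_obs
    return m_obs * (f - 1.0) / (f * np.log(f))


def mss_mle(assay: FluctuationAssay, level: float = 0.95,
            rate_denominator: str = "n_final") -> MLEResult:
    """Maximum-likelihood m and mutation rate from a fluctuation assay.

    ``rate_denominator``: ``n_final`` gives mu = m / N_final; the alternative
    ``n_final_minus_n0`` divides by the number of divisions N_final - N_0.
    """
    counts = np.asarray(assay.mutant_counts, dtype=int)
    k_max = min(int(counts.max()) * 4 + 50, 2000)
    crit = chi2.ppf(level, df=1)

    if rate_denominator == "n_final":
        denom = assay.n_final
    elif rate_denominator == "n_final_minus_n0":
        denom = assay.n_final - assay.n_initial
    else:
        raise ValueError("rate_denominator must be 'n_final' or "
                         "'n_final_minus_n0'")

    def nll(m):
        return -mss_log_likelihood(m, counts, k_max)

    if counts.max() == 0:
        # boundary MLE: lnL(m) = -m R, monotone decreasing
        m_hat, ll = 0.0, 0.0
        hi = crit / (2 * len(counts))          # 2(lnL(0) - lnL(m)) = 2mR
        m_lo, m_hi = 0.0, hi
    else:
        # p_0 = exp(-m) underflows past m ~ 745, where the likelihood is no
        # longer representable; real assays live far below that
        upper = min(max(float(counts.max()) * 3.0, 5.0), 700.0)
        grid = np.geomspace(1e-3, upper, 50)
        grid_ll = np.array([-nll(m) for m in grid])
        i = int(np.argmax(grid_ll))
        lo_b = grid[max(i - 1, 0)]
        hi_b = grid[min(i + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(nll, bounds=(lo_b, hi_b),
                                       method="bounded",
                                       options={"xatol": 1e-8})
        m_hat = float(res.x)
        ll = -float(res.fun)

        def profile(m):
            return 2.0 * (ll - mss_log_likelihood(m, counts, k_max)) - crit

        m_lo = 0.0
        if profile(1e-12) > 0:
            m_lo = float(optimize.brentq(profile, 1e-12, m_hat, xtol=1e-10))
        hi_bracket = m_hat * 2 + 1
        while profile(hi_bracket) < 0 and hi_bracket < 1e6:
            hi_bracket *= 2
        m_hi = float(optimize.brentq(profile, m_hat, hi_bracket, xtol=1e-10))

    f = assay.plated_fraction
    m_corr = _plating_correction(m_hat, f)
    lo_corr = _plating_correction(m_lo, f)
    hi_corr = _plating_correction(m_hi, f)
    mu = m_corr / denom
    return MLEResult(m_hat=m_corr, mu_hat=mu,
                     ci95=(lo_corr / denom, hi_corr / denom),
                     log_likelihood=ll, m_ci95=(lo_corr, hi_corr))


def rate_ratio_report(result_a: MLEResult, result_b: MLEResult
                      ) -> dict[str, float]:
    """Fold difference mu_b / mu_a with a CI from independent intervals."""
    if result_a.mu_hat <= 0:
        raise ZeroDivisionError("denominator rate is zero")
    fold = result_b.mu_hat / result_a.mu_hat
    lo_a, hi_a = result_a.ci95
    lo_b, hi_b = result_b.ci95
    ci = (lo_b / hi_a if hi_a > 0 else 0.0,
          hi_b / lo_a if lo_a > 0 else np.inf)
    return {"fold": float(fold), "ci_lo": float(ci[0]), "ci_hi": float(ci[1])}
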