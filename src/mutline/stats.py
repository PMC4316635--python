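"""Mutation-rate, spectrum, and ratio statistics for MA-line data.

Rates are per site per generation.  The pooled rate divides total mutation
counts by total exposure (sum over lines of analyzed sites x generations);
its standard error follows the Poisson per-line formula
SE = sqrt(u / (n T)) averaged over lines and divided by sqrt(N).

The six-class conditional spectrum normalizes each substitution class by the
number of source-class sites (A:T or G:C), so e.g. the GC->AT rate is
count / (n_GC x N x T).  Class asymmetry (GC->AT vs AT->GC) is tested with
the odds-ratio logit method: the log rate ratio is approximately normal with
a four-term reciprocal-count standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import BASES

__all__ = [
    "RateEstimate",
    "SpectrumTable",
    "OddsRatioResult",
    "SPECTRUM_CLASSES",
    "substitution_class",
    "substitution_rate",
    "pooled_se",
    "conditional_spectrum",
    "ts_tv_ratio",
    "is_transition",
    "odds_ratio_logit_test",
    "expected_ns_ratio",
    "goodness_of_fit_1df",
    "poisson_rate_ci",
    "compare_region_spectra",
    "expected_coding_intergenic_ratio",
]

SPECTRUM_CLASSES = ("AT->GC", "GC->AT", "AT->TA", "AT->CG", "GC->TA", "GC->CG")
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_PAIR = {"A": "AT", "T": "AT", "C": "GC", "G": "GC"}


def is_transition(ref: str, alt: str) -> bool:
    return (ref, alt) in _TRANSITIONS


_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def substitution_class(ref: str, alt: str):
    """Map a ref->alt substitution to one of the six base-pair classes.

    Classes use ordered-pair notation: the mutation is expressed on the
    strand where the reference base is A or G, and the destination pair is
    written mutant-base first — so G->A is GC->AT (transition) while G->T is
    GC->TA (transversion).
    """
    if ref == alt or ref not in _PAIR or alt not in _PAIR:
        raise ValueError(f"not a substitution: {ref}->{alt}")
    if ref in ("T", "C"):
        ref, alt = _COMP[ref], _COMP[alt]
    return f"{_PAIR[ref]}->{alt}{_COMP[alt]}"


@dataclass
class RateEstimate:
    """A mutation rate with its exposure bookkeeping."""

    rate: float
    se: float
    mutation_count: int
    analyzed_sites: float          # mean per line
    generations: float
    n_lines: int
    per_line_rates: np.ndarray | None = None
    per_line_mean_rate: float | None = None

    @property
    def exposure(self) -> float:
        return self.analyzed_sites * self.generations * self.n_lines


def _per_line_counts(calls, n_lines: int, line_ids=None) -> np.ndarray:
    """Per-line mutation counts from a calls frame, an int total, or a vector."""
    if isinstance(calls, pd.DataFrame):
        if line_ids is None:
            line_ids = sorted(calls["line_id"].unique())
        counts = calls["line_id"].value_counts()
        return np.array([counts.get(l, 0) for l in line_ids], dtype=float)
    if np.isscalar(calls):
        return np.full(n_lines, float(calls) / n_lines)
    return np.asarray(calls, dtype=float)


def substitution_rate(calls, analyzed_sites_per_line, generations,
                      n_lines: int | None = None,
                      line_ids=None) -> RateEstimate:
    """Pooled mutation rate: total count over total exposure, with pooled SE.

    ``calls`` may be a calls DataFrame, a total count (per-line counts then
    assumed identical), or a per-line count vector.  ``analyzed_sites_per_line``
    and ``generations`` may be scalars (identical lines) or per-line vectors.
    """
    if n_lines is None:
        if line_ids is not None:
            n_lines = len(line_ids)
        elif isinstance(calls, pd.DataFrame):
            line_ids = sorted(calls["line_id"].unique())
            n_lines = len(line_ids)
        elif not np.isscalar(calls):
            n_lines = len(np.atleast_1d(calls))
        else:
            n_lines = np.atleast_1d(np.asarray(
                analyzed_sites_per_line, dtype=float)).shape[0]
    per_line = _per_line_counts(calls, n_lines, line_ids)
    n = np.broadcast_to(np.asarray(analyzed_sites_per_line, dtype=float),
                        (n_lines,))
    T = np.broadcast_to(np.asarray(generations, dtype=float), (n_lines,))
    exposure = n * T
    if not (exposure > 0).all():
        raise ValueError("every line needs positive exposure (n x T)")
    total = per_line.sum()
    rate = total / exposure.sum()
    rates = per_line / exposure
    se = pooled_se(rates, exposure)
    return RateEstimate(rate=float(rate), se=float(se),
                        mutation_count=int(round(total)),
                        analyzed_sites=float(n.mean()),
                        generations=float(T.mean()), n_lines=int(n_lines),
                        per_line_rates=rates,
                        per_line_mean_rate=float(rates.mean()))


def pooled_se(per_line_rates, per_line_exposures) -> float:
    """SE of the pooled rate: mean over lines of sqrt(u/(nT)), over sqrt(N)."""
    u = np.asarray(per_line_rates, dtype=float)
    nT = np.asarray(per_line_exposures, dtype=float)
    if u.size == 0:
        raise ValueError("need at least one line")
    per_line_se = np.sqrt(u / nT)
    return float(per_line_se.mean() / np.sqrt(u.size))


# -- spectrum ------------------------------------------------------------------


@dataclass
class SpectrumTable:
    """Counts, fractions, conditional rates and Poisson CIs per class."""

    table: pd.DataFrame            # index: SPECTRUM_CLASSES
    gc_content: float
    analyzed_sites: float
    n_lines: int
    generations: float

    @property
    def total(self) -> int:
        return int(self.table["count"].sum())

    def class_rate(self, cls: str) -> float:
        return float(self.table.loc[cls, "rate"])

    @property
    def mean_at_rate(self) -> float:
        """Mean per-site rate of A:T source sites (all three AT-> classes)."""
        at = [c for c in SPECTRUM_CLASSES if c.startswith("AT")]
        return float(self.table.loc[at, "rate"].sum())

    @property
    def mean_gc_rate(self) -> float:
        gc = [c for c in SPECTRUM_CLASSES if c.startswith("GC")]
        return float(self.table.loc[gc, "rate"].sum())

    @property
    def mean_rate(self) -> float:
        """Genomic mean per-site rate (count-weighted over source classes)."""
        g = self.gc_content
        return float((1 - g) * self.mean_at_rate + g * self.mean_gc_rate)


def _class_counts(calls) -> dict[str, int]:
    if isinstance(calls, dict):
        missing = set(SPECTRUM_CLASSES) - set(calls)
        if missing:
            raise ValueError(f"missing classes {sorted(missing)}")
        return {c: int(calls[c]) for c in SPECTRUM_CLASSES}
    counts = dict.fromkeys(SPECTRUM_CLASSES, 0)
    for ref, alt in zip(calls["ref"], calls["alt"]):
        counts[substitution_class(ref, alt)] += 1
    return counts


def conditional_spectrum(calls, gc_content: float, analyzed_sites: float,
                         n_lines: int, generations: float,
                         level: float = 0.95) -> SpectrumTable:
    """Six-class spectrum with rates conditioned on source-base-class sites.

    ``calls`` is a calls DataFrame (with ref/alt columns) or a dict of class
    counts.  AT-source classes use exposure n x (1-GC) x N x T; GC-source use
    n x GC x N x T.
    """
    counts = _class_counts(calls)
    total = sum(counts.values())
    rows = []
    for cls in SPECTRUM_CLASSES:
        frac_sites = (1 - gc_content) if cls.startswith("AT") else gc_content
        exposure = analyzed_sites * frac_sites * n_lines * generations
        k = counts[cls]
        rate = k / exposure
        lo, hi = poisson_rate_ci(k, exposure, level)
        rows.append([cls, k, k / total if total else np.nan, rate,
                     np.sqrt(k) / exposure, lo, hi])
    table = pd.DataFrame(rows, columns=["class", "count", "fraction", "rate",
                                        "se", "ci_lo", "ci_hi"]
                         ).set_index("class")
    return SpectrumTable(table, gc_content, analyzed_sites, n_lines,
                         generations)


def ts_tv_ratio(calls) -> tuple[float, int, int]:
    """Transition/transversion count ratio; raises on zero transversions.

    ``calls`` may be a DataFrame with ref/alt or a dict of class counts.
    Returns (ratio, n_transitions, n_transversions).
    """
    counts = _class_counts(calls)
    ts = counts["AT->GC"] + counts["GC->AT"]
    tv = sum(counts[c] for c in ("AT->TA", "AT->CG", "GC->TA", "GC->CG"))
    if tv == 0:
        raise ZeroDivisionError("no transversions observed; ratio is infinite")
    return ts / tv, ts, tv


# -- odds-ratio logit test ----------------------------------------------------


@dataclass
class OddsRatioResult:
    ln_or: float
    se_ln_or: float
    z: float
    one_sided_p: float
    rate_ratio: float
    pi_gc_at: int
    pi_at_gc: int
    n_gc: float
    n_at: float
    alternative: str = "observed"


def odds_ratio_logit_test(pi_gc_at: int, pi_at_gc: int, n_gc: float,
                          n_at: float,
                          alternative: str = "observed") -> OddsRatioResult:
    """Test whether the GC->AT / AT->GC rate ratio equals 1.

    ln OR = ln((pi_GC->AT / N_GC) / (pi_AT->GC / N_AT)); its SE is
    sqrt(1/pi1 + 1/(N_GC - pi1) + 1/pi2 + 1/(N_AT - pi2)).

    ``alternative``:
      * ``observed`` — P(Z < -|lnOR|/SE), the one-sided P in the direction of
        the observed deviation (suited to reporting an observed asymmetry, but
        not a calibrated test: under the null it rejects at twice the nominal
        level);
      * ``less`` / ``greater`` — proper one-sided tests of rate ratio < 1 or
        > 1 fixed in advance.
    """
    cells = {"pi_gc_at": pi_gc_at, "pi_at_gc": pi_at_gc,
             "n_gc - pi_gc_at": n_gc - pi_gc_at,
             "n_at - pi_at_gc": n_at - pi_at_gc}
    for name, v in cells.items():
        if v <= 0:
            raise ValueError(f"cell {name} = {v}; SE undefined with a zero or "
                             "negative cell (consider a continuity correction)")
    ln_or = np.log((pi_gc_at / n_gc) / (pi_at_gc / n_at))
    se = np.sqrt(1 / pi_gc_at + 1 / (n_gc - pi_gc_at)
                 + 1 / pi_at_gc + 1 / (n_at - pi_at_gc))
    z = ln_or / se
    if alternative == "observed":
        p = sps.norm.cdf(-abs(z))
    elif alternative == "less":
        p = sps.norm.cdf(z)
    elif alternative == "greater":
        p = sps.norm.sf(z)
    else:
        raise ValueError("alternative must be 'observed', 'less' or 'greater'")
    return OddsRatioResult(float(ln_or), float(se), float(z), float(p),
                           float(np.exp(ln_or)), pi_gc_at, pi_at_gc,
                           n_gc, n_at, alternative)


# -- expected N:S ratio --------------------------------------------------------

_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]


def _spectrum_rate_map(spectrum) -> dict[str, float]:
    if isinstance(spectrum, SpectrumTable):
        return {c: spectrum.class_rate(c) for c in SPECTRUM_CLASSES}
    missing = set(SPECTRUM_CLASSES) - set(spectrum)
    if missing:
        raise ValueError(f"spectrum missing classes {sorted(missing)}")
    return {c: float(spectrum[c]) for c in SPECTRUM_CLASSES}


def expected_ns_ratio(codon_usage: dict[str, float], spectrum) -> float:
    """Expected nonsynonymous:synonymous ratio absent selection.

    Enumerates all 64 codons x 3 positions x 3 alternative bases, weighting
    each change by codon frequency x the conditional rate of its substitution
    class.  Changes creating or destroying a stop codon count as
    nonsynonymous (stop-to-stop counts synonymous).
    """
    from .genome import _translate_codon   # local import avoids cycle at load

    rates = _spectrum_rate_map(spectrum)
    if all(v == 0 for v in rates.values()):
        raise ValueError("degenerate spectrum: all class rates are zero")
    usage = {c.upper().replace("U", "T"): f for c, f in codon_usage.items()}
    total = sum(usage.values())
    if total <= 0:
        raise ValueError("codon usage must have positive mass")
    w_non = w_syn = 0.0
    for codon in _CODONS:
        freq = usage.get(codon, 0.0) / total
        if freq == 0:
            continue
        aa = _translate_codon(codon)
        for pos in range(3):
            ref = codon[pos]
            for alt in BASES:
                if alt == ref:
                    continue
                w = freq * rates[substitution_class(ref, alt)]
                mutant = codon[:pos] + alt + codon[pos + 1:]
                aa2 = _translate_codon(mutant)
                if aa2 == aa:
                    w_syn += w
                else:
                    w_non += w
    if w_syn == 0:
        raise ZeroDivisionError("no synonymous weight; ratio infinite")
    return w_non / w_syn


def goodness_of_fit_1df(observed_a: int, observed_b: int,
                        expected_ratio_a_to_b: float) -> tuple[float, float]:
    """Pearson chi-square (df=1) of two counts against an expected ratio."""
    if observed_a <= 0 or observed_b <= 0:
        raise ValueError("observed counts must be positive")
    n = observed_a + observed_b
    pa = expected_ratio_a_to_b / (1 + expected_ratio_a_to_b)
    ea, eb = n * pa, n * (1 - pa)
    chi2 = (observed_a - ea) ** 2 / ea + (observed_b - eb) ** 2 / eb
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def poisson_rate_ci(count: int, exposure: float,
                    level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) Poisson CI on a count, divided by the exposure."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if exposure <= 0:
        raise ValueError("exposure must be positive")
    alpha = 1 - level
    lo = 0.0 if count == 0 else sps.chi2.ppf(alpha / 2, 2 * count) / 2
    hi = sps.chi2.ppf(1 - alpha / 2, 2 * count + 2) / 2
    return lo / exposure, hi / exposure


def expected_coding_intergenic_ratio(coding_fraction: float) -> float:
    """Null ratio of coding to intergenic mutation counts by target size."""
    if not (0 < coding_fraction < 1):
        raise ValueError("coding_fraction must be strictly between 0 and 1")
    return coding_fraction / (1 - coding_fraction)


# -- region spectra ------------------------------------------------------------


def compare_region_spectra(calls: pd.DataFrame, region_sites: dict[str, dict],
                           n_lines: int, generations: float,
                           level: float = 0.95):
    """Per-region conditional spectra with a pairwise CI-overlap report.

    ``calls`` must carry a ``region`` column; ``region_sites`` maps region
    name -> {"sites": analyzed sites, "gc": GC fraction}.  Returns
    (spectra dict, overlap DataFrame with one row per class x region pair).
    """
    spectra = {}
    for region, meta in region_sites.items():
        if meta["sites"] <= 0:
            raise ValueError(f"region {region!r} has zero exposure")
        sub = calls[calls["region"] == region]
        spectra[region] = conditional_spectrum(
            sub, meta["gc"], meta["sites"], n_lines, generations, level)
    regions = list(spectra)
    rows = []
    for cls in SPECTRUM_CLASSES:
        for i, a in enumerate(regions):
            for b in regions[i + 1:]:
                la, ha = spectra[a].table.loc[cls, ["ci_lo", "ci_hi"]]
                lb, hb = spectra[b].table.loc[cls, ["ci_lo", "ci_hi"]]
                rows.append([cls, a, b, max(la, lb) <= min(ha, hb)])
    overlap = pd.DataFrame(rows, columns=["class", "region_a", "region_b",
                                          "ci_overlap"])
    return spectra, overlap
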