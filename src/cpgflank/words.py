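"""Markov-model word-count exceptionality and CpG-island metrics.

Under the first-order Markov (M1) background, the expected count of a word
w1..wh is the plug-in estimator

    Ehat(w) = prod_i N2(w_i w_{i+1}) / prod_i N1(w_i),   i interior,

which reproduces dinucleotide counts exactly (every 2-letter word scores 0).
The exceptionality score is z = (N_obs - Ehat) / sigma_hat with sigma_hat the
asymptotic Gaussian standard deviation of N(w) - Ehat(w).  sigma_hat is
computed by the delta method: the estimator is linearized in the word,
dinucleotide and letter counts, and the covariance of stationary Markov
word counts is evaluated exactly (overlapping-occurrence terms plus
long-range terms through the chain's fundamental matrix).  Scores map to
two-sided normal p-values: a score of 5 corresponds to p ~ 1e-6 and a score
of 10 to p ~ 1e-23.

The CpG-island verdict uses the operational definition GC fraction > 0.55
and observed/expected CpG ratio N(CG) * L / (N(C) * N(G)) > 0.8.
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

BASES = "ACGT"
_INDEX = {b: i for i, b in enumerate(BASES)}


# ---------------------------------------------------------------------------
# word counting
# ---------------------------------------------------------------------------

@dataclass
class WordCounts:
    """Overlapping word counts for all lengths 1..h over a sequence set.

    Windows never span sequence boundaries; windows containing a non-ACGT
    character are skipped (they break the word).
    """

    h: int
    counts: dict[int, Counter] = field(default_factory=dict)
    positions: dict[int, int] = field(default_factory=dict)

    def count(self, word: str) -> int:
        return self.counts.get(len(word), Counter()).get(word, 0)

    @property
    def total_letters(self) -> int:
        return self.positions.get(1, 0)


def count_words(sequences: str | list[str], h: int) -> WordCounts:
    """Count overlapping occurrences of every word of length 1..h."""
    if h < 1:
        raise ValueError("word length h must be >= 1")
    if isinstance(sequences, str):
        sequences = [sequences]
    wc = WordCounts(h=h, counts={}, positions={})
    valid = set(BASES)
    warned = False
    for length in range(1, h + 1):
        wc.counts[length] = Counter()
        wc.positions[length] = 0
    for seq in sequences:
        seq = seq.upper()
        if not warned and any(ch not in valid for ch in seq):
            warnings.warn("non-ACGT characters present; windows containing them are skipped")
            warned = True
        for length in range(1, h + 1):
            counter = wc.counts[length]
            for i in range(len(seq) - length + 1):
                word = seq[i : i + length]
                if all(ch in valid for ch in word):
                    counter[word] += 1
                    wc.positions[length] += 1
    return wc


# ---------------------------------------------------------------------------
# M1 expectation and variance
# ---------------------------------------------------------------------------

def m1_expected(word: str, counts: WordCounts) -> float:
    """Expected count of ``word`` under the M1 (first-order Markov) model.

    For h = 2 this equals the observed dinucleotide count exactly.  Returns
    NaN with a warning when an interior letter is unobserved (the estimator
    is undefined); returns 0.0 when a required dinucleotide is absent.
    """
    word = word.upper()
    h = len(word)
    if h < 1 or any(ch not in _INDEX for ch in word):
        raise ValueError(f"word must be non-empty over ACGT, got {word!r}")
    if counts.h < max(h if h == 1 else 2, 1):
        raise ValueError("counts must include dinucleotides (h >= 2)")
    if h == 1:
        return float(counts.count(word))
    num = 1.0
    for i in range(h - 1):
        num *= counts.count(word[i : i + 2])
    den = 1.0
    for i in range(1, h - 1):
        n1 = counts.count(word[i])
        if n1 == 0:
            if num == 0:
                return 0.0
            warnings.warn(
                f"interior letter {word[i]!r} unobserved; M1 expectation undefined"
            )
            return float("nan")
        den *= n1
    return num / den


def _transition_matrix(counts: WordCounts) -> tuple[np.ndarray, np.ndarray]:
    """(P, pi): row-stochastic transition matrix and its stationary law."""
    n2 = np.zeros((4, 4))
    for ab, c in counts.counts[2].items():
        n2[_INDEX[ab[0]], _INDEX[ab[1]]] = c
    rows = n2.sum(axis=1)
    if np.any(rows == 0):
        raise ValueError("every letter must appear followed by another letter")
    p = n2 / rows[:, None]
    w, v = np.linalg.eig(p.T)
    idx = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, idx])
    pi = np.abs(pi) / np.abs(pi).sum()
    return p, pi


def _word_prob(word: str, p: np.ndarray, pi: np.ndarray) -> float:
    mu = pi[_INDEX[word[0]]]
    for i in range(len(word) - 1):
        mu *= p[_INDEX[word[i]], _INDEX[word[i + 1]]]
    return float(mu)


def _merge_words(u: str, v: str, t: int) -> str | None:
    """Superword of u at 0 and v at offset t >= 0, or None if incompatible."""
    end = max(len(u), t + len(v))
    merged = [None] * end
    for i, ch in enumerate(u):
        merged[i] = ch
    for i, ch in enumerate(v):
        j = t + i
        if merged[j] is None:
            merged[j] = ch
        elif merged[j] != ch:
            return None
    if any(ch is None for ch in merged):  # gap between the two words
        return None
    return "".join(merged)


def _pair_cov_rate(
    u: str, v: str, p: np.ndarray, pi: np.ndarray, zmi: np.ndarray
) -> float:
    """Asymptotic per-position covariance of the counts of words u and v.

    Sum over all relative lags of the joint occurrence probability minus
    mu(u) mu(v), with the non-overlapping tail expressed through
    ``zmi = Z - I`` where Z is the fundamental matrix of the chain.
    """
    mu_u = _word_prob(u, p, pi)
    mu_v = _word_prob(v, p, pi)
    total = 0.0
    # overlapping / adjacent-window lags
    for t in range(-(len(v) - 1), len(u)):
        if t >= 0:
            merged = _merge_words(u, v, t)
        else:
            merged = _merge_words(v, u, -t)
        joint = _word_prob(merged, p, pi) if merged is not None else 0.0
        total += joint - mu_u * mu_v
    # u strictly before v, separated by >= 1 step
    total += mu_u * mu_v / pi[_INDEX[v[0]]] * zmi[_INDEX[u[-1]], _INDEX[v[0]]]
    # v strictly before u
    total += mu_u * mu_v / pi[_INDEX[u[0]]] * zmi[_INDEX[v[-1]], _INDEX[u[0]]]
    return total


def m1_sigma(word: str, counts: WordCounts) -> float:
    """Asymptotic standard deviation of N(word) - Ehat(word) under M1."""
    word = word.upper()
    h = len(word)
    if h < 2:
        raise ValueError("sigma is defined for words of length >= 2")
    if h == 2:
        return 0.0  # Ehat equals the observed count identically
    p, pi = _transition_matrix(counts)
    zmi = np.linalg.inv(np.eye(4) - p + np.outer(np.ones(4), pi)) - np.eye(4)
    n = counts.total_letters
    expected = m1_expected(word, counts)
    if not np.isfinite(expected):
        return float("nan")

    # linearization N(w) - Ehat ~ sum_s alpha_s (N_s - E N_s)
    items: list[tuple[str, float]] = [(word, 1.0)]
    transitions = Counter(word[i : i + 2] for i in range(h - 1))
    for v, mult in transitions.items():
        n2 = counts.count(v)
        if n2 == 0:
            return float("nan")
        items.append((v, -expected * mult / n2))
    interiors = Counter(word[1 : h - 1])
    for u, mult in interiors.items():
        items.append((u, expected * mult / counts.count(u)))

    var_rate = 0.0
    for (s, a_s), (t, a_t) in itertools.product(items, items):
        var_rate += a_s * a_t * _pair_cov_rate(s, t, p, pi, zmi)
    var = n * var_rate
    if var < 0:
        # numerically tiny negative values can occur when the statistic is
        # degenerate; clamp
        var = max(var, 0.0)
    return math.sqrt(var)


# ---------------------------------------------------------------------------
# scores, p-values, scans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExceptionalityResult:
    """Observed vs M1-expected count of one word (or pattern aggregate)."""

    word: str
    observed: int
    expected: float
    sd: float
    score: float
    pvalue: float

    @property
    def log10_pvalue_order(self) -> int | None:
        if not np.isfinite(self.pvalue) or self.pvalue <= 0:
            return None
        return round(math.log10(self.pvalue))


def score_to_pvalue(z: float) -> float:
    """Two-sided standard-normal p-value of an exceptionality score."""
    if not np.isfinite(z):
        return float("nan")
    return float(2.0 * stats.norm.sf(abs(z)))


def pvalue_order_of_magnitude(p: float) -> int:
    """round(log10 p): -6 for a score of 5, -23 for a score of 10."""
    if not (np.isfinite(p) and p > 0):
        raise ValueError("p must be a finite positive probability")
    return round(math.log10(p))


def exceptionality_score(word: str, counts: WordCounts) -> ExceptionalityResult:
    """z-score and p-value of a word's count under the M1 background."""
    word = word.upper()
    observed = counts.count(word)
    expected = m1_expected(word, counts)
    if not np.isfinite(expected) or expected == 0:
        warnings.warn(f"M1 expectation unavailable for {word!r}; score is NA")
        return ExceptionalityResult(word, observed, expected, float("nan"),
                                    float("nan"), float("nan"))
    if len(word) == 2:
        return ExceptionalityResult(word, observed, expected, 0.0, 0.0, 1.0)
    sd = m1_sigma(word, counts)
    if not np.isfinite(sd) or sd == 0:
        warnings.warn(f"M1 variance unavailable for {word!r}; score is NA")
        return ExceptionalityResult(word, observed, expected, sd,
                                    float("nan"), float("nan"))
    z = (observed - expected) / sd
    return ExceptionalityResult(word, observed, expected, sd, z, score_to_pvalue(z))


def expand_pattern(pattern: str) -> list[str]:
    """All concrete ACGT words matching a fixed-length pattern over ACGTN."""
    pattern = pattern.upper()
    if not pattern or any(ch not in BASES + "N" for ch in pattern):
        raise ValueError(f"pattern must be non-empty over ACGTN, got {pattern!r}")
    choices = [BASES if ch == "N" else ch for ch in pattern]
    return ["".join(w) for w in itertools.product(*choices)]


def scan_words(
    sequences: str | list[str] | WordCounts, pattern: str
) -> tuple[list[ExceptionalityResult], ExceptionalityResult]:
    """Score every concrete word matching ``pattern`` plus an aggregate.

    The aggregate compares summed observed against summed expected counts;
    its variance is approximated by the sum of per-word variances.
    """
    words = expand_pattern(pattern)
    h = len(pattern)
    counts = sequences if isinstance(sequences, WordCounts) else count_words(sequences, h)
    if counts.h < h:
        raise ValueError(f"counts only cover words up to length {counts.h}")
    results = [exceptionality_score(w, counts) for w in words]
    obs = sum(r.observed for r in results)
    finite = [r for r in results if np.isfinite(r.expected)]
    exp = sum(r.expected for r in finite)
    var = sum(r.sd**2 for r in finite if np.isfinite(r.sd))
    if var > 0 and exp > 0:
        z = (obs - exp) / math.sqrt(var)
        agg = ExceptionalityResult(pattern, obs, exp, math.sqrt(var), z, score_to_pvalue(z))
    else:
        agg = ExceptionalityResult(pattern, obs, exp, float("nan"),
                                   float("nan"), float("nan"))
    return results, agg


# ---------------------------------------------------------------------------
# M1 sequence simulation (oracle support and null calibration)
# ---------------------------------------------------------------------------

def fit_m1(sequence: str | list[str]) -> tuple[np.ndarray, np.ndarray]:
    """(P, pi) of the first-order Markov chain fitted to a sequence set."""
    return _transition_matrix(count_words(sequence, 2))


def simulate_markov_states(
    p: np.ndarray, pi: np.ndarray, length: int, n_sequences: int, seed: int
) -> np.ndarray:
    """Simulate first-order Markov chains as an (n_sequences, length) array
    of base indices into ACGT (vectorized across sequences)."""
    rng = np.random.default_rng(seed)
    cum_pi = np.cumsum(pi)
    cum_p = np.cumsum(p, axis=1)
    states = np.empty((n_sequences, length), dtype=np.int8)
    states[:, 0] = np.searchsorted(cum_pi, rng.random(n_sequences))
    for j in range(1, length):
        u = rng.random(n_sequences)
        rows = cum_p[states[:, j - 1]]
        states[:, j] = (u[:, None] > rows).sum(axis=1)
    return states


def simulate_markov(
    p: np.ndarray, pi: np.ndarray, length: int, n_sequences: int, seed: int
) -> list[str]:
    """Simulate sequences from a first-order Markov chain."""
    states = simulate_markov_states(p, pi, length, n_sequences, seed)
    alphabet = np.array(list(BASES))
    return ["".join(row) for row in alphabet[states]]


# ---------------------------------------------------------------------------
# CpG-island metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IslandMetrics:
    """GC fraction, observed/expected CpG ratio and the island verdict."""

    gc_fraction: float
    obs_exp_cpg: float
    is_island: bool


def island_metrics(sequence: str) -> IslandMetrics:
    """Operational CpG-island metrics: GC > 0.55 and obs/exp CpG > 0.8.

    The observed/expected ratio is N(CG) * L / (N(C) * N(G)); it is NA (and
    the verdict false) when the sequence lacks C or G.
    """
    seq = sequence.upper()
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    L = len(seq)
    n_c = seq.count("C")
    n_g = seq.count("G")
    gc = (n_c + n_g) / L
    if n_c == 0 or n_g == 0:
        return IslandMetrics(gc, float("nan"), False)
    n_cg = sum(1 for i in range(L - 1) if seq[i : i + 2] == "CG")
    ratio = n_cg * L / (n_c * n_g)
    return IslandMetrics(gc, ratio, gc > 0.55 and ratio > 0.8)
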