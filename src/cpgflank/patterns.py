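"""Per-site methylation pattern statistics.

Everything downstream of the call matrix: per-site efficiencies and ranks,
replicate/strand rank correlations, fold ranges, hot/cold decile selection,
flank extraction and orientation alignment, positional chi-square enrichment
with sequence-logo information content, DNMT3L fold-stimulation analysis and
the molecule-level one-tailed stimulation t-test.

Conventions
-----------
Ranks are descending in efficiency (rank 1 = most methylated) with average
ranks for ties.  Ratio computations (fold range, fold stimulation) use a
Haldane pseudocount (m + 0.5) / (n + 1) for zero-count sites only; reported
efficiencies are never pseudocounted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .calling import MethylationCallMatrix
from .regions import ReferenceRegion, reverse_complement

BASES = "ACGT"


# ---------------------------------------------------------------------------
# site efficiencies, ranks, correlations
# ---------------------------------------------------------------------------

def site_efficiencies(
    matrix: MethylationCallMatrix,
    strand: str | None = None,
    dcm_class: str | None = None,
    require_pass: bool = True,
    n_min: int = 10,
) -> pd.DataFrame:
    """Per-site methylated / informative counts and efficiencies for a stratum.

    Returns a DataFrame with columns position, m, n, efficiency and low_n
    (fewer than ``n_min`` informative calls).  The stratum-wide efficiency
    sum(m)/sum(n) is stored in ``df.attrs["overall"]``.
    """
    df = matrix.df
    label = []
    if require_pass:
        df = df[df["pass_filter"]]
        label.append("pass_filter")
    if strand is not None:
        df = df[df["strand"] == strand]
        label.append(f"strand={strand}")
    if dcm_class is not None:
        df = df[df["dcm_class"] == dcm_class]
        label.append(f"dcm_class={dcm_class}")
    if len(df) == 0:
        raise ValueError(
            f"empty stratum ({', '.join(label) or 'all molecules'}) "
            f"for region {matrix.region_name!r}"
        )
    calls = df[matrix.site_columns]
    m = calls.sum(axis=0, skipna=True).to_numpy()
    n = calls.notna().sum(axis=0).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        eff = np.where(n > 0, m / np.maximum(n, 1), np.nan)
    out = pd.DataFrame(
        {
            "position": matrix.sites,
            "m": m.astype(int),
            "n": n.astype(int),
            "efficiency": eff,
            "low_n": n < n_min,
        }
    )
    total_n = int(n.sum())
    out.attrs["overall"] = float(m.sum() / total_n) if total_n else float("nan")
    out.attrs["region"] = matrix.region_name
    return out


def rank_sites(table: pd.DataFrame) -> pd.DataFrame:
    """Add descending-efficiency ranks (1 = most methylated; ties averaged)."""
    out = table.copy()
    out["rank"] = stats.rankdata(-out["efficiency"].to_numpy(), method="average")
    return out


def relative_efficiencies(table: pd.DataFrame) -> pd.DataFrame:
    """Add per-site efficiency relative to the region mean (averages to 1)."""
    out = table.copy()
    mean = out["efficiency"].mean()
    if not mean > 0:
        raise ValueError("mean efficiency is zero; relative efficiencies undefined")
    out["relative_efficiency"] = out["efficiency"] / mean
    return out


def rank_correlation(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> tuple[float, float]:
    """(signed r, r^2) of the Pearson correlation on rank vectors.

    Equals the squared Spearman correlation of the efficiencies; requires at
    least 3 shared sites with rank variance on both sides.
    """
    merged = table_a.merge(table_b, on="position", suffixes=("_a", "_b"))
    if len(merged) < 3:
        warnings.warn("fewer than 3 shared sites; rank correlation is NA")
        return float("nan"), float("nan")
    ra = stats.rankdata(-merged["efficiency_a"].to_numpy(), method="average")
    rb = stats.rankdata(-merged["efficiency_b"].to_numpy(), method="average")
    if np.ptp(ra) == 0 or np.ptp(rb) == 0:
        warnings.warn("zero rank variance; rank correlation is NA")
        return float("nan"), float("nan")
    r = float(stats.pearsonr(ra, rb).statistic)
    return r, r * r


def strand_symmetry(
    top_table: pd.DataFrame, bottom_table: pd.DataFrame
) -> dict:
    """Pearson correlation of per-site efficiencies across the two strands."""
    merged = top_table.merge(
        bottom_table, on="position", suffixes=("_top", "_bottom")
    )
    if len(merged) < 3:
        warnings.warn("fewer than 3 shared sites; strand symmetry is NA")
        return {"r": float("nan"), "pvalue": float("nan"), "pairs": merged}
    x = merged["efficiency_top"].to_numpy()
    y = merged["efficiency_bottom"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero efficiency variance; strand symmetry is NA")
        return {"r": float("nan"), "pvalue": float("nan"), "pairs": merged}
    res = stats.pearsonr(x, y)
    return {"r": float(res.statistic), "pvalue": float(res.pvalue), "pairs": merged}


# ---------------------------------------------------------------------------
# fold ratios
# ---------------------------------------------------------------------------

def _ratio_efficiencies(table: pd.DataFrame) -> np.ndarray:
    """Efficiencies for ratio computations: Haldane-adjust zero-count sites."""
    e = table["efficiency"].to_numpy(dtype=float).copy()
    if "m" in table.columns and "n" in table.columns:
        m = table["m"].to_numpy(dtype=float)
        n = table["n"].to_numpy(dtype=float)
        zero = (m == 0) & (n > 0)
        e[zero] = (m[zero] + 0.5) / (n[zero] + 1.0)
    return e


def fold_range(table: pd.DataFrame, n_min: int = 0) -> dict:
    """Highest / lowest per-site efficiency ratio over usable sites.

    Sites with fewer than ``n_min`` informative calls are excluded when
    counts are present.  Zero-count sites enter through the Haldane
    pseudocount.  Returns the unrounded fold and its nearest integer.
    """
    use = table
    if n_min and "n" in table.columns:
        use = table[table["n"] >= n_min]
    e = _ratio_efficiencies(use)
    e = e[np.isfinite(e)]
    if len(e) < 2:
        raise ValueError("fold range needs at least 2 sites with calls")
    lo = float(np.min(e))
    hi = float(np.max(e))
    if hi == 0:
        warnings.warn("all efficiencies are zero; fold range is NA")
        return {"fold": float("nan"), "fold_int": None, "max": hi, "min": lo}
    fold = hi / lo
    return {"fold": fold, "fold_int": int(round(fold)), "max": hi, "min": lo}


def fold_stimulation(
    table_alone: pd.DataFrame, table_3l: pd.DataFrame
) -> pd.DataFrame:
    """Per-site DNMT3L fold stimulation and its trend against baseline.

    Folds use Haldane-adjusted efficiencies so zero-count baselines stay
    finite.  ``df.attrs`` carries the Spearman trend statistic between the
    baseline efficiency and the fold (negative under saturation-style
    stimulation), its p-value, and the fold ranges before and after.
    """
    a = table_alone.reset_index(drop=True)
    b = table_3l.reset_index(drop=True)
    if list(a["position"]) != list(b["position"]):
        raise ValueError("fold_stimulation requires matched site sets")
    e_alone = _ratio_efficiencies(a)
    e_3l = _ratio_efficiencies(b)
    out = pd.DataFrame(
        {
            "position": a["position"],
            "e_alone": a["efficiency"],
            "e_3l": b["efficiency"],
            "fold": e_3l / e_alone,
        }
    )
    folds = out["fold"].to_numpy()
    if np.ptp(folds[np.isfinite(folds)]) == 0:
        warnings.warn("fold stimulation is constant; trend statistic is NA")
        rho, pval = float("nan"), float("nan")
    else:
        res = stats.spearmanr(e_alone, folds)
        rho, pval = float(res.statistic), float(res.pvalue)
    out.attrs["trend_rho"] = rho
    out.attrs["trend_pvalue"] = pval
    out.attrs["fold_range_before"] = fold_range(a)["fold"]
    out.attrs["fold_range_after"] = fold_range(b)["fold"]
    return out


# ---------------------------------------------------------------------------
# hot / cold site selection and flank extraction
# ---------------------------------------------------------------------------

def select_extremes(
    table: pd.DataFrame, fraction: float = 0.10, n_min: int = 10
) -> tuple[list[int], list[int]]:
    """Top and bottom ``ceil(fraction * N)`` site positions by efficiency.

    Ties at the cut break by efficiency then ascending position; the two sets
    are kept disjoint (the cold set shrinks when the region is too small to
    hold two full deciles).
    """
    if not 0.0 < fraction <= 0.5:
        raise ValueError("fraction must lie in (0, 0.5]")
    use = table
    if n_min and "n" in table.columns:
        use = table[table["n"] >= n_min]
    use = use[np.isfinite(use["efficiency"])]
    n_sites = len(use)
    if n_sites < 2:
        raise ValueError("need at least 2 usable sites to select extremes")
    m = math.ceil(fraction * n_sites)
    hot_order = use.sort_values(
        ["efficiency", "position"], ascending=[False, True], kind="mergesort"
    )
    hot = list(hot_order["position"].iloc[:m])
    remaining = use[~use["position"].isin(hot)]
    cold_order = remaining.sort_values(
        ["efficiency", "position"], ascending=[True, True], kind="mergesort"
    )
    cold = list(cold_order["position"].iloc[: min(m, n_sites - m)])
    return hot, cold


@dataclass(frozen=True)
class Flank:
    """One extracted flank window: 2k+2 bases with CG in the middle."""

    site: int
    strand: str
    sequence: str
    orientation: str = "direct"  # direct | revcomp

    @property
    def oriented_sequence(self) -> str:
        return (
            self.sequence
            if self.orientation == "direct"
            else reverse_complement(self.sequence)
        )


def extract_flanks(
    region: ReferenceRegion, sites: list[int], strand: str, k: int = 2
) -> list[Flank]:
    """Flank windows for the given CpG positions on one strand.

    Sites without k bases of context on each side are excluded with a
    warning (edge sites are never analyzed).
    """
    flanks = []
    for site in sites:
        if not region.has_full_flank(site, k):
            warnings.warn(f"excluding edge CpG site {site}: fewer than {k} flank bases")
            continue
        flanks.append(Flank(site, strand, region.flank_window(site, strand, k)))
    return flanks


def _pfm(seqs: list[str], pseudocount: float = 0.5) -> np.ndarray:
    """Position frequency matrix (positions x 4) with pseudocounts."""
    length = len(seqs[0])
    counts = np.full((length, 4), pseudocount)
    for s in seqs:
        for i, b in enumerate(s):
            counts[i, BASES.index(b)] += 1
    return counts / counts.sum(axis=1, keepdims=True)


def _log_likelihood(seq: str, pfm: np.ndarray) -> float:
    return float(sum(np.log(pfm[i, BASES.index(b)]) for i, b in enumerate(seq)))


def orient_flanks(
    flanks: list[Flank], max_iter: int = 20
) -> tuple[list[Flank], bool]:
    """Assign direct / reverse-complement orientations by fixed-point matching.

    Starting from all-direct, a position frequency matrix (+0.5 pseudocounts)
    is built from the currently oriented sequences; any flank whose reverse
    complement scores a higher log-likelihood under the matrix is flipped;
    the matrix is rebuilt and the step repeated to a fixed point.  Ties keep
    the direct orientation.  Returns the oriented set and a convergence flag.
    """
    if not flanks:
        raise ValueError("orient_flanks requires at least one flank")
    current = [replace(f, orientation="direct") for f in flanks]
    for _ in range(max_iter):
        pfm = _pfm([f.oriented_sequence for f in current])
        updated = []
        changed = False
        for f in current:
            ll_direct = _log_likelihood(f.sequence, pfm)
            ll_rc = _log_likelihood(reverse_complement(f.sequence), pfm)
            orientation = "revcomp" if ll_rc > ll_direct else "direct"
            if orientation != f.orientation:
                changed = True
            updated.append(replace(f, orientation=orientation))
        current = updated
        if not changed:
            return current, True
    warnings.warn(f"flank orientation did not converge in {max_iter} iterations")
    return current, False


# ---------------------------------------------------------------------------
# positional enrichment
# ---------------------------------------------------------------------------

def pooled_background(
    regions: ReferenceRegion | list[ReferenceRegion], k: int = 2
) -> dict[str, float]:
    """Base composition pooled over the +/-k flank windows of all CpG sites.

    Both strands are pooled (so the composition is reverse-complement
    symmetric), conditioning the background on CpG context rather than on
    whole-region composition.
    """
    if isinstance(regions, ReferenceRegion):
        regions = [regions]
    counts = dict.fromkeys(BASES, 0)
    for region in regions:
        for strand in ("top", "bottom"):
            for f in extract_flanks(region, region.cpg_sites, strand, k):
                w = f.sequence
                for b in w[:k] + w[k + 2 :]:  # flank bases only, not the CG
                    counts[b] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no flank bases available for background composition")
    return {b: counts[b] / total for b in BASES}


def position_enrichment(
    flanks: list[Flank] | list[str],
    background: dict[str, float],
) -> pd.DataFrame:
    """Per-(offset, base) chi-square enrichment plus logo information content.

    For each offset in -k..-1, +1..+k and each base, a 1-df base-versus-rest
    chi-square compares the observed count against N * q_base from the
    background composition (no Yates correction); the direction column says
    whether the base is enriched or depleted.  Per offset, the information
    content is 2 - H(observed base frequencies) in bits and letter heights
    are frequency * IC, the usual sequence-logo scaling (2 bits = perfect
    conservation).  A Bonferroni column corrects across all 4 * 2k cells.
    """
    if not flanks:
        raise ValueError("position_enrichment requires at least one flank")
    seqs = [f.oriented_sequence if isinstance(f, Flank) else f for f in flanks]
    length = len(seqs[0])
    if length % 2 != 0 or length < 4:
        raise ValueError("flank windows must have even length 2k+2 >= 4")
    if any(len(s) != length for s in seqs):
        raise ValueError("all flanks must have the same length")
    k = (length - 2) // 2
    if abs(sum(background.get(b, 0.0) for b in BASES) - 1.0) > 1e-6:
        raise ValueError("background frequencies must sum to 1")
    n = len(seqs)
    if n < 5:
        warnings.warn(f"only {n} flanks; enrichment statistics will be unstable")

    offsets = [o for o in range(-k, k + 1) if o != 0]
    rows = []
    n_cells = 4 * len(offsets)
    for offset in offsets:
        col = k + offset if offset < 0 else k + 1 + offset
        obs_bases = [s[col] for s in seqs]
        counts = {b: obs_bases.count(b) for b in BASES}
        freqs = np.array([counts[b] / n for b in BASES])
        nonzero = freqs[freqs > 0]
        ic = 2.0 + float(np.sum(nonzero * np.log2(nonzero)))
        ic = min(max(ic, 0.0), 2.0)
        for b in BASES:
            q = background.get(b, 0.0)
            if q <= 0 and counts[b] > 0:
                raise ValueError(
                    f"background frequency for observed base {b!r} is zero"
                )
            o = counts[b]
            e = n * q
            if 0 < e < n:
                x2 = (o - e) ** 2 / e + (o - e) ** 2 / (n - e)
                p = float(stats.chi2.sf(x2, df=1))
            else:
                x2, p = 0.0, 1.0
            rows.append(
                {
                    "offset": offset,
                    "base": b,
                    "observed": o,
                    "expected": e,
                    "chi2": x2,
                    "pvalue": p,
                    "p_bonferroni": min(1.0, p * n_cells),
                    "direction": "enriched" if o >= e else "depleted",
                    "ic_bits": ic,
                    "letter_height": counts[b] / n * ic,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["n_flanks"] = n
    out.attrs["k"] = k
    return out


def logo_matrix(enrichment: pd.DataFrame) -> pd.DataFrame:
    """Offset x base letter-height matrix (bits) for logo plotting."""
    return enrichment.pivot(index="offset", columns="base", values="letter_height")


def top_cell(enrichment: pd.DataFrame, direction: str = "enriched") -> pd.Series:
    """Most significant cell in the requested direction (smallest p-value)."""
    sub = enrichment[enrichment["direction"] == direction]
    if sub.empty:
        raise ValueError(f"no {direction} cells in enrichment table")
    return sub.loc[sub["pvalue"].idxmin()]


# ---------------------------------------------------------------------------
# molecule-level stimulation test
# ---------------------------------------------------------------------------

def molecule_efficiencies(
    matrix: MethylationCallMatrix,
    strand: str | None = None,
    dcm_class: str | None = None,
    require_pass: bool = True,
) -> np.ndarray:
    """Overall methylation efficiency of each molecule in a stratum."""
    df = matrix.df
    if require_pass:
        df = df[df["pass_filter"]]
    if strand is not None:
        df = df[df["strand"] == strand]
    if dcm_class is not None:
        df = df[df["dcm_class"] == dcm_class]
    calls = df[matrix.site_columns]
    return calls.mean(axis=1, skipna=True).to_numpy(dtype=float)


def significance_stars(p: float) -> str:
    """Star category for a one-tailed stimulation p-value (ns/*/**/***)."""
    if not np.isfinite(p):
        return "NA"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def group_stimulation_test(
    eff_alone: np.ndarray, eff_3l: np.ndarray
) -> dict:
    """One-tailed two-sample Student t-test for DNMT3L stimulation.

    The unit of analysis is the per-molecule overall efficiency; the
    alternative is that the +DNMT3L group mean exceeds the alone group mean.
    Returns the t statistic, p-value and the star category.
    """
    a = np.asarray(eff_alone, dtype=float)
    b = np.asarray(eff_3l, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 molecules")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        warnings.warn("degenerate variance in both groups; t-test is NA")
        return {"t": float("nan"), "pvalue": float("nan"), "stars": "NA",
                "mean_alone": float(a.mean()), "mean_3l": float(b.mean())}
    res = stats.ttest_ind(b, a, equal_var=True, alternative="greater")
    p = float(res.pvalue)
    return {
        "t": float(res.statistic),
        "pvalue": p,
        "stars": significance_stars(p),
        "mean_alone": float(a.mean()),
        "mean_3l": float(b.mean()),
    }
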