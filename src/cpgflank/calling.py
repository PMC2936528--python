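"""Methylation calling from bisulfite clone reads.

Converts gaplessly aligned clone reads plus a reference into a per-molecule,
per-CpG call matrix with conversion-efficiency filtering, strand assignment
and dcm+/dcm- classification.

Reads must match the reference length (trimmed, gapless alignment); reads
sequenced from the bottom strand may be supplied in either orientation and
are re-oriented into top-strand coordinates before calling.  In top-strand
coordinates, bisulfite conversion of the top strand shows reference C
positions as T, while conversion of the bottom strand shows reference G
positions as A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import ReferenceRegion, reverse_complement

#: Values used in the call matrix: 1 methylated, 0 unmethylated, NaN missing.
CALL_METHYLATED = 1.0
CALL_UNMETHYLATED = 0.0

META_COLUMNS = ["molecule_id", "strand", "dcm_class", "conversion_efficiency", "pass_filter"]


@dataclass
class MethylationCallMatrix:
    """Molecules x CpG sites call table for one region.

    ``df`` holds one row per molecule with metadata columns plus one column
    per CpG site (named by its top-strand C position as a string); calls are
    1.0 (methylated), 0.0 (unmethylated) or NaN (missing).
    """

    region_name: str
    sites: list[int]
    df: pd.DataFrame = field(repr=False)

    @property
    def site_columns(self) -> list[str]:
        return [str(p) for p in self.sites]

    def calls(self) -> pd.DataFrame:
        """The numeric call block only (rows = molecules, columns = sites)."""
        return self.df[self.site_columns]

    def passing(self) -> pd.DataFrame:
        return self.df[self.df["pass_filter"]]

    def __len__(self) -> int:
        return len(self.df)


def orient_read(read: str, region: ReferenceRegion) -> tuple[str, bool]:
    """Return the read in top-strand coordinates plus a flipped flag.

    Scores both orientations by compatibility with bisulfite chemistry
    (match, ref C seen as T, or ref G seen as A count as compatible) and
    keeps the better one; ties keep the read as given.
    """
    if len(read) != len(region.sequence):
        raise ValueError(
            f"read length {len(read)} != reference length {len(region.sequence)}"
        )

    def score(r: str) -> int:
        return sum(
            1
            for ref, obs in zip(region.sequence, r)
            if obs == ref or (ref == "C" and obs == "T") or (ref == "G" and obs == "A")
        )

    rc = reverse_complement(read)
    return (rc, True) if score(rc) > score(read) else (read, False)


def assign_strand(read: str, region: ReferenceRegion) -> str | None:
    """Strand whose conversion pattern better explains a top-coordinate read.

    Counts reference-C positions read as T (top-strand evidence) against
    reference-G positions read as A (bottom-strand evidence); the larger
    count wins.  A tie, or two zero counts, returns None with a warning.
    """
    if len(read) != len(region.sequence):
        raise ValueError("read must be gaplessly aligned to the reference (same length)")
    top_ev = sum(1 for ref, obs in zip(region.sequence, read) if ref == "C" and obs == "T")
    bot_ev = sum(1 for ref, obs in zip(region.sequence, read) if ref == "G" and obs == "A")
    if top_ev == bot_ev:
        warnings.warn(
            f"strand assignment ambiguous (top evidence {top_ev}, bottom {bot_ev})",
            stacklevel=2,
        )
        return None
    return "top" if top_ev > bot_ev else "bottom"


def _eligible_positions(region: ReferenceRegion, strand: str) -> list[int]:
    """Top-coordinate positions of conversion-eligible cytosines on a strand.

    Eligible = cytosines of that strand outside CpG context and outside Dcm
    (CCWGG) context: a dcm+ strand legitimately retains C there, and counting
    those as unconverted would wrongly fail the conversion filter.
    """
    if strand == "top":
        excluded = set(region.cpg_sites) | set(region.dcm_sites_top)
        return [i for i, b in enumerate(region.sequence) if b == "C" and i not in excluded]
    # bottom-strand cytosines sit opposite top-strand Gs; the CpG cytosine of
    # the bottom strand is opposite the G at (site + 1)
    excluded = {p + 1 for p in region.cpg_sites} | set(region.dcm_sites_bottom)
    return [i for i, b in enumerate(region.sequence) if b == "G" and i not in excluded]


def call_molecule(read: str, region: ReferenceRegion, strand: str) -> dict:
    """Per-site calls plus conversion and dcm-retention tallies for one read.

    The read must be in top-strand coordinates.  At each CpG site a retained
    C (top) or retained G (bottom) is called methylated, the converted base
    (T / A) unmethylated, anything else missing.
    """
    if len(read) != len(region.sequence):
        raise ValueError("read must be gaplessly aligned to the reference (same length)")
    if strand not in ("top", "bottom"):
        raise ValueError(f"unknown strand {strand!r}")

    retained, converted = ("C", "T") if strand == "top" else ("G", "A")
    calls: dict[str, float] = {}
    for pos in region.cpg_sites:
        obs = read[pos] if strand == "top" else read[pos + 1]
        if obs == retained:
            calls[str(pos)] = CALL_METHYLATED
        elif obs == converted:
            calls[str(pos)] = CALL_UNMETHYLATED
        else:
            calls[str(pos)] = np.nan

    eligible = _eligible_positions(region, strand)
    n_conv = sum(1 for i in eligible if read[i] == converted)
    n_obs = sum(1 for i in eligible if read[i] in (retained, converted))

    dcm_positions = region.dcm_sites_top if strand == "top" else region.dcm_sites_bottom
    cpg_context = set(region.cpg_sites) | {p + 1 for p in region.cpg_sites}
    dcm_positions = [p for p in dcm_positions if p not in cpg_context]  # CpG precedence
    dcm_retained = sum(1 for i in dcm_positions if read[i] == retained)
    dcm_observed = sum(1 for i in dcm_positions if read[i] in (retained, converted))

    return {
        "strand": strand,
        "calls": calls,
        "n_eligible": n_obs,
        "n_converted": n_conv,
        "n_dcm_sites": dcm_observed,
        "n_dcm_retained": dcm_retained,
    }


def conversion_efficiency(row: dict | pd.Series) -> float:
    """Converted / eligible cytosines for one molecule; NaN if none eligible."""
    n_eligible = row["n_eligible"]
    if n_eligible == 0:
        warnings.warn("molecule has no eligible cytosines; conversion efficiency is NA")
        return float("nan")
    return row["n_converted"] / n_eligible


def classify_dcm(row: dict | pd.Series, retention_threshold: float = 0.5) -> str:
    """dcm+ / dcm- / NA from the fraction of Dcm-site cytosines retained as C."""
    n = row["n_dcm_sites"]
    if n == 0:
        return "NA"
    return "dcm+" if row["n_dcm_retained"] / n >= retention_threshold else "dcm-"


def filter_molecules(
    matrix: MethylationCallMatrix, threshold: float = 0.95
) -> MethylationCallMatrix:
    """Set ``pass_filter`` from the conversion-efficiency threshold (inclusive).

    The study filter was "no less than 95% conversion", read as inclusive;
    molecules with NA efficiency never pass.
    """
    df = matrix.df.copy()
    eff = df["conversion_efficiency"]
    df["pass_filter"] = eff.notna() & (eff >= threshold)
    return MethylationCallMatrix(matrix.region_name, list(matrix.sites), df)


def call_clones(
    reads: list[tuple[str, str]],
    region: ReferenceRegion,
    conversion_threshold: float = 0.95,
    dcm_retention_threshold: float = 0.5,
) -> MethylationCallMatrix:
    """Full calling stage: orient, assign strand, call, classify, filter.

    ``reads`` is a list of (id, sequence) pairs gaplessly matched to the
    reference.  Molecules with ambiguous strand or no eligible cytosines are
    dropped with a warning; no silent drops.
    """
    rows = []
    for read_id, seq in reads:
        seq = seq.upper()
        oriented, _ = orient_read(seq, region)
        strand = assign_strand(oriented, region)
        if strand is None:
            warnings.warn(f"dropping read {read_id!r}: ambiguous strand")
            continue
        res = call_molecule(oriented, region, strand)
        if res["n_eligible"] == 0:
            warnings.warn(f"dropping read {read_id!r}: no eligible cytosines")
            continue
        row = {
            "molecule_id": read_id,
            "strand": strand,
            "dcm_class": classify_dcm(res, dcm_retention_threshold),
            "conversion_efficiency": res["n_converted"] / res["n_eligible"],
            "pass_filter": False,
            **res["calls"],
        }
        rows.append(row)
    columns = META_COLUMNS + [str(p) for p in region.cpg_sites]
    df = pd.DataFrame(rows, columns=columns)
    matrix = MethylationCallMatrix(region.name, list(region.cpg_sites), df)
    return filter_molecules(matrix, conversion_threshold)
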