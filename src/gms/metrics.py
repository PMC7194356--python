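"""Panel and result statistics: map spacing, composition, PIC, concordance.

Map spacing summaries follow the convention used for published wheat SNP
panel overviews: per chromosome, markers are sorted by cM position, gaps are
the successive differences, the per-chromosome average is the mean gap, and
the panel-wide average spacing is the *unweighted* mean of the per-chromosome
averages.  Polymorphic information content is computed in two forms — the
expected-heterozygosity form 1 - sum(p_j^2) (biallelic maximum 0.50, the
primary value reported) and the full Botstein et al. expression
1 - sum(p_j^2) - sum_{j<k} 2 p_j^2 p_k^2 (biallelic maximum 0.375).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING_CALLS = {"-", "", "missing", "NA", "nan"}
HET_CALLS = {"het"}


class MetricsError(ValueError):
    pass


# -- genetic-map summaries ----------------------------------------------------


@dataclass(frozen=True)
class ChromosomeSummary:
    """Per-chromosome map metrics; gap fields are 0 for single-marker maps."""

    chromosome: str
    n_markers: int
    avg_gap_cM: float
    largest_gap_cM: float


@dataclass(frozen=True)
class PanelAggregates:
    total_markers: int
    mean_markers_per_chromosome: float
    mean_avg_gap_cM: float
    max_largest_gap_cM: float


@dataclass
class GeneticMap:
    """marker_id -> (chromosome, cM position)."""

    entries: dict[str, tuple[str, float]]

    def __post_init__(self) -> None:
        bad = {
            m: p for m, (_, p) in self.entries.items() if not np.isfinite(p) or p < 0
        }
        if bad:
            raise MetricsError(f"non-finite or negative cM positions: {bad}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chromosome": str})
        return cls(
            entries={
                r.marker_id: (r.chromosome, float(r.cM)) for r in df.itertuples()
            }
        )


def chromosome_summary(
    gmap: GeneticMap,
) -> tuple[list[ChromosomeSummary], PanelAggregates]:
    """Per-chromosome marker counts and gap statistics, plus panel aggregates.

    Single-marker chromosomes have undefined gaps; they report 0 and are
    excluded from the gap aggregates.  Invariant to marker input order.
    """
    if not gmap.entries:
        raise MetricsError("empty genetic map")
    by_chrom: dict[str, list[float]] = {}
    for _, (chrom, pos) in gmap.entries.items():
        by_chrom.setdefault(chrom, []).append(pos)
    summaries = []
    for chrom in sorted(by_chrom):
        positions = sorted(by_chrom[chrom])
        if len(positions) < 2:
            summaries.append(ChromosomeSummary(chrom, len(positions), 0.0, 0.0))
            continue
        gaps = np.diff(positions)
        summaries.append(
            ChromosomeSummary(
                chrom, len(positions), float(gaps.mean()), float(gaps.max())
            )
        )
    return summaries, aggregate_summaries(summaries)


def aggregate_summaries(summaries: Sequence[ChromosomeSummary]) -> PanelAggregates:
    """Panel-wide aggregates from per-chromosome rows (printed or computed)."""
    if not summaries:
        raise MetricsError("no chromosome summaries")
    multi = [s for s in summaries if s.n_markers >= 2]
    return PanelAggregates(
        total_markers=sum(s.n_markers for s in summaries),
        mean_markers_per_chromosome=float(
            np.mean([s.n_markers for s in summaries])
        ),
        mean_avg_gap_cM=float(np.mean([s.avg_gap_cM for s in multi])) if multi else 0.0,
        max_largest_gap_cM=max((s.largest_gap_cM for s in multi), default=0.0),
    )


def summarize_panel_rows(rows: pd.DataFrame) -> PanelAggregates:
    """Aggregates from a table of precomputed per-chromosome summaries.

    Expects columns chromosome / n_markers / avg_gap_cM / largest_gap_cM
    (the layout of a published panel-overview table ingested as data).
    """
    summaries = [
        ChromosomeSummary(
            str(r.chromosome),
            int(r.n_markers),
            float(r.avg_gap_cM),
            float(r.largest_gap_cM),
        )
        for r in rows.itertuples()
    ]
    return aggregate_summaries(summaries)


def load_reference_panel_summary() -> pd.DataFrame:
    """The packaged 21-chromosome wheat panel overview table."""
    with resources.files("gms.data").joinpath(
        "wheat_panel_map_summary.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def summaries_to_frame(
    summaries: Sequence[ChromosomeSummary], aggregates: PanelAggregates
) -> pd.DataFrame:
    rows = [
        {
            "chromosome": s.chromosome,
            "n_markers": s.n_markers,
            "avg_gap_cM": round(s.avg_gap_cM, 2),
            "largest_gap_cM": round(s.largest_gap_cM, 2),
        }
        for s in summaries
    ]
    rows += [
        {"chromosome": "total_markers", "n_markers": aggregates.total_markers},
        {
            "chromosome": "mean_markers_per_chromosome",
            "n_markers": round(aggregates.mean_markers_per_chromosome, 2),
        },
        {
            "chromosome": "mean_avg_gap_cM",
            "n_markers": round(aggregates.mean_avg_gap_cM, 2),
        },
        {
            "chromosome": "max_largest_gap_cM",
            "n_markers": round(aggregates.max_largest_gap_cM, 2),
        },
    ]
    return pd.DataFrame(rows)


# -- panel composition --------------------------------------------------------


@dataclass(frozen=True)
class PanelComposition:
    wheat: int
    barley: int
    kim: int
    homoeoalleles: int
    paralogs: int

    @property
    def base_total(self) -> int:
        """Markers in the designed panel (wheat + barley + KIM)."""
        return self.wheat + self.barley + self.kim

    @property
    def data_points(self) -> int:
        """Scorable loci: designed markers plus co-amplified off-targets."""
        return self.base_total + self.homoeoalleles + self.paralogs


def panel_totals(
    wheat: int, barley: int, kim: int, homoeoalleles: int = 0, paralogs: int = 0
) -> PanelComposition:
    counts = (wheat, barley, kim, homoeoalleles, paralogs)
    if any(c < 0 for c in counts):
        raise MetricsError(f"negative marker counts: {counts}")
    return PanelComposition(*counts)


# -- polymorphic information content ------------------------------------------


@dataclass(frozen=True)
class PICResult:
    marker_id: str
    frequencies: tuple[float, ...]
    pic_botstein: float
    pic_het: float
    n_scored: int


def pic_from_frequencies(freqs: Sequence[float]) -> tuple[float, float]:
    """(Botstein PIC, expected-heterozygosity PIC) from allele frequencies."""
    p = np.asarray(freqs, dtype=float)
    if p.size and not np.isclose(p.sum(), 1.0):
        raise MetricsError(f"allele frequencies sum to {p.sum()}, not 1")
    het = 1.0 - float(np.sum(p**2))
    cross = sum(2 * p[j] ** 2 * p[k] ** 2 for j, k in combinations(range(len(p)), 2))
    return het - float(cross), het


def allele_frequencies(calls: Sequence[str]) -> dict[str, float] | None:
    """Allele frequencies from one marker's calls.

    Accepts call categories (hom_a / hom_b / het) or SNP-report cells where a
    hom cell is the allele base and a het cell is a two-allele code resolved
    upstream to 'het'.  Hom calls contribute a full unit to their allele, het
    calls half a unit to each; missing calls are excluded listwise.  Returns
    None when every call is missing.
    """
    weights: dict[str, float] = {}
    n = 0
    for call in calls:
        if call in MISSING_CALLS or (isinstance(call, float) and np.isnan(call)):
            continue
        n += 1
        if call in HET_CALLS:
            weights["a"] = weights.get("a", 0) + 0.5
            weights["b"] = weights.get("b", 0) + 0.5
        elif call in {"hom_a", "hom_b"}:
            key = "a" if call == "hom_a" else "b"
            weights[key] = weights.get(key, 0) + 1.0
        else:  # report cells: the observed base itself
            weights[call] = weights.get(call, 0) + 1.0
    if n == 0:
        return None
    return {a: w / n for a, w in weights.items()}


def pic(matrix: pd.DataFrame, *, warn=None) -> list[PICResult]:
    """PIC per marker of a samples x markers genotype matrix.

    Cells may be call categories or SNP-report cells with hets pre-decoded
    to 'het' (see :func:`gms.seedcall.calls_from_report`).  All-missing
    markers are skipped with a warning.
    """
    results = []
    for marker_id in matrix.columns:
        calls = list(matrix[marker_id])
        freqs = allele_frequencies(calls)
        if freqs is None:
            if warn is not None:
                warn(f"marker {marker_id}: all calls missing, skipped")
            continue
        values = tuple(freqs[a] for a in sorted(freqs))
        botstein, het = pic_from_frequencies(values)
        n = sum(
            0 if (c in MISSING_CALLS or (isinstance(c, float) and np.isnan(c))) else 1
            for c in calls
        )
        results.append(PICResult(marker_id, values, botstein, het, n))
    return results


def pic_frame(results: Sequence[PICResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "marker_id": r.marker_id,
                "n_scored": r.n_scored,
                "pic_het": round(r.pic_het, 4),
                "pic_botstein": round(r.pic_botstein, 4),
            }
            for r in results
        ]
    )


# -- concordance --------------------------------------------------------------


@dataclass(frozen=True)
class ConcordanceResult:
    n_compared: int
    n_matching: int
    per_marker: dict[str, float]
    #: discordance class -> count: 'hom_vs_het', 'hom_vs_opposite_hom', 'other'
    discordance_breakdown: dict[str, int]

    @property
    def agreement(self) -> float:
        if self.n_compared == 0:
            raise MetricsError("no comparable calls")
        return self.n_matching / self.n_compared


def _is_missing(cell) -> bool:
    return (
        cell is None
        or (isinstance(cell, float) and np.isnan(cell))
        or str(cell) in MISSING_CALLS
    )


def _classify_discordance(a: str, b: str) -> str:
    het = {"het"}
    homs = {"hom_a", "hom_b"}
    if (a in het) != (b in het):
        return "hom_vs_het"
    if a in homs and b in homs and a != b:
        return "hom_vs_opposite_hom"
    return "other"


def concordance(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame
) -> ConcordanceResult:
    """Agreement between two genotype matrices on their label intersection.

    Cells missing in either matrix are excluded; discordant pairs are
    classified (hom vs het — the signature of homoeoallele mis-clustering on
    array platforms —, opposite homozygotes, other).  Symmetric in its two
    arguments.
    """
    samples = calls_a.index.intersection(calls_b.index)
    markers = calls_a.columns.intersection(calls_b.columns)
    if samples.empty or markers.empty:
        raise MetricsError("genotype matrices share no samples or markers")
    a = calls_a.loc[samples, markers]
    b = calls_b.loc[samples, markers]
    n_compared = 0
    n_matching = 0
    per_marker: dict[str, float] = {}
    breakdown = {"hom_vs_het": 0, "hom_vs_opposite_hom": 0, "other": 0}
    for marker in markers:
        m_compared = 0
        m_matching = 0
        for sample in samples:
            ca, cb = a.at[sample, marker], b.at[sample, marker]
            if _is_missing(ca) or _is_missing(cb):
                continue
            m_compared += 1
            if str(ca) == str(cb):
                m_matching += 1
            else:
                breakdown[_classify_discordance(str(ca), str(cb))] += 1
        n_compared += m_compared
        n_matching += m_matching
        if m_compared:
            per_marker[marker] = m_matching / m_compared
    return ConcordanceResult(n_compared, n_matching, per_marker, breakdown)


def concordance_frame(result: ConcordanceResult) -> pd.DataFrame:
    rows = [
        {"marker_id": m, "agreement": round(v, 4)}
        for m, v in result.per_marker.items()
    ]
    rows.append(
        {"marker_id": "overall", "agreement": round(result.agreement, 4)}
    )
    return pd.DataFrame(rows)
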