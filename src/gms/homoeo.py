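"""Chromosome assignment of co-amplified homoeoalleles and paralogs.

Allopolyploid wheat primer pairs frequently amplify, besides the target
locus, its homoeoallele (the copy on a homoeologous chromosome of another
subgenome) or a paralog elsewhere in the genome.  Nulli-tetrasomic lines —
aneuploid stocks each lacking one chromosome, compensated by extra copies of
a homoeologue — localize these off-target sequences by absence: a sequence
missing from exactly one line, and present in all others, must reside on
that line's absent chromosome.

The calling pipeline is run per line in its relaxed mode (95% identity) so
off-target seeds survive assignment; seeds matching a key at < 100% are the
candidate off-target sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .keyfile import KeyRecord, MarkerPanel
from .seedcall import AssignmentResult, CallingConfig, Seed

#: the 21 chromosomes of hexaploid bread wheat
WHEAT_CHROMOSOMES = tuple(f"{g}{s}" for g in range(1, 8) for s in "ABD")


class HomoeoError(ValueError):
    pass


@dataclass(frozen=True)
class NulliTetraPanel:
    """Aneuploid line set: line_id -> the single chromosome that line lacks."""

    lines: dict[str, str]

    def __post_init__(self) -> None:
        bad = {l: c for l, c in self.lines.items() if c not in WHEAT_CHROMOSOMES}
        if bad:
            raise HomoeoError(f"unknown chromosomes in line panel: {bad}")

    @property
    def chromosomes(self) -> set[str]:
        return set(self.lines.values())

    def lines_missing(self, chromosome: str) -> list[str]:
        """Replicate lines lacking *chromosome* (presence is OR-ed over them)."""
        return [l for l, c in self.lines.items() if c == chromosome]


@dataclass
class PresenceMatrix:
    query_sequence: str
    present: dict[str, bool]  # line_id -> flag
    min_reads: int
    no_data: set[str] = field(default_factory=set)

    @property
    def absent_lines(self) -> list[str]:
        return sorted(l for l, p in self.present.items() if not p)


@dataclass(frozen=True)
class LocusAssignment:
    marker_id: str
    query_sequence: str
    assigned_chromosome: str | None  # None when status != 'assigned'
    status: str  # 'assigned' | 'ambiguous' | 'unassigned' | 'no-data'
    classification: str | None  # 'homoeoallele' | 'paralog' | None
    absent_lines: tuple[str, ...] = ()


def homoeologous_group(chromosome: str) -> str:
    """Group digit of a wheat chromosome name, e.g. '5D' -> '5'."""
    return chromosome[:-1]


def classify_relationship(native: str | None, assigned: str) -> str | None:
    """Homoeoallele when same homoeologous group, another subgenome; else paralog."""
    if native is None:
        return None
    if native == assigned:
        return None  # the target locus itself, not an off-target copy
    if homoeologous_group(native) == homoeologous_group(assigned):
        return "homoeoallele"
    return "paralog"


def collect_offtarget_seeds(
    marker_id: str,
    per_line_assignments: dict[str, AssignmentResult],
    cfg: CallingConfig | None = None,
) -> list[str]:
    """Candidate off-target sequences for one marker across all lines.

    Surviving seeds whose identity against the marker's key lies in
    [identity_threshold, 1.0) — a perfect match is the target locus itself
    and is excluded.  Returned deduplicated, sorted for determinism.
    """
    cfg = cfg or CallingConfig(identity_threshold=0.95)
    queries: set[str] = set()
    for assignment in per_line_assignments.values():
        marker_seeds = assignment.per_marker.get(marker_id)
        if marker_seeds is None:
            continue
        for m in marker_seeds.matches:
            if cfg.identity_threshold <= m.identity < 1.0:
                queries.add(m.seed.sequence)
    return sorted(queries)


def build_presence_matrix(
    query: str,
    per_line_seeds: dict[str, list[Seed]],
    panel: NulliTetraPanel,
    min_reads: int = 2,
) -> PresenceMatrix:
    """Presence/absence of the exact *query* sequence in every line.

    A line is 'present' iff the literal sequence occurs among its seeds with
    count >= *min_reads* (guarding against single-read error coincidences).
    Replicate lines lacking the same chromosome are OR-ed.  Lines in the
    panel with no sequencing data are flagged and assignment is withheld.
    """
    if not query:
        raise HomoeoError("empty query sequence")
    present: dict[str, bool] = {}
    no_data: set[str] = set()
    for line_id in panel.lines:
        if line_id not in per_line_seeds:
            no_data.add(line_id)
            present[line_id] = False
            continue
        count = sum(
            s.count for s in per_line_seeds[line_id] if s.sequence == query
        )
        present[line_id] = count >= min_reads
    # OR replicates sharing a missing chromosome
    for chromosome in panel.chromosomes:
        replicates = panel.lines_missing(chromosome)
        if len(replicates) > 1:
            flag = any(present[l] for l in replicates)
            for l in replicates:
                present[l] = flag
    return PresenceMatrix(
        query_sequence=query, present=present, min_reads=min_reads, no_data=no_data
    )


def assign_chromosome(
    matrix: PresenceMatrix,
    panel: NulliTetraPanel,
    marker: KeyRecord | str | None = None,
) -> LocusAssignment:
    """Infer the query's chromosome from its absence pattern.

    Exactly one line absent -> that line's missing chromosome; none ->
    unassigned (sequence everywhere, uninformative); two or more -> ambiguous.
    Classification against the marker's native chromosome: same homoeologous
    group means homoeoallele, different group means paralog.
    """
    if isinstance(marker, KeyRecord):
        marker_id, native = marker.marker_id, marker.chromosome
    elif isinstance(marker, str):
        marker_id, native = marker, None
    else:
        marker_id, native = "", None
    if matrix.no_data:
        return LocusAssignment(
            marker_id, matrix.query_sequence, None, "no-data", None,
            tuple(matrix.absent_lines),
        )
    absent_chromosomes = sorted({panel.lines[l] for l in matrix.absent_lines})
    if not absent_chromosomes:
        return LocusAssignment(marker_id, matrix.query_sequence, None, "unassigned", None)
    if len(absent_chromosomes) > 1:
        return LocusAssignment(
            marker_id, matrix.query_sequence, None, "ambiguous", None,
            tuple(matrix.absent_lines),
        )
    chromosome = absent_chromosomes[0]
    return LocusAssignment(
        marker_id,
        matrix.query_sequence,
        chromosome,
        "assigned",
        classify_relationship(native, chromosome),
        tuple(matrix.absent_lines),
    )


def assign_all(
    panel: MarkerPanel,
    per_line_assignments: dict[str, AssignmentResult],
    nt_panel: NulliTetraPanel,
    *,
    per_line_seeds: dict[str, list[Seed]] | None = None,
    cfg: CallingConfig | None = None,
    min_reads: int = 2,
) -> list[LocusAssignment]:
    """Full procedure: collect off-target seeds per marker, then locate each.

    ``per_line_assignments`` are the per-line results of the relaxed-identity
    calling run; they supply the candidate off-target queries.  The presence
    search, however, scans each line's *full* dereplicated seed pool
    (``per_line_seeds``): a locus whose depth in one line happens to fall
    below the read-fraction filter must still register as present there, or
    that line would fake a second absence.  When ``per_line_seeds`` is not
    given it is reconstructed from the assignments (surviving + ambiguous +
    unassigned seeds), which is complete only if the fraction filter was
    disabled.  Each off-target seed is resolved independently.
    """
    cfg = cfg or CallingConfig(identity_threshold=0.95)
    if per_line_seeds is None:
        per_line_seeds = {
            line_id: [
                m.seed
                for ms in assignment.per_marker.values()
                for m in ms.matches
            ]
            + assignment.ambiguous
            + assignment.unassigned
            for line_id, assignment in per_line_assignments.items()
        }
    out: list[LocusAssignment] = []
    for record in panel:
        for query in collect_offtarget_seeds(
            record.marker_id, per_line_assignments, cfg
        ):
            matrix = build_presence_matrix(query, per_line_seeds, nt_panel, min_reads)
            out.append(assign_chromosome(matrix, nt_panel, record))
    return out


# -- file I/O -----------------------------------------------------------------


def read_nullitetra_panel(path: str | Path) -> NulliTetraPanel:
    """Load a line panel TSV with columns line_id / missing_chromosome."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("line_id", "missing_chromosome"):
        if col not in df.columns:
            raise HomoeoError(f"line panel {path} lacks column {col!r}")
    return NulliTetraPanel(lines=dict(zip(df["line_id"], df["missing_chromosome"])))


def write_nullitetra_panel(panel: NulliTetraPanel, path: str | Path) -> None:
    pd.DataFrame(
        {
            "line_id": list(panel.lines),
            "missing_chromosome": list(panel.lines.values()),
        }
    ).to_csv(path, sep="\t", index=False)


def write_assignments(assignments: list[LocusAssignment], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "marker_id": a.marker_id,
                "query_seq": a.query_sequence,
                "assigned_chromosome": a.assigned_chromosome or a.status,
                "class": a.classification or "",
                "n_absent_lines": len(a.absent_lines),
            }
            for a in assignments
        ],
        columns=["marker_id", "query_seq", "assigned_chromosome", "class", "n_absent_lines"],
    ).to_csv(path, sep="\t", index=False)
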