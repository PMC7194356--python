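"""Seed-based genotype calling: the GMS pipeline core.

One sample's trimmed reads are dereplicated into *seeds* (unique sequence +
occurrence count, what 100%-identity clustering of equal reads reduces to).
Each seed is scored against every key record with the SNP site excluded from
the identity; seeds are assigned to their best-matching marker at or above
the identity threshold, then a read-fraction filter discards seeds carrying
less than ``min_seed_fraction`` (default 10%, inclusive) of the marker's
assigned reads.  Genotypes are read off the surviving seeds' bases at the
SNP site: both canonical alleles seen -> het, one -> hom, none -> missing.

Identity between a seed and a key is positional (Hamming) when lengths are
equal, and derived from a global pairwise alignment otherwise; in both cases
the column carrying the SNP is excluded, mirroring how the key's ambiguity
code masks the site of interest.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import Align

from .demux import ReadBatch
from .keyfile import ALLELES_TO_AMBIGUITY, KeyRecord, MarkerPanel

logger = logging.getLogger(__name__)

MISSING_CELL = "-"


@dataclass(frozen=True)
class Seed:
    """A dereplicated unique read sequence and its within-sample count."""

    sequence: str
    count: int


@dataclass(frozen=True)
class MatchResult:
    """Identity of a seed against one key, SNP site excluded.

    ``allele_at_snp`` is the seed's base in the column aligned to the key's
    SNP position, or None when that column is a gap.
    """

    marker_id: str
    seed: Seed
    identity: float
    allele_at_snp: str | None


@dataclass(frozen=True)
class GenotypeCall:
    marker_id: str
    sample_id: str
    call: str  # 'hom_a' | 'hom_b' | 'het' | 'missing'
    depth_a: int = 0
    depth_b: int = 0
    total_marker_reads: int = 0

    def cell(self, record: KeyRecord) -> str:
        """SNP-report cell: observed base, IUPAC het code, or '-'."""
        if self.call == "missing":
            return MISSING_CELL
        if self.call == "het":
            return ALLELES_TO_AMBIGUITY[record.alleles]
        return record.alleles[0] if self.call == "hom_a" else record.alleles[1]


@dataclass(frozen=True)
class CallingConfig:
    """Thresholds of the calling pipeline.

    identity_threshold
        Minimum seed/key identity (SNP excluded) for assignment; 1.0 is the
        standard run, 0.95 the relaxed mode used with aneuploid lines.
    min_seed_fraction
        A seed must carry at least this fraction of its marker's assigned
        reads to survive (inclusive boundary).
    min_marker_depth
        Calls with fewer assigned reads are reported missing; set to 0 to
        disable the floor.
    """

    identity_threshold: float = 1.0
    min_seed_fraction: float = 0.10
    min_marker_depth: int = 5
    mask_snp: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold <= 1:
            raise ValueError("identity_threshold must be in (0, 1]")
        if not 0 <= self.min_seed_fraction < 1:
            raise ValueError("min_seed_fraction must be in [0, 1)")
        if self.min_marker_depth < 0:
            raise ValueError("min_marker_depth must be >= 0")


def dereplicate(reads: ReadBatch | list[str]) -> list[Seed]:
    """Collapse reads into unique-sequence seeds with occurrence counts.

    Count conservation: the seed counts sum to the number of input reads.
    Seeds are returned in deterministic order (count descending, then
    sequence) so downstream logs and reports are stable.
    """
    sequences = reads.sequences() if isinstance(reads, ReadBatch) else list(reads)
    counts = Counter(sequences)
    return [
        Seed(sequence=s, count=n)
        for s, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


# -- seed/key identity --------------------------------------------------------

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -1


def match_seed(seed: Seed, record: KeyRecord, cfg: CallingConfig) -> MatchResult:
    """Score one seed against one key record.

    Equal lengths: identity = matching positions / (length - 1), the SNP
    position excluded.  Unequal lengths: identity = matching columns /
    (alignment columns - 1) from a global alignment, the column holding the
    key's SNP excluded; the seed base in that column is the observed allele
    (None if gapped).  With ``mask_snp=False`` the SNP column is scored like
    any other (the key's ambiguity code never equals a seed base, so it
    counts as a mismatch).
    """
    s, key = seed.sequence, record.amplicon
    idx = record.snp_index
    if len(s) == len(key):
        matches = sum(
            1 for i, (a, b) in enumerate(zip(s, key)) if a == b and i != idx
        )
        denom = len(key) - 1 if cfg.mask_snp else len(key)
        identity = matches / denom if denom else 1.0
        return MatchResult(record.marker_id, seed, identity, s[idx])
    return _match_by_alignment(seed, record, cfg)


def _match_by_alignment(
    seed: Seed, record: KeyRecord, cfg: CallingConfig
) -> MatchResult:
    alignment = _aligner.align(record.amplicon, seed.sequence)[0]
    key_row, seed_row = str(alignment[0]), str(alignment[1])
    matches = 0
    columns = 0
    allele: str | None = None
    key_pos = -1
    for k, q in zip(key_row, seed_row):
        if k != "-":
            key_pos += 1
        at_snp = k != "-" and key_pos == record.snp_index
        if at_snp:
            allele = q if q != "-" else None
            if cfg.mask_snp:
                continue
        columns += 1
        if k == q and k != "-":
            matches += 1
    identity = matches / columns if columns else 0.0
    return MatchResult(record.marker_id, seed, identity, allele)


# -- assignment and filtering -------------------------------------------------


@dataclass
class MarkerSeeds:
    """Seeds assigned to one marker within one sample."""

    marker_id: str
    matches: list[MatchResult] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return sum(m.seed.count for m in self.matches)


@dataclass
class AssignmentResult:
    per_marker: dict[str, MarkerSeeds]
    ambiguous: list[Seed] = field(default_factory=list)
    unassigned: list[Seed] = field(default_factory=list)


def _snp_variants(record: KeyRecord) -> list[str]:
    pre, post = record.amplicon[: record.snp_index], record.amplicon[record.snp_index + 1 :]
    return [pre + b + post for b in "ACGT"]


def assign_seeds(
    seeds: list[Seed], panel: MarkerPanel, cfg: CallingConfig
) -> AssignmentResult:
    """Assign each seed to the single best-matching marker.

    A seed goes to the marker with maximal identity >= the threshold; an
    exact tie between markers is flagged ambiguous and the seed is excluded
    from both (logged, never broken at random).

    At ``identity_threshold == 1.0`` an exact-lookup fast path is used: a
    seed can only reach identity 1.0 against an equal-length key it matches
    everywhere outside the SNP site, i.e. one of the four SNP-substituted
    variants of that key (gap columns always pull alignment identity below
    1 when lengths differ).
    """
    if cfg.identity_threshold == 1.0 and cfg.mask_snp:
        return _assign_exact(seeds, panel)
    return _assign_scan(seeds, panel, cfg)


def _assign_exact(seeds: list[Seed], panel: MarkerPanel) -> AssignmentResult:
    lookup: dict[str, list[KeyRecord]] = {}
    for record in panel:
        for variant in _snp_variants(record):
            lookup.setdefault(variant, []).append(record)
    result = AssignmentResult(per_marker={})
    for seed in seeds:
        hits = lookup.get(seed.sequence)
        if hits is None:
            result.unassigned.append(seed)
        elif len(hits) > 1:
            logger.info(
                "seed (count %d) ties %s at identity 1.0; excluded as ambiguous",
                seed.count,
                [r.marker_id for r in hits],
            )
            result.ambiguous.append(seed)
        else:
            record = hits[0]
            match = MatchResult(
                record.marker_id, seed, 1.0, seed.sequence[record.snp_index]
            )
            result.per_marker.setdefault(
                record.marker_id, MarkerSeeds(record.marker_id)
            ).matches.append(match)
    return result


def _assign_scan(
    seeds: list[Seed], panel: MarkerPanel, cfg: CallingConfig
) -> AssignmentResult:
    result = AssignmentResult(per_marker={})
    for seed in seeds:
        best: list[MatchResult] = []
        best_identity = -1.0
        for record in panel:
            match = match_seed(seed, record, cfg)
            if match.identity > best_identity:
                best, best_identity = [match], match.identity
            elif match.identity == best_identity:
                best.append(match)
        if best_identity < cfg.identity_threshold:
            result.unassigned.append(seed)
        elif len(best) > 1:
            logger.info(
                "seed (count %d) ties %s at identity %.4f; excluded as ambiguous",
                seed.count,
                [m.marker_id for m in best],
                best_identity,
            )
            result.ambiguous.append(seed)
        else:
            match = best[0]
            result.per_marker.setdefault(
                match.marker_id, MarkerSeeds(match.marker_id)
            ).matches.append(match)
    return result


def filter_seeds(assigned: AssignmentResult, cfg: CallingConfig) -> AssignmentResult:
    """Apply the read-fraction filter per marker.

    A seed survives iff count / total assigned reads for its marker is at
    least ``min_seed_fraction`` — the boundary is inclusive.  Markers whose
    seeds are all filtered out drop from the map (downstream call: missing).
    """
    out = AssignmentResult(
        per_marker={},
        ambiguous=list(assigned.ambiguous),
        unassigned=list(assigned.unassigned),
    )
    for marker_id, ms in assigned.per_marker.items():
        total = ms.total_reads
        keep = [
            m for m in ms.matches if total and m.seed.count / total >= cfg.min_seed_fraction
        ]
        if keep:
            out.per_marker[marker_id] = MarkerSeeds(marker_id, matches=keep)
    return out


def assign_and_filter(
    seeds: list[Seed], panel: MarkerPanel, cfg: CallingConfig
) -> AssignmentResult:
    """Assignment followed by the read-fraction filter (one sample)."""
    return filter_seeds(assign_seeds(seeds, panel, cfg), cfg)


def call_genotype(
    marker_seeds: MarkerSeeds | None,
    record: KeyRecord,
    sample_id: str,
    cfg: CallingConfig,
    *,
    total_assigned_reads: int | None = None,
) -> GenotypeCall:
    """Call one marker x sample genotype from its surviving seeds.

    Surviving seeds whose SNP-site base is neither canonical allele (or is
    gapped) contribute to the read total but not to either allele depth.
    ``total_assigned_reads`` may carry the pre-filter assigned total; it
    defaults to the surviving total.
    """
    if marker_seeds is None or not marker_seeds.matches:
        return GenotypeCall(
            record.marker_id,
            sample_id,
            "missing",
            total_marker_reads=total_assigned_reads or 0,
        )
    total = (
        total_assigned_reads
        if total_assigned_reads is not None
        else marker_seeds.total_reads
    )
    allele_a, allele_b = record.alleles
    depth_a = sum(
        m.seed.count for m in marker_seeds.matches if m.allele_at_snp == allele_a
    )
    depth_b = sum(
        m.seed.count for m in marker_seeds.matches if m.allele_at_snp == allele_b
    )
    if total < cfg.min_marker_depth or (depth_a == 0 and depth_b == 0):
        call = "missing"
    elif depth_a > 0 and depth_b > 0:
        call = "het"
    else:
        call = "hom_a" if depth_a > 0 else "hom_b"
    return GenotypeCall(
        record.marker_id, sample_id, call, depth_a, depth_b, total
    )


@dataclass
class SampleResult:
    sample_id: str
    calls: dict[str, GenotypeCall]
    assignment: AssignmentResult


def call_sample(
    reads: ReadBatch, panel: MarkerPanel, cfg: CallingConfig, sample_id: str
) -> SampleResult:
    """Run dereplication -> assignment -> filter -> calling for one sample."""
    seeds = dereplicate(reads)
    assigned = assign_seeds(seeds, panel, cfg)
    surviving = filter_seeds(assigned, cfg)
    calls = {}
    for record in panel:
        pre_filter = assigned.per_marker.get(record.marker_id)
        calls[record.marker_id] = call_genotype(
            surviving.per_marker.get(record.marker_id),
            record,
            sample_id,
            cfg,
            total_assigned_reads=pre_filter.total_reads if pre_filter else 0,
        )
    return SampleResult(sample_id=sample_id, calls=calls, assignment=surviving)


def call_all(
    batches: dict[str, ReadBatch], panel: MarkerPanel, cfg: CallingConfig
) -> dict[str, SampleResult]:
    return {
        sample_id: call_sample(batch, panel, cfg, sample_id)
        for sample_id, batch in batches.items()
    }


# -- reports ------------------------------------------------------------------


def snp_report(results: dict[str, SampleResult], panel: MarkerPanel) -> pd.DataFrame:
    """Samples x markers table of call cells (base / IUPAC het code / '-')."""
    return pd.DataFrame(
        {
            record.marker_id: {
                s: r.calls[record.marker_id].cell(record) for s, r in results.items()
            }
            for record in panel
        }
    ).rename_axis(index="sample_id")


def hit_report(results: dict[str, SampleResult], panel: MarkerPanel) -> pd.DataFrame:
    """Samples x markers table of per-marker assigned read totals."""
    return pd.DataFrame(
        {
            record.marker_id: {
                s: r.calls[record.marker_id].total_marker_reads
                for s, r in results.items()
            }
            for record in panel
        }
    ).rename_axis(index="sample_id")


def _gapped_to_key(seed_seq: str, record: KeyRecord) -> str:
    """Project a seed onto key coordinates for the per-marker alignment file.

    Equal lengths pass through; otherwise deletions relative to the key are
    written as '-' and seed insertions are dropped, so every sequence in the
    file has the key's length.
    """
    if len(seed_seq) == len(record.amplicon):
        return seed_seq
    alignment = _aligner.align(record.amplicon, seed_seq)[0]
    key_row, seed_row = str(alignment[0]), str(alignment[1])
    return "".join(q for k, q in zip(key_row, seed_row) if k != "-")


def write_msa_files(
    results: dict[str, SampleResult], panel: MarkerPanel, outdir: str | Path
) -> list[Path]:
    """One FASTA per marker: the key sequence then every surviving seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for record in panel:
        lines = [f">{record.marker_id}|key", record.amplicon]
        for sample_id, result in results.items():
            ms = result.assignment.per_marker.get(record.marker_id)
            if ms is None:
                continue
            for i, m in enumerate(ms.matches):
                lines.append(
                    f">{sample_id}|seed{i}|count={m.seed.count}"
                    f"|identity={m.identity:.4f}"
                )
                lines.append(_gapped_to_key(m.seed.sequence, record))
        path = outdir / f"{record.marker_id}.msa.fasta"
        path.write_text("\n".join(lines) + "\n")
        written.append(path)
    return written


def write_reports(
    results: dict[str, SampleResult], panel: MarkerPanel, outdir: str | Path
) -> dict[str, Path]:
    """Write snp_report.tsv, hit_report.tsv and msa/<marker>.msa.fasta."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    snp_path = outdir / "snp_report.tsv"
    hit_path = outdir / "hit_report.tsv"
    snp_report(results, panel).to_csv(snp_path, sep="\t")
    hit_report(results, panel).to_csv(hit_path, sep="\t")
    write_msa_files(results, panel, outdir / "msa")
    return {"snp": snp_path, "hit": hit_path, "msa": outdir / "msa"}


def read_snp_report(path: str | Path) -> pd.DataFrame:
    """Load a SNP report back into a samples x markers DataFrame."""
    return pd.read_csv(path, sep="\t", index_col="sample_id", dtype=str)


def calls_from_report(
    report: pd.DataFrame, panel: MarkerPanel
) -> dict[str, dict[str, str]]:
    """Decode report cells back to call categories per sample per marker."""
    decoded: dict[str, dict[str, str]] = {}
    for record in panel:
        het_code = ALLELES_TO_AMBIGUITY[record.alleles]
        for sample_id, cell in report[record.marker_id].items():
            d = decoded.setdefault(sample_id, {})
            if cell == MISSING_CELL:
                d[record.marker_id] = "missing"
            elif cell == het_code:
                d[record.marker_id] = "het"
            elif cell == record.alleles[0]:
                d[record.marker_id] = "hom_a"
            elif cell == record.alleles[1]:
                d[record.marker_id] = "hom_b"
            else:
                raise ValueError(
                    f"cell {cell!r} is not a valid call for {record.marker_id}"
                )
    return decoded
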