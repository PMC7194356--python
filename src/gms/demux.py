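"""Barcode demultiplexing of raw amplicon reads.

Each sequencing read is ``[5' adapter context][8-base sample barcode][insert]``
with optional 3'-adapter read-through.  A read is assigned to a sample iff the
8 bases following the 5' context match that sample's barcode exactly (the
default; a mismatch tolerance and reverse-orientation scan exist as options).
Assigned reads are trimmed to the biological insert.  Quality strings are
carried through untouched — calling never uses them.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

BARCODE_LENGTH = 8
PLATFORMS = ("iontorrent", "illumina")

#: reads shorter than barcode + this many insert bases are primer-dimer junk
MIN_INSERT_AFTER_TRIM = 8

_COMPLEMENT = str.maketrans("ACGTRYSWKMN", "TGCAYRSWMKN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class DemuxError(ValueError):
    pass


@dataclass(frozen=True)
class BarcodeMap:
    """sample_id -> 8-base barcode, plus the platform adapter context."""

    entries: dict[str, str]
    platform: str = "iontorrent"
    adapter_5p: str = ""
    adapter_3p: str = ""

    def __post_init__(self) -> None:
        if not self.entries:
            raise DemuxError("barcode map is empty")
        if self.platform not in PLATFORMS:
            raise DemuxError(f"unknown platform {self.platform!r}")
        bad = {s: b for s, b in self.entries.items() if len(b) != BARCODE_LENGTH}
        if bad:
            raise DemuxError(f"barcodes not {BARCODE_LENGTH} bp: {bad}")
        barcodes = list(self.entries.values())
        if len(set(barcodes)) != len(barcodes):
            dupes = [b for b, n in Counter(barcodes).items() if n > 1]
            raise DemuxError(f"duplicate barcodes: {dupes}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.entries)


@dataclass
class ReadBatch:
    """A bag of reads: (read_id, bases, quality-or-None) triples."""

    reads: list[tuple[str, str, str | None]] = field(default_factory=list)
    sample_id: str | None = None

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[tuple[str, str, str | None]]:
        return iter(self.reads)

    def sequences(self) -> list[str]:
        return [bases for _, bases, _ in self.reads]


@dataclass
class DemuxResult:
    by_sample: dict[str, ReadBatch]
    unassigned: ReadBatch
    #: reason -> count for reads routed to 'unassigned'
    reasons: Counter = field(default_factory=Counter)

    def counts(self) -> dict[str, int]:
        return {s: len(b) for s, b in self.by_sample.items()}


def _match_barcode(
    region: str, barcodes: dict[str, str], mismatches: int
) -> str | None:
    """Sample id whose barcode matches *region*, or None.

    With ``mismatches > 0`` a unique nearest barcode within the tolerance is
    accepted; ties are rejected (never guessed).
    """
    if mismatches == 0:
        return barcodes.get(region)
    best: list[str] = []
    best_d = mismatches + 1
    for bc, sample in barcodes.items():
        d = sum(a != b for a, b in zip(region, bc))
        if d < best_d:
            best, best_d = [sample], d
        elif d == best_d:
            best.append(sample)
    return best[0] if len(best) == 1 and best_d <= mismatches else None


def demultiplex(
    reads: ReadBatch,
    barcode_map: BarcodeMap,
    *,
    mismatches: int = 0,
    both_orientations: bool = False,
) -> DemuxResult:
    """Assign every read to exactly one sample batch or to 'unassigned'.

    Conservation holds by construction: ``len(reads)`` equals the sum of the
    per-sample counts plus the unassigned count.
    """
    prefix_len = len(barcode_map.adapter_5p)
    barcode_to_sample = {b: s for s, b in barcode_map.entries.items()}
    out = {s: ReadBatch(sample_id=s) for s in barcode_map.sample_ids}
    unassigned = ReadBatch(sample_id=None)
    reasons: Counter = Counter()

    min_len = prefix_len + BARCODE_LENGTH + MIN_INSERT_AFTER_TRIM
    for read_id, bases, qual in reads:
        bases = bases.upper()
        candidates = [bases]
        if both_orientations:
            candidates.append(reverse_complement(bases))
        assigned = False
        for oriented in candidates:
            if len(oriented) < min_len:
                continue
            if prefix_len and not oriented.startswith(barcode_map.adapter_5p):
                continue
            region = oriented[prefix_len : prefix_len + BARCODE_LENGTH]
            sample = _match_barcode(region, barcode_to_sample, mismatches)
            if sample is None:
                continue
            insert = _trim(oriented, prefix_len, barcode_map.adapter_3p)
            trimmed_qual = (
                qual[prefix_len + BARCODE_LENGTH :][: len(insert)]
                if qual is not None and oriented is bases
                else None
            )
            out[sample].reads.append((read_id, insert, trimmed_qual))
            assigned = True
            break
        if not assigned:
            if len(bases) < min_len:
                reasons["too_short"] += 1
            else:
                reasons["no_barcode_match"] += 1
            unassigned.reads.append((read_id, bases, qual))
    return DemuxResult(by_sample=out, unassigned=unassigned, reasons=reasons)


def _trim(bases: str, prefix_len: int, adapter_3p: str) -> str:
    insert = bases[prefix_len + BARCODE_LENGTH :]
    if adapter_3p:
        pos = insert.find(adapter_3p)
        if pos != -1:
            insert = insert[:pos]
    return insert


def trim_to_insert(bases: str, barcode_map: BarcodeMap) -> str:
    """Strip 5' adapter + barcode and any exact 3'-adapter read-through."""
    return _trim(bases.upper(), len(barcode_map.adapter_5p), barcode_map.adapter_3p)


# -- file I/O -----------------------------------------------------------------


def _open(path: str | Path, mode: str = "rt"):
    path = Path(path)
    return gzip.open(path, mode) if path.suffix == ".gz" else open(path, mode)


def read_fastq(path: str | Path) -> ReadBatch:
    """Load a FASTQ (optionally gzipped) into a :class:`ReadBatch`."""
    reads: list[tuple[str, str, str | None]] = []
    with _open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip().upper()
            fh.readline()  # '+'
            qual = fh.readline().strip()
            reads.append((header.strip()[1:].split()[0], seq, qual or None))
    return ReadBatch(reads=reads)


def write_fastq(batch: ReadBatch, path: str | Path) -> None:
    with _open(path, "wt") as fh:
        for read_id, bases, qual in batch:
            fh.write(f"@{read_id}\n{bases}\n+\n{qual or 'I' * len(bases)}\n")


def read_barcode_map(
    path: str | Path, *, adapter_5p: str = "", adapter_3p: str = ""
) -> BarcodeMap:
    """Load a barcode map TSV with columns sample_id / barcode / platform."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "barcode"):
        if col not in df.columns:
            raise DemuxError(f"barcode map {path} lacks column {col!r}")
    platform = (
        df["platform"].iloc[0] if "platform" in df.columns else "iontorrent"
    )
    entries = dict(zip(df["sample_id"], df["barcode"].str.upper()))
    return BarcodeMap(
        entries=entries,
        platform=platform,
        adapter_5p=adapter_5p.upper(),
        adapter_3p=adapter_3p.upper(),
    )


def write_barcode_map(barcode_map: BarcodeMap, path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": barcode_map.sample_ids,
            "barcode": [barcode_map.entries[s] for s in barcode_map.sample_ids],
            "platform": barcode_map.platform,
        }
    ).to_csv(path, sep="\t", index=False)


def write_demux_report(result: DemuxResult, path: str | Path) -> None:
    rows = [{"sample_id": s, "n_reads": n} for s, n in result.counts().items()]
    rows.append({"sample_id": "unassigned", "n_reads": len(result.unassigned)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
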