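"""GMS key files: the panel's catalogue of expected amplicon sequences.

A key file is a minimal FASTA: one ``>marker_id`` header line followed by a
single unwrapped amplicon line.  Each amplicon carries exactly one two-base
IUPAC ambiguity character (R, Y, S, W, K, M) marking the SNP; the two bases
it expands to are the marker's canonical alleles, in alphabetical order.

Marker metadata that the key file itself does not carry (category,
chromosome, cM position, primer pool) lives in a sidecar TSV keyed by
marker_id, keeping the key file byte-compatible with its minimal format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

# Two-base IUPAC ambiguity codes only: the panel is biallelic by design.
AMBIGUITY_TO_ALLELES: dict[str, tuple[str, str]] = {
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}
ALLELES_TO_AMBIGUITY: dict[tuple[str, str], str] = {
    v: k for k, v in AMBIGUITY_TO_ALLELES.items()
}
UNAMBIGUOUS = frozenset("ACGT")
MULTIBASE_CODES = frozenset("NBDHV")  # 3- and 4-base codes: rejected

#: Platform ceiling on amplicon length; longer records draw a warning.
AMPLICON_LENGTH_CEILING = 150

CATEGORIES = frozenset({"wheat", "barley", "KIM", "homoeo_pool"})


class KeyfileError(ValueError):
    """Malformed key file (ambiguity count, duplicates, bad characters)."""


@dataclass(frozen=True)
class KeyRecord:
    """One marker's expected amplicon with its embedded SNP.

    Attributes
    ----------
    marker_id : str
        Unique marker name (no whitespace).
    amplicon : str
        Uppercase expected sequence containing exactly one ambiguity code.
    snp_index : int
        0-based offset of the ambiguity character.
    alleles : tuple[str, str]
        The two bases the code expands to, alphabetical.
    category : str or None
        One of wheat / barley / KIM / homoeo_pool.
    chromosome : str or None
        e.g. ``"1A"``.
    cM : float or None
        Genetic-map position, centimorgans.
    """

    marker_id: str
    amplicon: str
    snp_index: int
    alleles: tuple[str, str]
    category: str | None = None
    chromosome: str | None = None
    cM: float | None = None

    @property
    def ambiguity_code(self) -> str:
        return self.amplicon[self.snp_index]

    def expected_allele_sequences(self) -> tuple[str, str]:
        """The two concrete amplicons implied by the ambiguity code.

        Substitutes each canonical allele at ``snp_index``; the pair differs
        at exactly that one position.
        """
        pre, post = self.amplicon[: self.snp_index], self.amplicon[self.snp_index + 1 :]
        return tuple(pre + a + post for a in self.alleles)  # type: ignore[return-value]

    def masked_amplicon(self, mask: str = "N") -> str:
        """Amplicon with the SNP site replaced by *mask*."""
        return (
            self.amplicon[: self.snp_index] + mask + self.amplicon[self.snp_index + 1 :]
        )


def make_key_record(
    marker_id: str,
    amplicon: str,
    *,
    category: str | None = None,
    chromosome: str | None = None,
    cM: float | None = None,
) -> tuple[KeyRecord, list[str]]:
    """Validate one marker entry and derive its SNP fields.

    Returns the record plus a list of non-fatal validation warnings.
    Raises :class:`KeyfileError` on a malformed entry.
    """
    if not marker_id or any(c.isspace() for c in marker_id):
        raise KeyfileError(f"marker id {marker_id!r} is empty or contains whitespace")
    seq = amplicon.upper()
    if not seq:
        raise KeyfileError(f"marker {marker_id}: empty amplicon")
    ambiguous = [i for i, c in enumerate(seq) if c not in UNAMBIGUOUS]
    if not ambiguous:
        raise KeyfileError(f"marker {marker_id}: no ambiguity character (no SNP site)")
    if len(ambiguous) > 1:
        raise KeyfileError(
            f"marker {marker_id}: {len(ambiguous)} ambiguity characters, expected 1"
        )
    idx = ambiguous[0]
    code = seq[idx]
    if code in MULTIBASE_CODES:
        raise KeyfileError(
            f"marker {marker_id}: ambiguity code {code!r} is not a two-base code "
            "(panel is biallelic)"
        )
    if code not in AMBIGUITY_TO_ALLELES:
        raise KeyfileError(f"marker {marker_id}: invalid character {code!r} in amplicon")
    if category is not None and category not in CATEGORIES:
        raise KeyfileError(f"marker {marker_id}: unknown category {category!r}")
    if cM is not None and not cM >= 0:
        raise KeyfileError(f"marker {marker_id}: negative cM position {cM}")
    warnings: list[str] = []
    if len(seq) > AMPLICON_LENGTH_CEILING:
        warnings.append(
            f"marker {marker_id}: amplicon length {len(seq)} exceeds the "
            f"{AMPLICON_LENGTH_CEILING} bp platform ceiling"
        )
    record = KeyRecord(
        marker_id=marker_id,
        amplicon=seq,
        snp_index=idx,
        alleles=AMBIGUITY_TO_ALLELES[code],
        category=category,
        chromosome=chromosome,
        cM=cM,
    )
    return record, warnings


@dataclass
class MarkerPanel:
    """Ordered collection of :class:`KeyRecord` with optional pool labels."""

    records: list[KeyRecord] = field(default_factory=list)
    pool_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.marker_id for r in self.records]
        dupes = {m for m in ids if ids.count(m) > 1}
        if dupes:
            raise KeyfileError(f"duplicate marker ids: {sorted(dupes)}")
        unknown = set(self.pool_of) - set(ids)
        if unknown:
            raise KeyfileError(f"pool labels for unknown markers: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[KeyRecord]:
        return iter(self.records)

    def __getitem__(self, marker_id: str) -> KeyRecord:
        try:
            return self._index()[marker_id]
        except KeyError:
            raise KeyError(f"no marker {marker_id!r} in panel") from None

    def _index(self) -> dict[str, KeyRecord]:
        return {r.marker_id: r for r in self.records}

    @property
    def marker_ids(self) -> list[str]:
        return [r.marker_id for r in self.records]


def parse_keyfile(path: str | Path) -> MarkerPanel:
    """Parse a key file (FASTA dialect: header line, one sequence line).

    Case-insensitive on input; sequences are stored uppercase.  Raises
    :class:`KeyfileError` on entries with zero or multiple ambiguity
    characters, non-biallelic codes, or duplicate marker ids.
    """
    records: list[KeyRecord] = []
    seen: set[str] = set()
    for marker_id, seq in _iter_fasta(Path(path).read_text().splitlines()):
        if marker_id in seen:
            raise KeyfileError(f"duplicate marker id {marker_id!r}")
        seen.add(marker_id)
        record, _ = make_key_record(marker_id, seq)
        records.append(record)
    return MarkerPanel(records=records)


def _iter_fasta(lines: Iterable[str]) -> Iterator[tuple[str, str]]:
    header: str | None = None
    chunks: list[str] = []
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                yield header, "".join(chunks)
            header = line[1:].split()[0] if line[1:].split() else ""
            chunks = []
        else:
            if header is None:
                raise KeyfileError("sequence line before first '>' header")
            chunks.append(line)
    if header is not None:
        yield header, "".join(chunks)


def write_keyfile(panel: MarkerPanel, path: str | Path) -> None:
    """Write *panel* in the key-file dialect; inverse of :func:`parse_keyfile`."""
    with open(path, "w") as fh:
        fh.write(format_keyfile(panel))


def format_keyfile(panel: MarkerPanel) -> str:
    return "".join(f">{r.marker_id}\n{r.amplicon}\n" for r in panel)


# -- sidecar metadata ---------------------------------------------------------

META_COLUMNS = ["marker_id", "category", "chromosome", "cM", "pool"]


def write_metadata(panel: MarkerPanel, path: str | Path) -> None:
    rows = [
        {
            "marker_id": r.marker_id,
            "category": r.category or "",
            "chromosome": r.chromosome or "",
            "cM": "" if r.cM is None else r.cM,
            "pool": panel.pool_of.get(r.marker_id, ""),
        }
        for r in panel
    ]
    pd.DataFrame(rows, columns=META_COLUMNS).to_csv(path, sep="\t", index=False)


def attach_metadata(panel: MarkerPanel, path: str | Path) -> MarkerPanel:
    """Return a new panel with sidecar-TSV metadata merged onto its records."""
    meta = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chromosome": str})
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise KeyfileError(f"metadata file {path} lacks columns: {missing}")
    by_id = meta.set_index("marker_id")
    records = []
    pool_of: dict[str, str] = {}
    for r in panel:
        if r.marker_id in by_id.index:
            row = by_id.loc[r.marker_id]
            category = row["category"] if isinstance(row["category"], str) else None
            chromosome = (
                row["chromosome"] if isinstance(row["chromosome"], str) else None
            )
            cM = None if pd.isna(row["cM"]) else float(row["cM"])
            if isinstance(row["pool"], str) and row["pool"]:
                pool_of[r.marker_id] = row["pool"]
            record, _ = make_key_record(
                r.marker_id, r.amplicon, category=category, chromosome=chromosome, cM=cM
            )
            records.append(record)
        else:
            records.append(r)
    return MarkerPanel(records=records, pool_of=pool_of)
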