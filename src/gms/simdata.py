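"""Synthetic GMS experiments with full truth tables.

The generator emulates the data a multiplexed-amplicon genotyping study
produces but does not deposit: a marker panel with an evenly spaced genetic
map, RIL or diversity-panel genotype matrices, homoeoallele/paralog
co-amplification, barcoded error-bearing reads with dispersed per-sample
depths, and nulli-tetrasomic aneuploid lines.  Every read is derivable from
the emitted truth set, and identical seeds give byte-identical output.

Depth is drawn from a negative-binomial (gamma-mixed Poisson) distribution:
amplicon panels show strong marker- and sample-level depth variation that a
Poisson would understate, and observed depth is essentially decoupled from
nominal DNA input.  Sequencing errors are i.i.d. substitutions by default
(an indel knob exists for robustness testing); short adapter-flanked
primer-dimer junk can be mixed in to exercise the demultiplexer's length
guard.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .demux import BarcodeMap, ReadBatch, write_barcode_map, write_fastq
from .homoeo import (
    WHEAT_CHROMOSOMES,
    NulliTetraPanel,
    homoeologous_group,
    write_nullitetra_panel,
)
from .keyfile import (
    ALLELES_TO_AMBIGUITY,
    KeyRecord,
    MarkerPanel,
    make_key_record,
    write_keyfile,
    write_metadata,
)
from .metrics import GeneticMap

BASES = np.array(list("ACGT"))

DEFAULT_ADAPTER_5P = "CCATCTCATCCCTGCGTGTC"  # Ion A-adapter-style context
DEFAULT_ADAPTER_3P = "ATCACCGACTGCCCATAGAG"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic experiment.

    Defaults mirror the emulated study design: 48-sample RIL populations,
    150 bp amplicons on a 2 cM map grid, mean depth 200 with strong
    negative-binomial dispersion, 0.2% per-base substitution error, and
    roughly a fifth of markers co-amplifying a homoeoallele and ~6%
    a paralog (the proportions implied by 396 homoeoalleles and 125
    paralogs over a 1,912-marker panel).
    """

    rng_seed: int
    n_markers: int = 200
    amplicon_length: int = 150
    n_samples: int = 48
    population: str = "RIL"  # 'RIL' | 'diversity'
    residual_het_rate: float = 0.02
    allele_freq_range: tuple[float, float] = (0.1, 0.9)
    mean_depth: float = 200.0
    depth_dispersion: float = 5.0
    per_base_error_rate: float = 0.002
    indel_rate: float = 0.0
    fraction_markers_with_homoeoallele: float = 0.20
    fraction_markers_with_paralog: float = 0.065
    homoeo_divergence_subs: tuple[int, int] = (2, 7)
    map_spacing_cM: float = 2.0
    dimer_fraction: float = 0.0
    adapter_5p: str = DEFAULT_ADAPTER_5P
    adapter_3p: str = DEFAULT_ADAPTER_3P
    platform: str = "iontorrent"

    def __post_init__(self) -> None:
        for name in (
            "residual_het_rate",
            "per_base_error_rate",
            "indel_rate",
            "fraction_markers_with_homoeoallele",
            "fraction_markers_with_paralog",
            "dimer_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.amplicon_length < 30:
            raise ValueError("amplicon_length must be >= 30")
        if self.population not in {"RIL", "diversity"}:
            raise ValueError(f"unknown population {self.population!r}")


@dataclass(frozen=True)
class OffTargetLocus:
    """A co-amplified copy of one marker's amplicon, placed on a chromosome."""

    marker_id: str
    kind: str  # 'homoeoallele' | 'paralog'
    chromosome: str
    sequence: str


@dataclass
class TruthSet:
    """Everything needed to reconstruct or verify the emitted reads."""

    panel: MarkerPanel
    gmap: GeneticMap | None
    genotypes: pd.DataFrame | None = None  # samples x markers: hom_a/hom_b/het
    barcode_map: BarcodeMap | None = None
    offtargets: list[OffTargetLocus] = field(default_factory=list)
    #: (sample_id, marker_or_locus label) -> emitted read count
    read_depths: dict[tuple[str, str], int] = field(default_factory=dict)
    read_origin: dict[str, str] = field(default_factory=dict)  # read_id -> sample
    nullitetra: NulliTetraPanel | None = None

    def offtargets_of(self, marker_id: str) -> list[OffTargetLocus]:
        return [o for o in self.offtargets if o.marker_id == marker_id]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, length)])


def _mutate(
    rng: np.random.Generator, seq: str, n_subs: int, forbidden: set[int]
) -> str:
    """Apply exactly n_subs substitutions avoiding the forbidden positions."""
    allowed = [i for i in range(len(seq)) if i not in forbidden]
    sites = rng.choice(len(allowed), size=n_subs, replace=False)
    out = list(seq)
    for s in sites:
        i = allowed[s]
        out[i] = str(rng.choice([b for b in "ACGT" if b != out[i]]))
    return "".join(out)


def simulate_panel(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[MarkerPanel, GeneticMap, list[OffTargetLocus]]:
    """Random marker panel, its genetic map, and planted off-target loci.

    Markers are dealt round-robin across the 21 wheat chromosomes at the
    configured cM spacing.  A designated fraction of markers receives a
    homoeoallele copy (same homoeologous group, another subgenome) and/or a
    paralog (a random other-group chromosome); each copy carries a fixed
    base at the SNP-homologous site plus the configured number of divergence
    substitutions, so its identity to the key sits below 100% but inside the
    relaxed-mode window.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    records: list[KeyRecord] = []
    entries: dict[str, tuple[str, float]] = {}
    offtargets: list[OffTargetLocus] = []
    lo, hi = cfg.homoeo_divergence_subs
    per_chrom_counter: dict[str, int] = {}
    for i in range(cfg.n_markers):
        marker_id = f"M{i:04d}"
        chromosome = WHEAT_CHROMOSOMES[i % len(WHEAT_CHROMOSOMES)]
        rank = per_chrom_counter.get(chromosome, 0)
        per_chrom_counter[chromosome] = rank + 1
        snp_index = int(rng.integers(10, cfg.amplicon_length - 10))
        code = str(rng.choice(list(ALLELES_TO_AMBIGUITY.values())))
        seq = _random_seq(rng, cfg.amplicon_length)
        amplicon = seq[:snp_index] + code + seq[snp_index + 1 :]
        record, _ = make_key_record(
            marker_id,
            amplicon,
            category="wheat",
            chromosome=chromosome,
            cM=rank * cfg.map_spacing_cM,
        )
        records.append(record)
        entries[marker_id] = (chromosome, rank * cfg.map_spacing_cM)
        group = homoeologous_group(chromosome)
        if rng.random() < cfg.fraction_markers_with_homoeoallele:
            target = str(
                rng.choice([c for c in WHEAT_CHROMOSOMES
                            if homoeologous_group(c) == group and c != chromosome])
            )
            offtargets.append(
                _make_offtarget(rng, record, "homoeoallele", target, lo, hi)
            )
        if rng.random() < cfg.fraction_markers_with_paralog:
            target = str(
                rng.choice([c for c in WHEAT_CHROMOSOMES
                            if homoeologous_group(c) != group])
            )
            offtargets.append(
                _make_offtarget(rng, record, "paralog", target, lo, hi)
            )
    panel = MarkerPanel(records=records)
    return panel, GeneticMap(entries=entries), offtargets


def _make_offtarget(
    rng: np.random.Generator,
    record: KeyRecord,
    kind: str,
    chromosome: str,
    lo: int,
    hi: int,
) -> OffTargetLocus:
    base_at_snp = str(rng.choice(list(record.alleles)))
    seq = (
        record.amplicon[: record.snp_index]
        + base_at_snp
        + record.amplicon[record.snp_index + 1 :]
    )
    n_subs = int(rng.integers(lo, hi + 1))
    seq = _mutate(rng, seq, n_subs, forbidden={record.snp_index})
    return OffTargetLocus(record.marker_id, kind, chromosome, seq)


def simulate_population(
    cfg: SimConfig, panel: MarkerPanel, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Truth genotype matrix (samples x markers; hom_a / hom_b / het).

    RIL mode draws a parental homozygote per marker with a fair coin and
    injects residual heterozygosity at the configured rate, matching
    near-fixed recombinant inbred material.  Diversity mode draws each
    marker's allele frequency uniformly from the configured range and then
    genotypes under Hardy-Weinberg proportions.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed + 1)
    sample_ids = [f"S{i:03d}" for i in range(cfg.n_samples)]
    data = {}
    for record in panel:
        if cfg.population == "RIL":
            calls = np.where(
                rng.random(cfg.n_samples) < 0.5, "hom_a", "hom_b"
            ).astype(object)
            het = rng.random(cfg.n_samples) < cfg.residual_het_rate
            calls[het] = "het"
        else:
            p = rng.uniform(*cfg.allele_freq_range)
            u = rng.random(cfg.n_samples)
            calls = np.full(cfg.n_samples, "het", dtype=object)
            calls[u < p**2] = "hom_a"
            calls[u > 1 - (1 - p) ** 2] = "hom_b"
        data[record.marker_id] = calls
    return pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id"))


def make_barcode_map(
    cfg: SimConfig, n: int, rng: np.random.Generator
) -> BarcodeMap:
    """n pairwise-distinct random 8-base barcodes."""
    barcodes: list[str] = []
    seen: set[str] = set()
    while len(barcodes) < n:
        bc = _random_seq(rng, 8)
        if bc not in seen:
            seen.add(bc)
            barcodes.append(bc)
    return BarcodeMap(
        entries={f"S{i:03d}": bc for i, bc in enumerate(barcodes)},
        platform=cfg.platform,
        adapter_5p=cfg.adapter_5p,
        adapter_3p=cfg.adapter_3p,
    )


def _draw_depth(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=int)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size)


def _apply_errors(
    rng: np.random.Generator, seqs: list[str], depths: list[int], error: float
) -> list[str]:
    """Expand (sequence, depth) pairs to reads with i.i.d. substitutions."""
    reads: list[str] = []
    for seq, depth in zip(seqs, depths):
        if depth == 0:
            continue
        if error == 0:
            reads.extend([seq] * depth)
            continue
        L = len(seq)
        n_err = rng.binomial(L, error, depth)
        total = int(n_err.sum())
        positions = rng.integers(0, L, total)
        shifts = rng.integers(1, 4, total)
        k = 0
        for errs in n_err:
            if errs == 0:
                reads.append(seq)
                continue
            out = list(seq)
            for j in range(k, k + errs):
                i = int(positions[j])
                out[i] = "ACGT"[("ACGT".index(out[i]) + int(shifts[j])) % 4]
            k += errs
            reads.append("".join(out))
    return reads


def simulate_reads(
    cfg: SimConfig,
    panel: MarkerPanel,
    genotypes: pd.DataFrame,
    *,
    offtargets: list[OffTargetLocus] | None = None,
    barcode_map: BarcodeMap | None = None,
    rng: np.random.Generator | None = None,
    sample_ids: list[str] | None = None,
    excluded_chromosomes: dict[str, set[str]] | None = None,
) -> tuple[ReadBatch, TruthSet]:
    """Emit one multiplexed raw-read batch plus its truth set.

    Per sample x marker, depth is negative-binomial around ``mean_depth``;
    hom samples emit the one allele amplicon, hets split depth binomially
    between both.  Each planted off-target locus adds reads of its own
    sequence in every sample (co-amplification is genotype-independent).
    Reads get the 5' adapter + sample barcode attached and are shuffled;
    ``excluded_chromosomes`` (per sample) suppresses loci on those
    chromosomes, which is how aneuploid lines are modelled.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed + 2)
    offtargets = offtargets or []
    sample_ids = sample_ids or list(genotypes.index)
    if barcode_map is None:
        barcode_map = make_barcode_map(cfg, len(sample_ids), rng)
    excluded_chromosomes = excluded_chromosomes or {}

    truth = TruthSet(panel=panel, gmap=None, genotypes=genotypes,
                     barcode_map=barcode_map, offtargets=offtargets)
    by_marker_offt: dict[str, list[OffTargetLocus]] = {}
    for o in offtargets:
        by_marker_offt.setdefault(o.marker_id, []).append(o)

    tagged: list[tuple[str, str]] = []  # (sample_id, insert)
    for sample_id in sample_ids:
        skip = excluded_chromosomes.get(sample_id, set())
        seqs: list[str] = []
        depths: list[int] = []
        for record in panel:
            marker_depth = 0
            if record.chromosome not in skip:
                call = genotypes.at[sample_id, record.marker_id]
                depth = int(
                    _draw_depth(rng, cfg.mean_depth, cfg.depth_dispersion, 1)[0]
                )
                a_seq, b_seq = record.expected_allele_sequences()
                if call == "het":
                    d_a = int(rng.binomial(depth, 0.5))
                    seqs += [a_seq, b_seq]
                    depths += [d_a, depth - d_a]
                else:
                    seqs.append(a_seq if call == "hom_a" else b_seq)
                    depths.append(depth)
                marker_depth = depth
            truth.read_depths[(sample_id, record.marker_id)] = marker_depth
            for o in by_marker_offt.get(record.marker_id, []):
                label = f"{o.marker_id}|{o.kind}|{o.chromosome}"
                o_depth = 0
                if o.chromosome not in skip:
                    o_depth = int(
                        _draw_depth(rng, cfg.mean_depth, cfg.depth_dispersion, 1)[0]
                    )
                    seqs.append(o.sequence)
                    depths.append(o_depth)
                truth.read_depths[(sample_id, label)] = o_depth
        inserts = _apply_errors(rng, seqs, depths, cfg.per_base_error_rate)
        tagged.extend((sample_id, ins) for ins in inserts)

    if cfg.dimer_fraction > 0:
        n_dimers = int(cfg.dimer_fraction * len(tagged))
        for _ in range(n_dimers):
            sample_id = str(rng.choice(sample_ids))
            tagged.append((sample_id, _random_seq(rng, int(rng.integers(0, 8)))))

    order = rng.permutation(len(tagged))
    reads: list[tuple[str, str, str | None]] = []
    for n, idx in enumerate(order):
        sample_id, insert = tagged[idx]
        bases = cfg.adapter_5p + barcode_map.entries[sample_id] + insert
        read_id = f"r{n:07d}"
        truth.read_origin[read_id] = sample_id
        reads.append((read_id, bases, None))
    return ReadBatch(reads=reads), truth


def simulate_nullitetra(
    cfg: SimConfig,
    panel: MarkerPanel,
    offtargets: list[OffTargetLocus],
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, ReadBatch], NulliTetraPanel, TruthSet]:
    """One aneuploid line per wheat chromosome, each lacking that chromosome.

    A line's reads omit every locus — marker, homoeoallele or paralog —
    whose truth chromosome is the line's deleted one.  Lines are homozygous
    for the first allele at every marker (aneuploid reference stocks are a
    single genotype); error rate follows the config.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed + 3)
    nt_panel = NulliTetraPanel(
        lines={f"N{c}": c for c in WHEAT_CHROMOSOMES}
    )
    line_ids = list(nt_panel.lines)
    genotypes = pd.DataFrame(
        {r.marker_id: ["hom_a"] * len(line_ids) for r in panel},
        index=pd.Index(line_ids, name="sample_id"),
    )
    barcode_map = make_barcode_map(
        replace(cfg, platform=cfg.platform), len(line_ids), rng
    )
    barcode_map = BarcodeMap(
        entries=dict(zip(line_ids, barcode_map.entries.values())),
        platform=cfg.platform,
        adapter_5p=cfg.adapter_5p,
        adapter_3p=cfg.adapter_3p,
    )
    excluded = {line_id: {chrom} for line_id, chrom in nt_panel.lines.items()}
    batch, truth = simulate_reads(
        cfg,
        panel,
        genotypes,
        offtargets=offtargets,
        barcode_map=barcode_map,
        rng=rng,
        sample_ids=line_ids,
        excluded_chromosomes=excluded,
    )
    truth.nullitetra = nt_panel
    per_line: dict[str, ReadBatch] = {l: ReadBatch(sample_id=l) for l in line_ids}
    for read in batch:
        per_line[truth.read_origin[read[0]]].reads.append(read)
    return per_line, nt_panel, truth


def ril_concordance_experiment(
    seed: int,
    *,
    n_samples: int = 48,
    n_markers: int = 200,
    mean_depth: float = 200.0,
    error_rate: float = 0.002,
) -> tuple[float, int, int]:
    """Simulate a RIL run, genotype it, and score calls against truth.

    The in-silico analogue of validating the platform against an independent
    genotyping assay: simulate barcoded reads for a recombinant-inbred
    population, demultiplex and call with default thresholds, then compare
    every non-missing call with the simulated truth matrix.

    Returns (percent agreement over non-missing calls, number of calls
    compared, number of missing calls).
    """
    from . import metrics, seedcall
    from .demux import demultiplex

    cfg = preset_config(
        "ril48",
        seed,
        n_samples=n_samples,
        n_markers=n_markers,
        mean_depth=mean_depth,
        per_base_error_rate=error_rate,
    )
    rng = np.random.default_rng(cfg.rng_seed)
    panel, _, offtargets = simulate_panel(cfg, rng)
    genotypes = simulate_population(cfg, panel, rng)
    batch, truth = simulate_reads(
        cfg, panel, genotypes, offtargets=offtargets, rng=rng
    )
    demuxed = demultiplex(batch, truth.barcode_map)
    results = seedcall.call_all(
        demuxed.by_sample, panel, seedcall.CallingConfig()
    )
    called = pd.DataFrame(
        {s: {m: c.call for m, c in r.calls.items()} for s, r in results.items()}
    ).T.rename_axis(index="sample_id")
    agreement = metrics.concordance(called, genotypes)
    n_missing = int((called == "missing").to_numpy().sum())
    return 100.0 * agreement.agreement, agreement.n_compared, n_missing


# -- presets and file output --------------------------------------------------

PRESETS: dict[str, dict] = {
    "ril48": dict(n_samples=48, population="RIL"),
    "dp96": dict(n_samples=96, population="diversity"),
    "nullitetra": dict(population="RIL", mean_depth=100.0),
}


def preset_config(name: str, seed: int, **overrides) -> SimConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = {**PRESETS[name], **overrides}
    return SimConfig(rng_seed=seed, **params)


def run_simulation(cfg: SimConfig, outdir: str | Path, preset: str = "ril48") -> TruthSet:
    """Simulate and write FASTQ + key FASTA + metadata + truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.rng_seed)
    panel, gmap, offtargets = simulate_panel(cfg, rng)
    write_keyfile(panel, outdir / "panel.fa")
    write_metadata(panel, outdir / "panel.tsv")
    pd.DataFrame(
        [
            {"marker_id": m, "chromosome": c, "cM": p}
            for m, (c, p) in gmap.entries.items()
        ]
    ).to_csv(outdir / "map.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "marker_id": o.marker_id,
                "kind": o.kind,
                "chromosome": o.chromosome,
                "sequence": o.sequence,
            }
            for o in offtargets
        ],
        columns=["marker_id", "kind", "chromosome", "sequence"],
    ).to_csv(outdir / "offtarget_truth.tsv", sep="\t", index=False)

    if preset == "nullitetra":
        per_line, nt_panel, truth = simulate_nullitetra(cfg, panel, offtargets, rng)
        truth.gmap = gmap
        write_nullitetra_panel(nt_panel, outdir / "nullitetra_panel.tsv")
        fastq_dir = outdir / "reads"
        fastq_dir.mkdir(exist_ok=True)
        for line_id, batch in per_line.items():
            write_fastq(batch, fastq_dir / f"{line_id}.fastq")
        write_barcode_map(truth.barcode_map, outdir / "barcodes.tsv")
        return truth

    genotypes = simulate_population(cfg, panel, rng)
    batch, truth = simulate_reads(
        cfg, panel, genotypes, offtargets=offtargets, rng=rng
    )
    truth.gmap = gmap
    write_fastq(batch, outdir / "reads.fastq")
    write_barcode_map(truth.barcode_map, outdir / "barcodes.tsv")
    genotypes.to_csv(outdir / "genotype_truth.tsv", sep="\t")
    return truth
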