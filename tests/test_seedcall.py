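"""Seed dereplication, masked-identity matching, filtering, and calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gms.keyfile import MarkerPanel, make_key_record
from gms.seedcall import (
    CallingConfig,
    Seed,
    assign_and_filter,
    assign_seeds,
    call_genotype,
    call_sample,
    calls_from_report,
    dereplicate,
    filter_seeds,
    match_seed,
    snp_report,
    hit_report,
    write_reports,
    read_snp_report,
    MarkerSeeds,
)
from gms.demux import ReadBatch


def _panel(*amplicons):
    return MarkerPanel(
        records=[make_key_record(f"m{i}", s)[0] for i, s in enumerate(amplicons)]
    )


def _batch(seqs):
    return ReadBatch(reads=[(f"r{i}", s, None) for i, s in enumerate(seqs)])


class TestDereplicate:
    def test_counts(self):
        seeds = dereplicate(_batch(["ACGT", "ACGT", "ACGA"]))
        assert {(s.sequence, s.count) for s in seeds} == {("ACGT", 2), ("ACGA", 1)}

    def test_empty(self):
        assert dereplicate(_batch([])) == []

    @given(st.lists(st.text(alphabet="ACGT", min_size=4, max_size=8), max_size=60))
    @settings(derandomize=True, max_examples=50)
    def test_multiset_reconstruction(self, seqs):
        seeds = dereplicate(seqs)
        rebuilt = sorted(sum(([s.sequence] * s.count for s in seeds), []))
        assert rebuilt == sorted(seqs)
        assert len({s.sequence for s in seeds}) == len(seeds)


class TestMatchSeed:
    cfg = CallingConfig()

    def test_perfect_allele_match(self):
        panel = _panel("ACGTRACGT")
        rec = panel["m0"]
        a_seq, _ = rec.expected_allele_sequences()
        m = match_seed(Seed(a_seq, 1), rec, self.cfg)
        assert (m.identity, m.allele_at_snp) == (1.0, "A")

    def test_single_offsite_mismatch_on_150mer(self):
        seq = "AC" * 70 + "GT" * 4 + "AC"  # 150 bases
        amplicon = seq[:75] + "R" + seq[76:]
        rec, _ = make_key_record("m", amplicon)
        a_seq = rec.expected_allele_sequences()[0]
        mutated = "T" + a_seq[1:]  # one non-SNP mismatch
        # oracle: count matches position by position, SNP excluded
        expected = sum(
            1 for i, (x, y) in enumerate(zip(mutated, rec.amplicon))
            if x == y and i != rec.snp_index
        ) / (len(amplicon) - 1)
        m = match_seed(Seed(mutated, 1), rec, self.cfg)
        assert m.identity == pytest.approx(expected)
        assert m.identity == pytest.approx(148 / 149)

    def test_mismatch_only_at_snp_is_full_identity(self):
        rec, _ = make_key_record("m", "ACGTRACGT")
        m = match_seed(Seed("ACGTTACGT", 1), rec, self.cfg)  # T not in {A,G}
        assert m.identity == 1.0
        assert m.allele_at_snp == "T"

    def test_length_discordant_alignment(self):
        rec, _ = make_key_record("m", "ACGTACGTRACGTACGT")
        a_seq = rec.expected_allele_sequences()[0]
        deleted = a_seq[:3] + a_seq[4:]  # one deletion upstream of the SNP
        m = match_seed(Seed(deleted, 1), rec, self.cfg)
        assert m.identity < 1.0
        assert m.allele_at_snp == "A"  # SNP column still readable

    def test_gap_at_snp_column_gives_undefined_allele(self):
        rec, _ = make_key_record("m", "ACCTACGGRTCGTACGT")
        a_seq = rec.expected_allele_sequences()[0]
        dropped = a_seq[: rec.snp_index] + a_seq[rec.snp_index + 1 :]
        m = match_seed(Seed(dropped, 1), rec, self.cfg)
        assert m.allele_at_snp is None


class TestAssignAndFilter:
    def test_ten_percent_rule_arithmetic(self):
        panel = _panel("ACGTACGTACRTACGTACGTA")
        rec = panel["m0"]
        a_seq, b_seq = rec.expected_allele_sequences()
        error_seed = rec.amplicon.replace("R", "T")  # off-allele at SNP
        seeds = [Seed(a_seq, 90), Seed(error_seed, 9), Seed(b_seq, 1)]
        surviving = assign_and_filter(seeds, panel, CallingConfig())
        kept = {m.seed.sequence for m in surviving.per_marker["m0"].matches}
        assert kept == {a_seq}

    def test_boundary_exactly_ten_percent_is_kept(self):
        panel = _panel("ACGTACGTACRTACGTACGTA")
        rec = panel["m0"]
        a_seq, b_seq = rec.expected_allele_sequences()
        seeds = [Seed(a_seq, 10), Seed(b_seq, 90)]
        surviving = assign_and_filter(seeds, panel, CallingConfig())
        kept = {m.seed.sequence for m in surviving.per_marker["m0"].matches}
        assert kept == {a_seq, b_seq}  # 10/100 is >= 10%, inclusive

    def test_singleton_noise_discarded_at_relaxed_identity(self):
        # 90 distinct near-miss singletons against 10 true-allele reads
        panel = _panel("ACGTACGTACRTACGTACGTA")
        rec = panel["m0"]
        a_seq = rec.expected_allele_sequences()[0]
        noise = []
        for i in range(len(a_seq)):
            if i == rec.snp_index:
                continue
            for b in "ACGT":
                if b != a_seq[i]:
                    noise.append(a_seq[:i] + b + a_seq[i + 1 :])
        noise = noise[:90]
        seeds = [Seed(a_seq, 10)] + [Seed(s, 1) for s in noise]
        cfg = CallingConfig(identity_threshold=0.9)
        surviving = assign_and_filter(seeds, panel, cfg)
        kept = {m.seed.sequence for m in surviving.per_marker["m0"].matches}
        assert kept == {a_seq}  # 10/100 kept, each 1% singleton discarded

    def test_no_identity_match_leaves_marker_absent(self):
        panel = _panel("ACGTACGTACRTACGTACGTA")
        surviving = assign_and_filter(
            [Seed("T" * 21, 50)], panel, CallingConfig()
        )
        assert surviving.per_marker == {}
        assert len(surviving.unassigned) == 1

    def test_tie_between_markers_excluded_and_logged(self):
        # two keys differing only at their (shared) SNP position
        panel = _panel("ACGTACGTACRTACGTACGTA", "ACGTACGTACYTACGTACGTA")
        seed = Seed("ACGTACGTACATACGTACGTA", 30)
        result = assign_seeds([seed], panel, CallingConfig())
        assert result.per_marker == {}
        assert result.ambiguous == [seed]

    def test_fast_and_scan_paths_agree_at_full_identity(self, small_sim):
        cfg, panel, genotypes, batch, truth = small_sim
        from gms.demux import demultiplex
        from gms.seedcall import _assign_scan

        sample = demultiplex(batch, truth.barcode_map).by_sample["S000"]
        seeds = dereplicate(sample)
        ccfg = CallingConfig()
        fast = assign_seeds(seeds, panel, ccfg)
        scan = _assign_scan(seeds, panel, ccfg)
        scan.per_marker = {
            m: ms for m, ms in scan.per_marker.items()
        }
        # the scan path assigns a superset (identity < 1 best hits) — compare
        # only at-threshold assignments
        scan_at_1 = {
            m: {(x.seed.sequence, x.seed.count) for x in ms.matches if x.identity == 1.0}
            for m, ms in scan.per_marker.items()
        }
        scan_at_1 = {m: v for m, v in scan_at_1.items() if v}
        fast_set = {
            m: {(x.seed.sequence, x.seed.count) for x in ms.matches}
            for m, ms in fast.per_marker.items()
        }
        assert fast_set == scan_at_1

    def test_monotonicity_in_thresholds(self, small_sim):
        cfg, panel, genotypes, batch, truth = small_sim
        from gms.demux import demultiplex

        sample = demultiplex(batch, truth.barcode_map).by_sample["S001"]
        seeds = dereplicate(sample)

        def n_surviving(identity, fraction):
            c = CallingConfig(identity_threshold=identity, min_seed_fraction=fraction)
            result = assign_and_filter(seeds, panel, c)
            return sum(len(ms.matches) for ms in result.per_marker.values())

        assert n_surviving(1.0, 0.10) <= n_surviving(1.0, 0.05)
        assert n_surviving(1.0, 0.10) <= n_surviving(0.95, 0.10)


class TestCallGenotype:
    cfg = CallingConfig()

    def _marker_seeds(self, rec, spec):
        """spec: list of (sequence, count) assigned to the marker."""
        matches = [
            match_seed(Seed(s, n), rec, self.cfg) for s, n in spec
        ]
        return MarkerSeeds(rec.marker_id, matches=matches)

    def test_het_hom_missing(self):
        rec, _ = make_key_record("m", "ACGTACGTACRTACGTACGTA")
        a_seq, b_seq = rec.expected_allele_sequences()
        het = call_genotype(
            self._marker_seeds(rec, [(a_seq, 50), (b_seq, 45)]), rec, "s", self.cfg
        )
        assert (het.call, het.depth_a, het.depth_b) == ("het", 50, 45)
        hom = call_genotype(
            self._marker_seeds(rec, [(a_seq, 95)]), rec, "s", self.cfg
        )
        assert (hom.call, hom.depth_a, hom.depth_b) == ("hom_a", 95, 0)
        missing = call_genotype(None, rec, "s", self.cfg)
        assert missing.call == "missing"

    def test_depth_floor_forces_missing(self):
        rec, _ = make_key_record("m", "ACGTACGTACRTACGTACGTA")
        a_seq, _ = rec.expected_allele_sequences()
        call = call_genotype(
            self._marker_seeds(rec, [(a_seq, 3)]), rec, "s", self.cfg
        )
        assert call.call == "missing"
        no_floor = call_genotype(
            self._marker_seeds(rec, [(a_seq, 3)]),
            rec, "s", CallingConfig(min_marker_depth=0),
        )
        assert no_floor.call == "hom_a"

    def test_off_allele_counts_toward_total_only(self):
        rec, _ = make_key_record("m", "ACGTACGTACRTACGTACGTA")
        a_seq, _ = rec.expected_allele_sequences()
        off = rec.amplicon.replace("R", "T")
        call = call_genotype(
            self._marker_seeds(rec, [(a_seq, 60), (off, 40)]), rec, "s", self.cfg
        )
        assert (call.call, call.depth_a, call.depth_b) == ("hom_a", 60, 0)
        assert call.total_marker_reads == 100


class TestOracleEquivalence:
    """Brute-force per-read implementation vs the seed-based pipeline."""

    @staticmethod
    def _brute_force(reads, panel, cfg):
        counts = {}
        for r in reads:
            counts[r] = counts.get(r, 0) + 1
        per_marker_seeds = {}
        for seq, n in counts.items():
            scored = []
            for rec in panel:
                if len(seq) != len(rec.amplicon):
                    continue
                hits = 0
                for i in range(len(seq)):
                    if i != rec.snp_index and seq[i] == rec.amplicon[i]:
                        hits += 1
                scored.append((hits / (len(seq) - 1), rec.marker_id))
            if not scored:
                continue
            best = max(s[0] for s in scored)
            winners = [m for s, m in scored if s == best]
            if best >= cfg.identity_threshold and len(winners) == 1:
                per_marker_seeds.setdefault(winners[0], []).append((seq, n))
        calls = {}
        for rec in panel:
            assigned = per_marker_seeds.get(rec.marker_id, [])
            total = sum(n for _, n in assigned)
            kept = [
                (s, n) for s, n in assigned
                if total and n / total >= cfg.min_seed_fraction
            ]
            da = sum(n for s, n in kept if s[rec.snp_index] == rec.alleles[0])
            db = sum(n for s, n in kept if s[rec.snp_index] == rec.alleles[1])
            if not kept or total < cfg.min_marker_depth or (da == 0 and db == 0):
                call = "missing"
            elif da and db:
                call = "het"
            else:
                call = "hom_a" if da else "hom_b"
            calls[rec.marker_id] = (call, da, db, total)
        return calls

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_markers = int(rng.integers(1, 6))
        length = 30
        records = []
        for i in range(n_markers):
            body = "".join("ACGT"[j] for j in rng.integers(0, 4, length))
            idx = int(rng.integers(2, length - 2))
            code = str(rng.choice(list("RYSWKM")))
            records.append(make_key_record(f"m{i}", body[:idx] + code + body[idx + 1 :])[0])
        panel = MarkerPanel(records=records)
        reads = []
        for rec in panel:
            a_seq, b_seq = rec.expected_allele_sequences()
            for _ in range(int(rng.integers(0, 40))):
                base = a_seq if rng.random() < 0.6 else b_seq
                if rng.random() < 0.2:  # sprinkle substitution errors
                    i = int(rng.integers(0, length))
                    base = base[:i] + str(rng.choice(list("ACGT"))) + base[i + 1 :]
                reads.append(base)
        reads = reads[:200]
        cfg = CallingConfig(min_marker_depth=2)
        expected = self._brute_force(reads, panel, cfg)
        result = call_sample(_batch(reads), panel, cfg, "s")
        got = {
            m: (c.call, c.depth_a, c.depth_b, c.total_marker_reads)
            for m, c in result.calls.items()
        }
        assert got == expected


class TestReports:
    def test_cells_and_roundtrip(self, tmp_path, tiny_panel):
        recs = {r.marker_id: r for r in tiny_panel}
        reads = []
        a_seq, b_seq = recs["mA"].expected_allele_sequences()
        reads += [a_seq] * 30 + [b_seq] * 30          # het on mA
        c_seq = recs["mB"].expected_allele_sequences()[1]
        reads += [c_seq] * 40                          # hom T on mB
        results = {"s1": call_sample(_batch(reads), tiny_panel, CallingConfig(), "s1")}
        snp = snp_report(results, tiny_panel)
        assert snp.at["s1", "mA"] == "R"      # het A/G -> IUPAC R
        assert snp.at["s1", "mB"] == "T"
        assert snp.at["s1", "mC"] == "-"      # no reads
        hits = hit_report(results, tiny_panel)
        assert hits.at["s1", "mA"] == 60
        assert hits.at["s1", "mC"] == 0

        paths = write_reports(results, tiny_panel, tmp_path)
        decoded = calls_from_report(read_snp_report(paths["snp"]), tiny_panel)
        assert decoded["s1"] == {"mA": "het", "mB": "hom_b", "mC": "missing"}
        msa = (tmp_path / "msa" / "mA.msa.fasta").read_text().splitlines()
        assert msa[0] == ">mA|key"
        assert msa[1] == recs["mA"].amplicon

    def test_read_count_conservation(self, small_sim):
        cfg, panel, genotypes, batch, truth = small_sim
        from gms.demux import demultiplex

        sample = demultiplex(batch, truth.barcode_map).by_sample["S002"]
        seeds = dereplicate(sample)
        assigned = assign_seeds(seeds, panel, CallingConfig())
        total = (
            sum(ms.total_reads for ms in assigned.per_marker.values())
            + sum(s.count for s in assigned.ambiguous)
            + sum(s.count for s in assigned.unassigned)
        )
        assert total == len(sample)
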