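import random

import pytest

from frtscan import (
    GenomeLayout,
    PlantedSite,
    SyntheticGenomeSpec,
    generate_genome,
    random_site,
    revcomp,
    scan_genome,
)
from frtscan.scanner import partition_duplicates, scan_chunks, scan_contig

from oracle import oracle_scan


def embed(site, left_flank, right_flank, rng):
    """Site with random flanks, re-drawn until the flanks add no extra
    accepted windows (verified by the independent oracle)."""
    for _ in range(50):
        contig = ("".join(rng.choice("ACGT") for _ in range(left_flank))
                  + site
                  + "".join(rng.choice("ACGT") for _ in range(right_flank)))
        if oracle_scan(contig) == [left_flank]:
            return contig
    raise AssertionError("could not build a clean flank fixture")


class TestScanContig:
    def test_single_planted_site_found_at_offset(self, model, rng):
        site = random_site(8, model, rng)
        contig = embed(site, 50, 50, rng)
        hits = scan_contig(contig, "c1", model)
        assert [(h.contig_offset, h.sequence) for h in hits] == [(50, site)]

    def test_contig_below_window_size_is_empty(self, model):
        assert scan_contig("A" * 33, "c1", model) == []

    def test_chunked_equals_whole_string(self, model):
        rng = random.Random(3)
        pieces = []
        for _ in range(10):
            pieces.append("".join(rng.choice("ACGT") for _ in range(9_500)))
            pieces.append(random_site(rng.choice([5, 6, 7, 8]), model, rng))
        contig = "".join(pieces)
        assert len(contig) > 90_000
        chunked = scan_contig(contig, "c", model)  # internally 10-kb chunks
        # degenerate chunking: whole string in one piece, and tiny pieces
        whole = list(scan_chunks([contig], "c", model))
        tiny = list(scan_chunks(
            [contig[i:i + 997] for i in range(0, len(contig), 997)], "c", model))
        offsets = [h.contig_offset for h in chunked]
        assert offsets == [h.contig_offset for h in whole]
        assert offsets == [h.contig_offset for h in tiny]
        assert [h.sequence for h in chunked] == [h.sequence for h in whole]

    def test_masked_windows_are_skipped_not_fatal(self, model, rng):
        site = random_site(8, model, rng)
        contig = "N" * 40 + site + "N" * 40
        hits = scan_contig(contig, "c", model)
        assert [h.contig_offset for h in hits] == [40]


class TestScanGenome:
    def test_linear_coordinates_across_contigs(self, model, rng, tmp_path):
        site = random_site(8, model, rng)
        c2 = embed(site, 10, 56, rng)
        c1 = embed(random_site(7, model, rng), 300, 666, rng)
        (tmp_path / "a.fa").write_text(f">c1\n{c1}\n>c2\n{c2}\n")
        layout = GenomeLayout.from_records(
            [("chr1", 1, "c1", 1000), ("chr1", 2, "c2", 100)])
        result = scan_genome(tmp_path, layout, model)
        positions = {(h.contig_id, h.contig_offset, h.chrom_linear_pos)
                     for h in result.hits}
        assert positions == {("c1", 300, 300), ("c2", 10, 1010)}

    def test_planted_sites_recovered_exactly(self, model, fixture_genome):
        result = scan_genome(fixture_genome.fasta_dir, fixture_genome.layout, model)
        got = {(h.chromosome, h.chrom_linear_pos, h.sequence) for h in result.hits}
        want = {(r.chromosome, r.pos_0based, r.sequence)
                for r in fixture_genome.truth.itertuples()}
        assert got == want

    def test_empty_directory_is_an_error(self, model, tmp_path):
        layout = GenomeLayout.from_records([("chr1", 1, "c1", 100)])
        with pytest.raises(FileNotFoundError, match="no FASTA inputs"):
            scan_genome(tmp_path, layout, model)

    def test_conservation_law(self, model, fixture_genome):
        result = scan_genome(fixture_genome.fasta_dir, fixture_genome.layout, model)
        assert len(result.hits) == (
            len(result.unique_pool)
            + sum(g.copy_number for g in result.duplicate_groups))

    def test_revcomp_genome_same_canonical_multiset(self, model, fixture_genome, tmp_path):
        flipped_dir = tmp_path / "flipped"
        flipped_dir.mkdir()
        records = []
        for chrom, contigs in fixture_genome.layout.ordered_contigs.items():
            # reverse contig order too, so the chromosome is truly mirrored
            lines = []
            for i, (cid, length) in enumerate(reversed(contigs), start=1):
                seq = None
                for c2, s in _contig_seqs(fixture_genome):
                    if c2 == cid:
                        seq = s
                lines.append(f">rc_{cid}")
                lines.append(revcomp(seq))
                records.append((chrom, i, f"rc_{cid}", length))
            (flipped_dir / f"{chrom}.fa").write_text("\n".join(lines) + "\n")
        flipped_layout = GenomeLayout.from_records(records)
        fwd = scan_genome(fixture_genome.fasta_dir, fixture_genome.layout, model)
        rev = scan_genome(flipped_dir, flipped_layout, model)
        assert sorted(h.canonical_seq for h in fwd.hits) == \
               sorted(h.canonical_seq for h in rev.hits)


def _contig_seqs(gen):
    from frtscan.io import read_fasta_dir

    yield from read_fasta_dir(gen.fasta_dir, gen.layout)


class TestPartitionDuplicates:
    def _site(self, seq, model, pos=0, chrom="chr1"):
        from frtscan.scanner import _make_site

        site = _make_site(seq, pos, "c", chrom, pos, model)
        assert site is not None
        return site

    def test_forward_and_reverse_copies_group_together(self, model, rng):
        s = random_site(8, model, rng)
        hits = [self._site(s, model, 0),
                self._site(s, model, 100),
                self._site(revcomp(s), model, 200)]
        unique, groups = partition_duplicates(hits)
        assert unique == []
        assert len(groups) == 1 and groups[0].copy_number == 3
        assert groups[0].canonical_seq == min(s, revcomp(s))

    def test_all_distinct_gives_no_groups(self, model, rng):
        hits = []
        seen = set()
        while len(hits) < 5:
            s = random_site(8, model, rng)
            if min(s, revcomp(s)) not in seen:
                seen.add(min(s, revcomp(s)))
                hits.append(self._site(s, model, 100 * len(hits)))
        unique, groups = partition_duplicates(hits)
        assert groups == [] and len(unique) == 5

    def test_repeat_family_with_mutated_copy(self, model, fixture_genome):
        """Six verbatim repeat copies form one group of 6; truth agrees."""
        result = scan_genome(fixture_genome.fasta_dir, fixture_genome.layout, model)
        truth = fixture_genome.truth
        truth_groups = truth[truth.group_id != ""].groupby("group_id")
        scan_groups = {g.canonical_seq: g.copy_number
                       for g in result.duplicate_groups}
        assert any(n == 6 for n in scan_groups.values())
        for _, rows in truth_groups:
            canon = min(rows.sequence.iloc[0], revcomp(rows.sequence.iloc[0]))
            assert scan_groups[canon] == len(rows)
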