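import math

import pytest

from bhlhscan.introns import (
    INTRONLESS_LABEL,
    IntronEvent,
    IntronPatternRegistry,
    assign_pattern,
    cds_junction_offsets,
    domain_cds_interval,
    gene_structure_stats,
    map_introns_to_domain,
    pattern_distribution,
)
from bhlhscan.io import GeneModel
from bhlhscan.scan import DomainHit, RegionTemplate
from bhlhscan.simulate import FamilySpec, generate_family


def _hit(pid="p", start=10, loop=6):
    spans01 = RegionTemplate().spans(loop)
    spans = {r: (start + s - 1, start + e - 1) for r, (s, e) in spans01.items()}
    length = 54 + loop
    return DomainHit(
        protein_id=pid, start=start, end=start + length - 1, loop_length=loop,
        region_spans=spans,
        mismatches_by_region={"basic": 0, "helix1": 0, "loop": 0, "helix2": 0},
        accepted=True,
    )


def _toy_gene(cut, cds_len=300, strand="+"):
    """A two-exon plus- or minus-strand gene whose single intron sits after
    ``cut`` spliced-CDS nucleotides."""
    intron = 100
    if strand == "+":
        exons = [(1, cut), (cut + intron + 1, cds_len + intron)]
    else:
        total = cds_len + intron
        # mirror the plus-strand layout; transcription runs high -> low
        exons = [(total - cut + 1, total), (1, total - cut - intron)]
    cds = []
    cumulative = 0
    for s, e in exons:
        cds.append((s, e, (3 - cumulative % 3) % 3))
        cumulative += e - s + 1
    return GeneModel(
        gene_id="g", transcript_id="t", strand=strand, chromosome="chr1",
        exons=exons, cds=cds,
    )


class TestDomainCdsInterval:
    def test_arithmetic(self):
        gene = _toy_gene(cut=100, cds_len=300)
        assert domain_cds_interval(gene, _hit(start=10)) == (28, 207)

    def test_domain_at_protein_start(self):
        gene = _toy_gene(cut=100, cds_len=300)
        assert domain_cds_interval(gene, _hit(start=1))[0] == 1

    def test_domain_beyond_cds_rejected(self):
        gene = _toy_gene(cut=50, cds_len=120)
        with pytest.raises(ValueError, match="only 120"):
            domain_cds_interval(gene, _hit(start=10))


class TestMapIntrons:
    def test_single_exon_gene_has_no_events(self):
        gene = GeneModel(
            gene_id="g", transcript_id="t", strand="+", chromosome="c",
            exons=[(1, 300)], cds=[(1, 300, 0)],
        )
        assert map_introns_to_domain(gene, _hit(start=10)) == []

    def test_intron_after_first_nucleotide_of_codon_30(self):
        # domain starts at protein residue 10 -> domain CDS starts at 28;
        # an intron after CDS nucleotide 27 + 3*29 + 1 = 115 interrupts
        # domain codon 30 with phase 1
        gene = _toy_gene(cut=115, cds_len=300)
        events = map_introns_to_domain(gene, _hit(start=10))
        assert len(events) == 1
        assert (events[0].domain_codon, events[0].phase) == (30, 1)
        assert events[0].region == "helix1"

    def test_minus_strand_gives_identical_event(self):
        plus = map_introns_to_domain(_toy_gene(cut=115, strand="+"), _hit(start=10))
        minus = map_introns_to_domain(_toy_gene(cut=115, strand="-"), _hit(start=10))
        assert plus == minus

    def test_intron_outside_domain_ignored(self):
        gene = _toy_gene(cut=12, cds_len=300)  # before the domain interval
        assert map_introns_to_domain(gene, _hit(start=10)) == []

    @pytest.mark.parametrize("phase", [0, 1, 2])
    def test_exhaustive_codon_phase_round_trip(self, phase, scanner):
        """Planting an intron at every domain codon and phase maps back
        exactly (the generator-to-analysis coordinate round trip)."""
        for codon in range(1, 61):
            spec = FamilySpec(
                n_genes=1, seed=900 + codon,
                intron_blueprints=((((codon, phase),), 1.0),),
                loop_length_distribution={6: 1.0},
                binding_category_mix={"G_binder": 1.0},
                expression_class_mix={"broad": 1.0},
            )
            data = generate_family(spec)
            hit = scanner.predict(data.proteins)[0]
            assert hit.accepted
            events = map_introns_to_domain(data.genes[0], hit)
            assert [(e.domain_codon, e.phase) for e in events] == [(codon, phase)]

    def test_invalid_phase_rejected(self):
        with pytest.raises(ValueError):
            IntronEvent(domain_codon=5, phase=3, region="basic")


class TestPatternRegistry:
    def _events(self, *pairs):
        return [IntronEvent(domain_codon=c, phase=p, region="loop") for c, p in pairs]

    def test_identical_signatures_share_label(self):
        reg = IntronPatternRegistry()
        p1 = assign_pattern(self._events((35, 0)), reg, 60)
        p2 = assign_pattern(self._events((35, 0)), reg, 60)
        assert p1.label == p2.label == "A"

    def test_intronless_reserved_label(self):
        reg = IntronPatternRegistry()
        pattern = assign_pattern([], reg, 60)
        assert pattern.label == INTRONLESS_LABEL
        assert pattern.n_introns == 0

    def test_phase_difference_separates_patterns(self):
        reg = IntronPatternRegistry()
        p1 = assign_pattern(self._events((35, 0)), reg, 60)
        p2 = assign_pattern(self._events((35, 1)), reg, 60)
        assert p1.label != p2.label

    def test_positions_within_tolerance_merge(self):
        reg = IntronPatternRegistry(tolerance=2.0)
        p1 = assign_pattern(self._events((35, 0)), reg, 60)
        p2 = assign_pattern(self._events((37, 0)), reg, 60)
        p3 = assign_pattern(self._events((38, 0)), reg, 60)
        assert p1.label == p2.label
        assert p3.label != p1.label

    def test_loop_length_normalization_merges_across_domain_lengths(self):
        # same canonical intron in a loop-6 (60 aa) and loop-7 (61 aa) domain
        reg = IntronPatternRegistry()
        p60 = assign_pattern(self._events((35, 0)), reg, 60)
        p61 = assign_pattern(self._events((35, 0)), reg, 61)
        assert p60.label == p61.label

    def test_registry_order_determinism(self):
        events = {
            "g_b": (self._events((35, 0)), 60),
            "g_a": (self._events((10, 0), (35, 0), (50, 0)), 60),
            "g_c": (self._events((24, 1)), 60),
        }
        reg1 = IntronPatternRegistry().fit(events)
        shuffled = {k: events[k] for k in ["g_c", "g_b", "g_a"]}
        reg2 = IntronPatternRegistry().fit(shuffled)
        assert reg1.transform(events)["g_b"].label == reg2.transform(events)["g_b"].label
        assert [lbl for _, lbl in reg1.entries_] == [lbl for _, lbl in reg2.entries_]

    def test_save_load_round_trip(self, tmp_path):
        reg = IntronPatternRegistry()
        reg.assign(self._events((35, 0)), 60)
        reg.assign(self._events((10, 0), (50, 2)), 60)
        path = tmp_path / "registry.yaml"
        reg.save(path)
        back = IntronPatternRegistry.load(path)
        assert back.entries_ == reg.entries_
        assert back.tolerance == reg.tolerance


class TestPatternDistribution:
    def test_subfamily_reference_percentage(self):
        # 87 of 93 genes sharing one pattern -> 93.55%
        reg = IntronPatternRegistry()
        patterns = {}
        for i in range(87):
            patterns[f"xii_{i:03d}"] = assign_pattern(
                [IntronEvent(10, 0, "basic"), IntronEvent(35, 0, "loop"),
                 IntronEvent(50, 0, "helix2")], reg, 60)
        for i in range(6):
            patterns[f"xii_rest_{i}"] = assign_pattern([], reg, 60)
        dist = pattern_distribution(patterns, {g: "XII" for g in patterns})
        row = dist[dist["pattern"] == "A"].iloc[0]
        assert row["count"] == 87 and row["percentage"] == 93.55

    def test_single_gene_is_100_percent(self):
        reg = IntronPatternRegistry()
        patterns = {"g": assign_pattern([], reg, 60)}
        dist = pattern_distribution(patterns, {"g": "wheat"})
        assert dist.iloc[0]["percentage"] == 100.00

    def test_counts_conserved(self, clean_family, scanner, clean_hits):
        reg = IntronPatternRegistry()
        events = {
            p.id: (map_introns_to_domain(g, h), h.length)
            for p, g, h in zip(clean_family.proteins, clean_family.genes, clean_hits)
        }
        patterns = reg.fit_transform(events)
        dist = pattern_distribution(patterns, {p.id: p.species for p in clean_family.proteins})
        assert dist["count"].sum() == len(clean_family.proteins)


class TestGeneStructureStats:
    def test_single_exon_gene_is_intronless(self):
        gene = GeneModel(
            gene_id="g", transcript_id="t", strand="+", chromosome="c",
            exons=[(1, 300)], cds=[(1, 300, 0)],
        )
        stats = gene_structure_stats([gene]).iloc[0]
        assert stats["intronless"] and stats["exon_count"] == 1

    def test_phase_zero_flanked_exon_is_symmetric(self):
        # three exons of length 99/99/102: both introns fall between codons
        exons = [(1, 99), (200, 298), (400, 501)]
        cds = [(1, 99, 0), (200, 298, 0), (400, 501, 0)]
        gene = GeneModel(
            gene_id="g", transcript_id="t", strand="+", chromosome="c",
            exons=exons, cds=cds,
        )
        stats = gene_structure_stats([gene]).iloc[0]
        assert stats["symmetric_phase0_fraction"] == 1.0

    def test_matches_brute_force_recomputation(self, clean_family):
        stats = gene_structure_stats(clean_family.genes).set_index("transcript_id")
        for gene in clean_family.genes:
            # independent recomputation straight from the intervals
            lengths = [e - s + 1 for s, e, _ in gene.cds]
            offsets = []
            total = 0
            for ln in lengths[:-1]:
                total += ln
                offsets.append(total)
            assert offsets == cds_junction_offsets(gene)
            row = stats.loc[gene.transcript_id]
            assert row["exon_count"] == len(gene.exons)
            assert row["intronless"] == (len(gene.cds) == 1)
            internal = [
                1 if offsets[i - 1] % 3 == 0 and offsets[i] % 3 == 0 else 0
                for i in range(1, len(gene.cds) - 1)
            ]
            expected = sum(internal) / len(internal) if internal else 0.0
            assert math.isclose(row["symmetric_phase0_fraction"], round(expected, 4))
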