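import numpy as np
import pytest

from regulonkit.genome_io import Gene, Genome
from regulonkit.pwm_scanner import STRONG, Site
from regulonkit.regulon_builder import (
    CohortContext,
    Operon,
    assemble_regulons,
    call_operons,
    consistency_check,
)
from regulonkit.tf_catalog import OrthoGroup, TFRecord


def _genome(spec, genome_id="G1", length=10_000):
    """spec: list of (start, end, strand)."""
    genes = [
        Gene(f"g{i}", s, e, strand) for i, (s, e, strand) in enumerate(spec)
    ]
    return Genome(genome_id, "A" * length, genes)


class TestCallOperons:
    def test_small_gap_chains_codirectional_genes(self):
        g = _genome([(100, 400, "+"), (550, 900, "+")])  # gap 150
        ops = call_operons(g)
        assert [o.gene_ids for o in ops] == [("g0", "g1")]

    def test_gap_above_200_splits(self):
        g = _genome([(100, 400, "+"), (650, 900, "+")])  # gap 250
        ops = call_operons(g)
        assert [o.gene_ids for o in ops] == [("g0",), ("g1",)]

    def test_opposite_strands_never_chain(self):
        g = _genome([(100, 400, "+"), (450, 900, "-")])  # gap 50
        assert len(call_operons(g)) == 2

    def test_minus_strand_operon_first_gene_is_promoter_proximal(self):
        g = _genome([(100, 400, "-"), (450, 900, "-")])
        (op,) = call_operons(g)
        assert op.first_gene == "g1"  # 5'-most in transcription direction

    def test_partition_and_idempotence(self, rng):
        for _ in range(20):
            spec, cursor = [], 0
            for _ in range(rng.integers(3, 15)):
                cursor += int(rng.integers(0, 400))
                length = int(rng.integers(200, 900))
                spec.append(
                    (cursor, cursor + length, "+-"[rng.integers(2)])
                )
                cursor += length
            g = _genome(spec, length=cursor + 100)
            ops = call_operons(g)
            covered = [gid for o in ops for gid in o.gene_ids]
            assert sorted(covered) == sorted(x.gene_id for x in g.genes)

    def test_matches_bruteforce_oracle_on_random_layouts(self):
        # oracle: examine every consecutive pair independently
        rng = np.random.default_rng(123)
        for _ in range(100):
            spec, cursor = [], 0
            for _ in range(int(rng.integers(2, 30))):
                cursor += int(rng.integers(0, 350))
                length = int(rng.integers(150, 1200))
                spec.append((cursor, cursor + length, "+-"[rng.integers(2)]))
                cursor += length
            g = _genome(spec, length=cursor + 10)
            ops = call_operons(g)
            # oracle partition
            genes = g.genes
            oracle, chain = [], [genes[0]]
            for prev, gene in zip(genes, genes[1:]):
                if gene.strand == prev.strand and gene.start - prev.end <= 200:
                    chain.append(gene)
                else:
                    oracle.append(chain)
                    chain = [gene]
            oracle.append(chain)
            got = [set(o.gene_ids) for o in ops]
            assert got == [set(x.gene_id for x in c) for c in oracle]

    def test_conservation_context_splits_unsupported_links(self):
        spec = [(100, 400, "+"), (500, 900, "+")]
        g1 = _genome(spec, "G1")
        labels = {"g0": "opA", "g1": "opB"}
        # adjacency seen in one genome only -> split
        ctx = CohortContext.build([g1], labels)
        assert len(call_operons(g1, conservation=ctx, ortholog_map=labels)) == 2
        # same adjacency in a second genome -> kept
        g2 = _genome(spec, "G2")
        ctx = CohortContext.build([g1, g2], labels)
        assert len(call_operons(g1, conservation=ctx, ortholog_map=labels)) == 1


def _site(genome, gene, score=12.0):
    return Site(
        genome_id=genome, gene_id=gene, position=100, strand="+",
        word="TGTGAGCGCTCACA", score=score, rel_position=-80,
        site_class=STRONG,
    )


class TestConsistencyCheck:
    def _candidates(self):
        # ortholog family "fam1" has candidates in 3 genomes, "fam2" in 1
        omap = {"a1": "fam1", "a2": "fam1", "a3": "fam1", "b1": "fam2"}
        cands = {
            "G1": [("a1", _site("G1", "a1")), ("b1", _site("G1", "b1"))],
            "G2": [("a2", _site("G2", "a2"))],
            "G3": [("a3", _site("G3", "a3"))],
        }
        return cands, omap

    def test_recurrent_gene_accepted_single_genome_gene_rejected(self):
        cands, omap = self._candidates()
        accepted = consistency_check(cands, omap, min_support=2)
        genes = {g for entries in accepted.values() for g, _ in entries}
        assert genes == {"a1", "a2", "a3"}

    def test_min_support_one_is_identity(self):
        cands, omap = self._candidates()
        accepted = consistency_check(cands, omap, min_support=1)
        assert accepted == cands

    def test_accepted_set_shrinks_as_support_grows(self):
        cands, omap = self._candidates()
        sizes = []
        for support in (1, 2, 3, 4):
            accepted = consistency_check(cands, omap, min_support=support)
            sizes.append(sum(len(v) for v in accepted.values()))
        assert sizes == sorted(sizes, reverse=True)


class TestAssembleRegulons:
    def _group(self):
        return OrthoGroup(
            "OG1", [TFRecord("G1", "tf1", "LacI", frozenset())]
        )

    def test_membership_extends_to_whole_operon(self):
        operon = Operon("G1", ("a", "b", "c"), "+")
        regulons, totals = assemble_regulons(
            [self._group()],
            {"OG1": {"G1": [("a", _site("G1", "a"))]}},
            {"G1": [operon]},
        )
        assert regulons[0].n_genes == 3
        assert regulons[0].n_operons == 1
        assert totals == {"tfs": 1, "tfbs": 1, "operons": 1, "genes": 3}

    def test_empty_sites_give_zero_totals(self):
        regulons, totals = assemble_regulons(
            [self._group()], {}, {"G1": []}
        )
        assert totals == {"tfs": 0, "tfbs": 0, "operons": 0, "genes": 0}
        assert regulons[0].members == {}

    def test_dangling_gene_reference_is_rejected(self):
        with pytest.raises(ValueError, match="not the"):
            assemble_regulons(
                [self._group()],
                {"OG1": {"G1": [("zz", _site("G1", "zz"))]}},
                {"G1": [Operon("G1", ("a",), "+")]},
            )
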