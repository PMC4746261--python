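import filecmp

import numpy as np
import pytest

from regulonkit.evaluation import reverse_complement_iupac
from regulonkit.genome_io import upstream_region
from regulonkit.synthetic_cohort import (
    CohortConfig,
    generate_cohort,
    mutate_site,
    resolve_site_model,
    write_cohort,
)


def test_same_seed_gives_byte_identical_cohorts(tmp_path):
    cfg = CohortConfig(
        n_genomes=3, genome_length=80_000, n_tf_groups=2,
        decoy_fraction=0.0, seed=42,
    )
    dirs = []
    for name in ("a", "b"):
        out = tmp_path / name
        write_cohort(*generate_cohort(cfg), str(out))
        dirs.append(out)
    files = sorted(p.name for p in dirs[0].iterdir())
    match, mismatch, errors = filecmp.cmpfiles(
        dirs[0], dirs[1], files, shallow=False
    )
    assert sorted(match) == files and not mismatch and not errors


def test_planted_site_count_is_sites_per_regulon_times_genomes():
    cfg = CohortConfig(
        n_genomes=6, genome_length=120_000, n_tf_groups=1,
        sites_per_regulon=5, decoy_fraction=0.0, seed=3,
    )
    _, _, truth = generate_cohort(cfg)
    assert len(truth.sites) == 30


def test_realized_gc_content_matches_config():
    # binomial standard error at 100 kb: 3 * sqrt(0.6*0.4/1e5) ~ 0.005
    cfg = CohortConfig(
        n_genomes=1, genome_length=100_000, n_tf_groups=1,
        gc_content=0.60, decoy_fraction=0.0, seed=11,
    )
    genomes, _, _ = generate_cohort(cfg)
    gc = genomes[0].background[1] + genomes[0].background[2]
    assert abs(gc - 0.60) < 0.02


def test_planted_consensus_is_palindromic(small_cohort):
    _, _, truth = small_cohort
    for group in truth.groups.values():
        assert reverse_complement_iupac(group.consensus) == group.consensus


def test_planted_sites_lie_inside_upstream_windows(small_cohort):
    genomes, _, truth = small_cohort
    by_id = {g.genome_id: g for g in genomes}
    for site in truth.sites:
        region = upstream_region(by_id[site.genome_id], site.gene_id)
        offset = site.rel_position + region.offset_of_start
        assert 0 <= offset <= len(region) - len(site.word)
        assert region.sequence[offset : offset + len(site.word)] == site.word


def test_decoy_groups_have_no_planted_sites():
    cfg = CohortConfig(
        n_genomes=3, genome_length=100_000, n_tf_groups=4,
        decoy_fraction=0.5, seed=9,
    )
    _, _, truth = generate_cohort(cfg)
    decoys = {g for g, t in truth.groups.items() if t.decoy}
    assert len(decoys) == 2
    assert all(s.group_id not in decoys for s in truth.sites)


def test_decoy_sites_are_single_genome():
    cfg = CohortConfig(
        n_genomes=4, genome_length=120_000, n_tf_groups=2,
        decoy_fraction=0.0, decoy_site_fraction=0.25, seed=13,
    )
    _, _, truth = generate_cohort(cfg)
    assert truth.decoy_sites
    by_template = {}
    for s in truth.decoy_sites:
        template = s.operon_id.split(":", 1)[1]
        by_template.setdefault(template, set()).add(s.genome_id)
    assert all(len(gs) == 1 for gs in by_template.values())


def test_overfull_config_is_rejected_with_capacity_message():
    cfg = CohortConfig(
        n_genomes=2, genome_length=30_000, n_tf_groups=4,
        sites_per_regulon=8, decoy_fraction=0.0, seed=1,
    )
    with pytest.raises(ValueError, match="genome_length"):
        generate_cohort(cfg)


def test_tf_annotation_matches_truth(small_cohort):
    _, tf_table, truth = small_cohort
    annotated = set(zip(tf_table.genome_id, tf_table.gene_id))
    planted = {
        (genome, gene)
        for g in truth.groups.values()
        for genome, gene in g.tf_genes.items()
    }
    assert annotated == planted


class TestMutateSite:
    def test_rate_zero_is_identity(self, rng):
        assert mutate_site("TGATAAAACGTTTTATCA", 0.0, rng) == (
            "TGATAAAACGTTTTATCA"
        )

    def test_rate_one_substitutes_every_position(self, rng):
        word = "TGATAAAACGTTTTATCA"
        out = mutate_site(word, 1.0, rng)
        assert sum(a != b for a, b in zip(word, out)) == len(word)

    def test_mean_hamming_distance_matches_width_times_rate(self, rng):
        # Monte-Carlo oracle: expectation = 18 * 0.1 = 1.8
        word = "TGATAAAACGTTTTATCA"
        n = 10_000
        total = sum(
            sum(a != b for a, b in zip(word, mutate_site(word, 0.1, rng)))
            for _ in range(n)
        )
        assert abs(total / n - 1.8) < 0.05


def _column_ic(rate: float) -> float:
    if rate == 0:
        return 2.0
    return 2.0 + (1 - rate) * np.log2(1 - rate) + rate * np.log2(rate / 3.0)


@pytest.mark.parametrize("ic", [12.0, 16.0, 20.0])
def test_site_model_meets_information_target(ic):
    rate, core = resolve_site_model(ic, 18, None)
    assert core % 2 == 0
    assert abs(core * _column_ic(rate) - ic) <= 0.5
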