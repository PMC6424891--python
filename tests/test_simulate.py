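import math

import numpy as np
import pytest
from scipy import stats as sps

from farseq.alignments import filter_alignments
from farseq.counting import count_reads
from farseq.simulate import (
    CapacityError,
    RegulonSpec,
    SimulationConfig,
    build_genome,
    default_study_scenario,
    simulate_alignments,
    simulate_counts,
)


def small_config(**kw):
    params = dict(
        n_orfs=30,
        orf_length_range=(300, 1200),
        reference_length=60_000,
        conditions={"base": 1, "induced": 1},
        regulons=[
            RegulonSpec(
                name="reg",
                member_features=[f"orf{i:04d}" for i in range(1, 6)],
                fold_factor_by_condition={"induced": 20.0},
            )
        ],
        depth=50_000,
        seed=4,
    )
    params.update(kw)
    return SimulationConfig(**params)


class TestBuildGenome:
    def test_layout_counts_and_membership(self):
        ann, truth = build_genome(small_config())
        assert len(ann.protein_coding) == 30
        classes = {f.feature_class for f in ann.excluded_regions}
        assert classes == {"rRNA", "tRNA"}
        assert truth.regulon_members["reg"] == [f"orf{i:04d}" for i in range(1, 6)]

    def test_orfs_do_not_overlap(self):
        ann, _ = build_genome(small_config())
        feats = sorted(ann.features, key=lambda f: f.start)
        for a, b in zip(feats, feats[1:]):
            assert a.end < b.start

    def test_truth_sums_to_one(self):
        _, truth = build_genome(small_config())
        for cond in truth.conditions:
            assert truth.abundance_vector(cond).sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_unit_factors_give_unit_ratios(self):
        cfg = small_config(regulons=[])
        _, truth = build_genome(cfg)
        ratios = truth.expected_ratio("base", "induced")
        assert all(r == pytest.approx(1.0, abs=1e-12) for r in ratios.values())

    def test_expected_ratio_reflects_renormalization(self):
        _, truth = build_genome(small_config())
        ratios = truth.expected_ratio("base", "induced")
        member = ratios["orf0001"]
        outsider = ratios["orf0010"]
        # induction inflates the denominator, so realized ratios sit below
        # the raw factor and outsiders sit symmetrically below 1
        assert 1.0 < member < 20.0
        assert outsider < 1.0
        assert member / outsider == pytest.approx(20.0, rel=1e-9)

    def test_same_seed_identical_output(self):
        cfg = small_config()
        ann1, truth1 = build_genome(cfg)
        ann2, truth2 = build_genome(cfg)
        assert [(f.feature_id, f.start, f.end) for f in ann1] == [
            (f.feature_id, f.start, f.end) for f in ann2
        ]
        for cond in truth1.conditions:
            assert np.array_equal(
                truth1.abundance_vector(cond), truth2.abundance_vector(cond)
            )

    def test_capacity_error(self):
        with pytest.raises(CapacityError):
            build_genome(small_config(reference_length=5_000))


class TestSimulateCounts:
    def test_counts_within_binomial_bounds(self):
        cfg = small_config(n_orfs=10, regulons=[], baseline_abundance_law="uniform")
        _, truth = build_genome(cfg)
        table = simulate_counts(truth, "base", 1_000_000, seed=9)
        mean = 100_000
        sd = math.sqrt(1_000_000 * 0.1 * 0.9)
        for c in table.counts.values():
            assert abs(c - mean) < 4 * sd

    def test_depth_zero_rejected(self):
        _, truth = build_genome(small_config())
        with pytest.raises(ValueError):
            simulate_counts(truth, "base", 0, seed=1)

    def test_unknown_condition_rejected(self):
        _, truth = build_genome(small_config())
        with pytest.raises(KeyError):
            simulate_counts(truth, "nope", 100, seed=1)

    def test_same_seed_identical_counts(self):
        _, truth = build_genome(small_config())
        t1 = simulate_counts(truth, "base", 10_000, seed=3)
        t2 = simulate_counts(truth, "base", 10_000, seed=3)
        assert t1.counts == t2.counts

    def test_replicates_differ_but_conditions_isolated(self):
        _, truth = build_genome(small_config())
        r0 = simulate_counts(truth, "base", 10_000, seed=3, replicate=0)
        r1 = simulate_counts(truth, "base", 10_000, seed=3, replicate=1)
        assert r0.counts != r1.counts
        # drawing another condition does not perturb this one
        _ = simulate_counts(truth, "induced", 10_000, seed=3)
        again = simulate_counts(truth, "base", 10_000, seed=3, replicate=0)
        assert again.counts == r0.counts

    def test_overdispersion_inflates_variance(self):
        cfg = small_config(n_orfs=20, regulons=[], baseline_abundance_law="uniform")
        _, truth = build_genome(cfg)
        plain = np.array(
            [
                list(simulate_counts(truth, "base", 20_000, seed=s).counts.values())
                for s in range(30)
            ]
        )
        noisy = np.array(
            [
                list(
                    simulate_counts(
                        truth, "base", 20_000, seed=s, overdispersion=50.0
                    ).counts.values()
                )
                for s in range(30)
            ]
        )
        assert noisy.var(axis=0).mean() > 2 * plain.var(axis=0).mean()


class TestSimulateAlignments:
    def test_contamination_fractions_within_binomial_bounds(self):
        cfg = small_config(
            depth=50_000, rrna_fraction=0.05, non_unique_fraction=0.02, read_length=100
        )
        ann, truth = build_genome(cfg)
        records = simulate_alignments(truth, "base", cfg, seed=4)
        assert len(records) == cfg.depth
        n = cfg.depth
        rrna = [f for f in ann.excluded_regions if f.feature_class == "rRNA"]
        n_rrna = sum(
            1
            for r in records
            if any(r.start <= f.end and r.end >= f.start for f in rrna)
        )
        sd = math.sqrt(n * 0.05 * 0.95)
        assert abs(n_rrna - 0.05 * n) < 4 * sd
        n_nonuniq = sum(1 for r in records if not r.unique)
        sd = math.sqrt(n * 0.02 * 0.98)
        assert abs(n_nonuniq - 0.02 * n) < 4 * sd

    def test_reads_fully_contained_without_jitter(self):
        cfg = small_config(depth=5_000)
        ann, truth = build_genome(cfg)
        feats = sorted(ann.features, key=lambda f: f.start)
        records = simulate_alignments(truth, "base", cfg, seed=4)
        for rec in records[:500]:
            assert any(f.start <= rec.start and rec.end <= f.end for f in feats)

    def test_jitter_produces_partial_overlaps(self):
        cfg = small_config(depth=20_000)
        ann, truth = build_genome(cfg)
        records = simulate_alignments(truth, "base", cfg, seed=4, boundary_jitter=True)
        feats = list(ann.features)
        partial = sum(
            1
            for rec in records[:2000]
            if not any(f.start <= rec.start and rec.end <= f.end for f in feats)
            and any(f.start <= rec.end and rec.start <= f.end for f in feats)
        )
        assert partial > 0

    def test_read_length_exceeding_features_rejected(self):
        cfg = small_config(orf_length_range=(300, 400), read_length=500)
        _, truth = build_genome(cfg)
        with pytest.raises(ValueError, match="read length"):
            simulate_alignments(truth, "base", cfg, seed=4)

    def test_alignment_path_matches_count_path_distribution(self):
        """Round-trip simulate -> filter -> count agrees in distribution
        with direct count simulation (chi-square goodness of fit)."""
        cfg = small_config(
            n_orfs=15,
            depth=30_000,
            rrna_fraction=0.05,
            non_unique_fraction=0.02,
            regulons=[],
            baseline_abundance_law="uniform",
        )
        ann, truth = build_genome(cfg)
        records = simulate_alignments(truth, "base", cfg, seed=4)
        retained, stats = filter_alignments(records, ann)
        table = count_reads(retained, ann)
        p = truth.abundance_vector("base")
        observed = np.array([table.counts[f] for f in truth.feature_ids])
        expected = p * observed.sum()
        chi2 = ((observed - expected) ** 2 / expected).sum()
        pval = sps.chi2.sf(chi2, df=len(observed) - 1)
        assert pval > 0.01


class TestDefaultScenario:
    def test_condition_roster(self):
        cfg = default_study_scenario(seed=0)
        assert len(cfg.conditions) == 7
        assert cfg.conditions["WT_WL"] == 3
        assert all(v == 1 for k, v in cfg.conditions.items() if k != "WT_WL")

    def test_knockouts_abolish_induction(self):
        cfg = default_study_scenario(seed=0)
        farlip = next(r for r in cfg.regulons if r.name == "farlip_cluster")
        assert np.all(farlip.factors("rfpB_FRL") == 1.0)
        assert np.all(farlip.factors("rfpC_FRL") == 1.0)
        assert np.all(farlip.factors("rfpA_FRL") > 1.0)
        assert np.all(farlip.factors("rfpA_FRL") <= 5.0)

    def test_regulon_factor_anchors(self):
        cfg = default_study_scenario(seed=0)
        farlip = next(r for r in cfg.regulons if r.name == "farlip_cluster")
        assert farlip.factors("WT_FRL").min() == pytest.approx(1e3)
        assert farlip.factors("WT_FRL").max() == pytest.approx(4.35e4)
        pbp = next(r for r in cfg.regulons if r.name == "pbp_psi_wl")
        assert np.all(pbp.factors("WT_FRL") <= 0.5)
        em = next(r for r in cfg.regulons if r.name == "em_response")
        assert em.factors("WT_WL_Em").max() == pytest.approx(670.0)

    def test_scenario_json_round_trip(self, tmp_path):
        import json

        cfg = default_study_scenario(seed=5, depth=1000)
        path = tmp_path / "scenario.json"
        cfg.to_json(str(path))
        with open(path) as fh:
            again = SimulationConfig.from_dict(json.load(fh))
        assert again.depth == 1000
        assert again.seed == 5
        assert [r.name for r in again.regulons] == [r.name for r in cfg.regulons]
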