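"""The synthetic dikaryon/homokaryon generator against its own ground truth."""

import subprocess

import numpy as np
import pytest

import karyorec as kr
from karyorec import intervals as iv
from karyorec.sim import (
    SimConfig,
    default_scaffold_lengths,
    generate_nuclei,
    generate_nucleotypes,
    generate_reference,
    plan_tract_over_snps,
    simulate,
    simulate_observations,
)


def small_cfg(**kw):
    base = dict(seed=5, n_scaffolds=4, genome_size=200_000, n_nuclei_per_mat=2)
    base.update(kw)
    return SimConfig(**base)


class TestConfig:
    def test_derived_lengths_are_descending_and_sum(self):
        lengths = default_scaffold_lengths(1_000_000, 40)
        assert sum(lengths) == 1_000_000
        assert lengths == sorted(lengths, reverse=True)

    @pytest.mark.parametrize(
        "kw",
        [
            {"divergence": 0.02},
            {"dup_fraction": 0.6},
            {"mixture": 1.5},
            {"scaffold_lengths": [100, 200]},
            {"recomb_tracts": [(99, "scaffold_001", 10, 20)]},
            {"n_scaffolds": 0, "scaffold_lengths": []},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            small_cfg(**kw)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = small_cfg(recomb_tracts=[(1, "scaffold_001", 100, 5000)])
        cfg.to_yaml(tmp_path / "c.yaml")
        assert SimConfig.from_yaml(tmp_path / "c.yaml") == cfg


class TestReference:
    def test_no_duplicates_when_fraction_zero(self):
        _, dup = generate_reference(small_cfg(dup_fraction=0.0))
        assert dup == {}

    def test_deterministic_for_fixed_seed(self):
        cfg = small_cfg(dup_fraction=0.05)
        ref1, dup1 = generate_reference(cfg)
        ref2, dup2 = generate_reference(cfg)
        assert all(ref1[n] == ref2[n] for n in ref1.names)
        assert dup1.keys() == dup2.keys()

    def test_duplicated_bases_match_requested_fraction(self):
        cfg = SimConfig(
            seed=2, n_scaffolds=5, genome_size=1_000_000, dup_fraction=0.1
        )
        ref, dup = generate_reference(cfg)
        total = sum(iv.total_length(arr) for arr in dup.values())
        assert abs(total - 100_000) <= 2 * cfg.dup_segment_length
        # emitted copies are exact
        for name, arr in dup.items():
            for s, e in arr[:2]:
                seg = ref.fetch(name, int(s), int(e))
                assert sum(ref[n].count(seg) for n in ref.names) >= 2


class TestNucleotypes:
    def test_zero_divergence_means_identical_nucleotypes(self):
        cfg = small_cfg(divergence=0.0, n_collapsed_sites=0)
        ref, dup = generate_reference(cfg)
        truth = generate_nucleotypes(ref, cfg, dup)
        assert truth.n_snps == 0

    def test_snp_count_within_binomial_band(self):
        cfg = SimConfig(
            seed=9, n_scaffolds=5, genome_size=1_000_000,
            divergence=0.001, dup_fraction=0.0,
        )
        ref, dup = generate_reference(cfg)
        truth = generate_nucleotypes(ref, cfg, dup)
        sd = np.sqrt(1_000_000 * 0.001 * 0.999)
        assert abs(truth.n_snps - 1000) <= 3 * sd

    def test_alleles_differ_and_are_bases(self):
        cfg = small_cfg()
        ref, dup = generate_reference(cfg)
        truth = generate_nucleotypes(ref, cfg, dup)
        for s in truth.snp_pos:
            for p, r, a in zip(truth.snp_pos[s], truth.snp_ref[s], truth.snp_alt[s]):
                assert r != a and r in "ACGT" and a in "ACGT"
                assert ref[s][p - 1] == r

    def test_truth_snps_avoid_duplicates_by_default(self):
        cfg = small_cfg(dup_fraction=0.1)
        ref, dup = generate_reference(cfg)
        truth = generate_nucleotypes(ref, cfg, dup)
        for s, arr in dup.items():
            assert not iv.contains(arr, truth.snp_pos[s]).any()

    def test_mat_markers_are_truth_snps_on_largest_scaffold(self):
        cfg = small_cfg()
        ref, dup = generate_reference(cfg)
        truth = generate_nucleotypes(ref, cfg, dup)
        assert len(truth.mat_markers) == cfg.n_mat_markers
        for scaffold, pos in truth.mat_markers:
            assert scaffold == ref.names[0]
            assert pos in truth.snp_pos[scaffold]


class TestNuclei:
    def _truth(self, cfg):
        ref, dup = generate_reference(cfg)
        return generate_nuclei(cfg, generate_nucleotypes(ref, cfg, dup))

    def test_no_tracts_every_nucleus_equals_its_nucleotype(self):
        truth = self._truth(small_cfg())
        for nuc in truth.nuclei:
            is_alt = truth.clade[nuc] == "MAT-5"
            for s, hap in truth.haplotype[nuc].items():
                assert (hap == is_alt).all()

    def test_tract_flips_exactly_the_spanned_snps(self):
        cfg0 = small_cfg()
        base = self._truth(cfg0)
        scaffold = list(base.snp_pos)[0]
        start, end = plan_tract_over_snps(base, scaffold, 3, 5)
        cfg = small_cfg(recomb_tracts=[(0, scaffold, start, end)])
        truth = self._truth(cfg)
        nuc = truth.nuclei[0]
        flipped = truth.haplotype[nuc][scaffold] != base.haplotype[nuc][scaffold]
        assert flipped.sum() == 5
        pos = truth.snp_pos[scaffold]
        assert ((pos[flipped] >= start) & (pos[flipped] <= end)).all()

    def test_overlapping_tracts_rejected(self):
        cfg0 = small_cfg()
        base = self._truth(cfg0)
        scaffold = list(base.snp_pos)[0]
        a = plan_tract_over_snps(base, scaffold, 0, 4)
        b = (a[0] + 10, a[1] + 10)
        cfg = small_cfg(
            recomb_tracts=[(0, scaffold, *a), (0, scaffold, *b)]
        )
        with pytest.raises(ValueError, match="overlap"):
            self._truth(cfg)

    def test_homokaryon_nuclei_all_reference(self):
        truth = self._truth(small_cfg(mixture=1.0))
        for nuc in truth.nuclei:
            assert truth.clade[nuc] == "MAT-1"
            assert not any(h.any() for h in truth.haplotype[nuc].values())


class TestObservations:
    def test_coverage_fraction_matches_target(self):
        cfg = SimConfig(
            seed=3, n_scaffolds=5, genome_size=1_000_000,
            n_nuclei_per_mat=2, nucleus_coverage_fraction=0.14,
        )
        res = simulate(cfg)
        for nuc in res.truth.nuclei:
            covered = sum(iv.total_length(m) for m in res.truth.masks[nuc].values())
            assert abs(covered / cfg.genome_size - 0.14) <= 0.02

    def test_bulk_mean_af_near_half_for_dikaryon(self):
        cfg = SimConfig(
            seed=4, n_scaffolds=5, genome_size=1_000_000, divergence=0.01,
            error_rate=0.0, n_collapsed_sites=0, n_nuclei_per_mat=1,
            dup_fraction=0.0,
        )
        res = simulate(cfg)
        afs = [o.allele_frequency for o in res.bulk]
        assert len(afs) > 8000
        assert abs(np.mean(afs) - 0.5) <= 0.01

    def test_error_free_reads_support_the_true_allele(self):
        cfg = small_cfg(error_rate=0.0, n_collapsed_sites=0)
        res = simulate(cfg)
        for nuc, obs in res.nuclei_obs.items():
            lookup = {
                (s, int(p)): bool(h)
                for s in res.truth.snp_pos
                for p, h in zip(res.truth.snp_pos[s], res.truth.haplotype[nuc][s])
            }
            for o in obs:
                carries_alt = lookup[(o.scaffold, o.pos)]
                assert (o.ref_depth == 0) if carries_alt else (o.alt_depth == 0)

    def test_observations_confined_to_masks(self, dikaryon_run):
        res = dikaryon_run.res
        for nuc, obs in res.nuclei_obs.items():
            mask = res.truth.masks[nuc]
            for o in obs:
                assert o.scaffold in mask
                assert iv.contains(mask[o.scaffold], [o.pos])[0]

    def test_masks_nested_as_coverage_grows(self):
        lo = simulate(small_cfg(nucleus_coverage_fraction=0.2))
        hi = simulate(small_cfg(nucleus_coverage_fraction=0.5))
        for nuc in lo.truth.nuclei:
            for s, m_lo in lo.truth.masks[nuc].items():
                inter = iv.intersect(m_lo, hi.truth.masks[nuc].get(s, []))
                assert iv.total_length(inter) == iv.total_length(m_lo)

    def test_written_outputs_byte_identical_across_reruns(self, tmp_path):
        cfg = small_cfg(n_collapsed_sites=3)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate(cfg).write_outputs(d1)
        simulate(cfg).write_outputs(d2)
        assert (
            subprocess.run(["diff", "-r", str(d1), str(d2)], capture_output=True)
            .returncode
            == 0
        )
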