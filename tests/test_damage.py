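"""Misincorporation tallying, damage-model MLE, group comparison, binning."""

import numpy as np
import pandas as pd
import pytest

from archaeome import damage, preprocess, profiler, simkit, taxa
from archaeome.damage import MisincorporationProfile
from archaeome.records import AlignmentRecord
from archaeome.simkit import DamageParams, SimConfig
from archaeome._seq import revcomp
from conftest import make_reads


def brute_force_tally(alignments, references, K):
    """Independent per-position oracle: explicit loops, no vectorization."""
    n_C = [0] * K
    k_CT = [0] * K
    n_G = [0] * K
    k_GA = [0] * K
    for a in alignments:
        ref = references[a.reference_id]
        seg = ref[a.ref_start : a.ref_start + a.read_length]
        if a.strand == "-":
            seg = revcomp(seg)
        mism = {p: (rb, qb) for p, rb, qb in a.mismatches}
        L = a.read_length
        for x in range(1, min(K, L) + 1):
            if seg[x - 1] == "C":
                n_C[x - 1] += 1
                if mism.get(x, ("", ""))[1] == "T":
                    k_CT[x - 1] += 1
        for y in range(1, min(K, L) + 1):
            if seg[L - y] == "G":
                n_G[y - 1] += 1
                if mism.get(L - y + 1, ("", ""))[1] == "A":
                    k_GA[y - 1] += 1
    return n_C, k_CT, n_G, k_GA


class TestTally:
    def test_perfect_read_counts_opportunities_only(self):
        ref = "CCGGTTAACCGGAACC" * 5
        aln = AlignmentRecord("r", "g", 0, "+", 20)
        prof = damage.tally_misincorporations([aln], {"g": ref}, K=10)
        assert prof.k_CT.sum() == 0 and prof.k_GA.sum() == 0
        for x in range(10):
            assert prof.n_C[x] == (ref[x] == "C")

    def test_hand_tally_example(self):
        # ref CCGG vs read TCGG: C->T at position 1 only
        aln = AlignmentRecord("r", "g", 0, "+", 4, ((1, "C", "T"),))
        prof = damage.tally_misincorporations([aln], {"g": "CCGG"}, K=5)
        assert prof.n_C[0] == 1 and prof.k_CT[0] == 1
        assert prof.n_C[1] == 1 and prof.k_CT[1] == 0
        # 3' end: positions 1 and 2 from the right are G
        assert prof.n_G[0] == 1 and prof.n_G[1] == 1 and prof.k_GA.sum() == 0

    def test_matches_brute_force_on_random_alignments(self, pack):
        cfg = SimConfig(
            community=[("environmental_000", 1.0, DamageParams(0.3, 0.02, 0.3, 0.005))],
            n_reads=100, seed=21,
        )
        s = simkit.simulate_sample(pack, cfg, "bf")
        alns = simkit.truth_alignments(s, pack)
        prof = damage.tally_misincorporations(alns, pack.genomes, K=25)
        n_C, k_CT, n_G, k_GA = brute_force_tally(alns, pack.genomes, 25)
        assert prof.n_C.tolist() == n_C and prof.k_CT.tolist() == k_CT
        assert prof.n_G.tolist() == n_G and prof.k_GA.tolist() == k_GA

    def test_alignment_overrunning_reference_rejected(self):
        aln = AlignmentRecord("r", "g", 95, "+", 10)
        with pytest.raises(ValueError, match="overrun"):
            damage.tally_misincorporations([aln], {"g": "A" * 100}, K=5)

    def test_frequencies_match_forward_model(self, pack, ancient_params):
        cfg = SimConfig(
            community=[("oral_000", 1.0, ancient_params)], n_reads=50_000, seed=22
        )
        s = simkit.simulate_sample(pack, cfg, "fm")
        prof = damage.tally_misincorporations(
            simkit.truth_alignments(s, pack), pack.genomes, K=25, cycles=75
        )
        exp = simkit.expected_ct_frequency(np.arange(1, 26), ancient_params)
        for freq, n in ((prof.k_CT / prof.n_C, prof.n_C), (prof.k_GA / prof.n_G, prof.n_G)):
            se = np.sqrt(exp * (1 - exp) / n)
            assert np.all(np.abs(freq - exp) < 4 * se)


class TestFit:
    def _profile_from_sim(self, pack, params, n_reads, seed, per_read=False):
        cfg = SimConfig(community=[("oral_000", 1.0, params)], n_reads=n_reads, seed=seed)
        s = simkit.simulate_sample(pack, cfg, f"fit{seed}")
        return damage.tally_misincorporations(
            simkit.truth_alignments(s, pack), pack.genomes,
            K=25, cycles=75, collect_per_read=per_read,
        )

    def test_degenerate_all_zero_counts(self):
        prof = MisincorporationProfile(
            10, np.full(10, 100), np.zeros(10, int), np.full(10, 100), np.zeros(10, int)
        )
        fit = damage.fit_damage_model(prof, n_bootstrap=0)
        assert fit.params.delta_s == 0 and fit.params.delta_d == 0
        assert not fit.lambda_identifiable

    def test_below_floor_flagged_insufficient(self):
        prof = MisincorporationProfile(
            10, np.full(10, 10), np.zeros(10, int), np.full(10, 10), np.zeros(10, int)
        )
        fit = damage.fit_damage_model(prof, n_bootstrap=0)
        assert fit.insufficient and fit.params is None

    def test_parameter_recovery(self, pack, ancient_params):
        prof = self._profile_from_sim(pack, ancient_params, 50_000, 23)
        fit = damage.fit_damage_model(prof, n_bootstrap=0)
        assert abs(fit.params.delta_s - 0.30) < 0.03
        assert abs(fit.params.delta_d - 0.01) < 0.01
        assert abs(fit.params.mean_overhang - 1.5) / 1.5 < 0.20

    def test_mean_overhang_algebra(self):
        assert DamageParams(0.1, 0.01, 0.5).mean_overhang == pytest.approx(1.0)

    def test_refined_likelihood_never_below_grid(self, pack):
        for seed, params in ((1, DamageParams(0.22, 0.02, 0.35, 0.001)),
                             (2, DamageParams(0.05, 0.005, 0.7, 0.002))):
            prof = self._profile_from_sim(pack, params, 5000, seed)
            n5, k5 = prof.n_C.astype(float), prof.k_CT.astype(float)
            n3, k3 = prof.n_G.astype(float), prof.k_GA.astype(float)
            x = np.arange(1.0, 26.0)
            _, ll_grid = damage._grid_scan(x, n5, k5, n3, k3, prof.epsilon_hat / 3)
            fit = damage.fit_damage_model(prof, n_bootstrap=0)
            assert fit.loglik >= ll_grid.max() - 1e-9

    def test_recovery_error_shrinks_with_depth(self, pack, ancient_params):
        errs = []
        for n in (1000, 10_000, 50_000):
            per_seed = []
            for seed in (31, 32, 33):
                prof = self._profile_from_sim(pack, ancient_params, n, seed)
                fit = damage.fit_damage_model(prof, n_bootstrap=0)
                per_seed.append(abs(fit.params.delta_s - 0.3))
            errs.append(np.mean(per_seed))
        assert errs[0] > errs[2]

    def test_five_and_three_prime_fits_agree(self, pack, ancient_params):
        prof = self._profile_from_sim(pack, ancient_params, 30_000, 34)
        only5 = MisincorporationProfile(
            prof.K, prof.n_C, prof.k_CT, np.zeros(prof.K, int), np.zeros(prof.K, int),
            prof.n_background, prof.k_background,
        )
        only3 = MisincorporationProfile(
            prof.K, np.zeros(prof.K, int), np.zeros(prof.K, int), prof.n_G, prof.k_GA,
            prof.n_background, prof.k_background,
        )
        f5 = damage.fit_damage_model(only5, n_bootstrap=0, min_opportunities=0)
        f3 = damage.fit_damage_model(only3, n_bootstrap=0, min_opportunities=0)
        assert abs(f5.params.delta_s - f3.params.delta_s) < 0.05

    def test_bootstrap_interval_covers_point(self, pack, ancient_params):
        prof = self._profile_from_sim(pack, ancient_params, 5000, 35, per_read=True)
        fit = damage.fit_damage_model(prof, n_bootstrap=50, seed=1)
        for p in ("delta_s", "delta_d", "mean_overhang"):
            lo, hi = fit.ci[p]
            point = getattr(fit.params, p) if p != "mean_overhang" else fit.params.mean_overhang
            assert lo <= point <= hi

    def test_metropolis_agrees_with_mle(self, pack, ancient_params):
        prof = self._profile_from_sim(pack, ancient_params, 20_000, 36)
        post = damage.metropolis_sample(prof, n_iter=3000, burn_in=500, seed=2)
        fit = damage.fit_damage_model(prof, n_bootstrap=0)
        assert abs(post["delta_s"] - fit.params.delta_s) < 0.05


class TestRepresentativeSpecies:
    def _profile(self, sid, species_ab):
        lineages = {
            sp: {"kingdom": "bacteria", "class": "c", "family": "f",
                 "genus": f"g{sp}", "species": sp}
            for sp in species_ab
        }
        return profiler.AbundanceProfile(
            sid, profiler._aggregate_ranks(species_ab, lineages), 100, lineages
        )

    def test_threshold_rule(self):
        profs = [
            self._profile("s1", {"a": 0.12, "b": 0.88}),
            self._profile("s2", {"b": 0.91, "c": 0.09}),
        ]
        assert damage.select_representative_species(profs, 0.10) == ["a", "b"]

    def test_zero_threshold_selects_all_observed(self):
        profs = [self._profile("s1", {"a": 0.5, "b": 0.5})]
        assert damage.select_representative_species(profs, 0.0) == ["a", "b"]


class TestGroupDamage:
    def _cohort_sample(self, pack, ancient, seed, n_reads=4000):
        env = pack.taxa_of_habitat("environmental")[:2]
        human = pack.taxa_of_habitat("oral")[:2]
        cfg = SimConfig(
            community=[(t, 0.35 / len(env), "modern") for t in env]
            + [(t, 0.35 / len(human), ancient) for t in human],
            host_fraction=0.3, host_damage=ancient, n_reads=n_reads, seed=seed,
        )
        s = simkit.simulate_sample(pack, cfg, f"gd{seed}")
        reads = list(preprocess.quality_trim_filter(s.reads))
        exo, _, host_aln = preprocess.remove_host_reads(reads, pack.host_genome)
        return exo, host_aln

    def test_damaged_human_related_vs_modern_environmental(self, pack, ancient_params):
        exo, host_aln = self._cohort_sample(pack, ancient_params, 41, n_reads=8000)
        habitat = {t: tr.habitat for t, tr in pack.traits.items() if tr.habitat}
        results = damage.group_damage(
            exo, pack, habitat, host_aln,
            groups=["environmental", "human_related"],
        )
        by = {r.group: r for r in results}
        assert by["environmental"].delta["delta_s"] > by["human_related"].delta["delta_s"]
        assert abs(by["human_related"].fit.params.delta_s
                   - by["host"].fit.params.delta_s) < 0.05

    def test_identical_damage_gives_near_zero_deltas(self, pack, ancient_params):
        env = pack.taxa_of_habitat("environmental")[:2]
        oral = pack.taxa_of_habitat("oral")[:2]
        cfg = SimConfig(
            community=[(t, 0.35, ancient_params) for t in env[:1]]
            + [(t, 0.35, ancient_params) for t in oral[:1]],
            host_fraction=0.3, host_damage=ancient_params, n_reads=8000, seed=42,
        )
        s = simkit.simulate_sample(pack, cfg, "null")
        exo, _, host_aln = preprocess.remove_host_reads(list(s.reads), pack.host_genome)
        habitat = {t: tr.habitat for t, tr in pack.traits.items() if tr.habitat}
        results = damage.group_damage(
            exo, pack, habitat, host_aln, groups=["environmental", "human_related"]
        )
        for r in results:
            if r.delta is not None:
                assert abs(r.delta["delta_s"]) < 0.07

    def test_empty_group_flagged_without_affecting_others(self, pack, ancient_params):
        exo, host_aln = self._cohort_sample(pack, ancient_params, 43)
        habitat = {
            t: tr.habitat for t, tr in pack.traits.items()
            if tr.habitat in ("environmental", "gut_other")
        }
        results = damage.group_damage(
            exo, pack, habitat, host_aln, groups=["environmental", "oral"]
        )
        by = {r.group: r for r in results}
        assert by["oral"].fit.insufficient
        assert by["environmental"].fit.ok


class TestBinning:
    def test_boundary_value_goes_to_upper_bin(self):
        assert damage.assign_bin(25.0) == "25-50"
        assert damage.assign_bin(0.0) == "0-25"
        assert damage.assign_bin(100.0) == "75-100"

    def test_single_sample_populates_one_bin(self):
        df = pd.DataFrame(
            [{"sample_id": "s", "environmental_fraction": 40.0, "microbial_delta_s": 0.2}]
        )
        out = damage.bin_by_environmental_fraction(df)
        assert out.set_index("bin").loc["25-50", "n_samples"] == 1
        assert out.n_samples.sum() == 1
        assert np.isnan(out.set_index("bin").loc["0-25", "microbial_delta_s_mean"])

    def test_means_per_bin(self):
        df = pd.DataFrame(
            [
                {"environmental_fraction": 10.0, "v": 1.0},
                {"environmental_fraction": 20.0, "v": 3.0},
                {"environmental_fraction": 80.0, "v": 5.0},
            ]
        )
        out = damage.bin_by_environmental_fraction(df).set_index("bin")
        assert out.loc["0-25", "v_mean"] == pytest.approx(2.0)
        assert out.loc["75-100", "v_mean"] == pytest.approx(5.0)
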