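import math
from itertools import combinations_with_replacement

import numpy as np
import pytest

from csnptrack.forensic_stats import (
    allele_frequencies,
    bonferroni_alpha,
    hwe_exact,
    match_probability,
    pairwise_independence,
    panel_summary,
    pic,
    power_of_exclusion,
    typical_pi,
)
from csnptrack.model_io import AlleleFrequencySet, Genotype, GenotypeCounts, GenotypeTable
from csnptrack.simulate import SimConfig, sim_genotypes


class TestAlleleFrequencies:
    def test_symmetric(self):
        c = GenotypeCounts("rs1", {"A/A": 25, "C/C": 25, "A/C": 50})
        fs = allele_frequencies(c)
        assert fs["A"] == pytest.approx(0.5)

    def test_hand_tally(self):
        c = GenotypeCounts("rs1", {"A/C": 30, "C/C": 20, "A/A": 5, "C/G": 5})
        fs = allele_frequencies(c)
        assert fs.freqs == pytest.approx({"A": 40 / 120, "C": 75 / 120, "G": 5 / 120})

    def test_empty_counts_error(self):
        with pytest.raises(ValueError):
            allele_frequencies(GenotypeCounts("rs1", {}))


class TestMatchProbability:
    def test_single_class_is_certain_match(self):
        mp, dp = match_probability(GenotypeCounts("rs1", {"A/A": 10}))
        assert mp == 1.0 and dp == 0.0

    def test_hwe_half(self):
        mp, dp = match_probability(
            GenotypeCounts("rs1", {"A/A": 25, "A/C": 50, "C/C": 25})
        )
        assert mp == pytest.approx(0.375)
        assert mp + dp == pytest.approx(1.0)


class TestPowerOfExclusion:
    def test_no_heterozygotes(self):
        assert power_of_exclusion(GenotypeCounts("rs1", {"A/A": 10})) == 0.0

    def test_closed_form_h_half(self):
        c = GenotypeCounts("rs1", {"A/A": 25, "A/C": 50, "C/C": 25})
        assert power_of_exclusion(c) == pytest.approx(0.25 * (1 - 2 * 0.5 * 0.25))


class TestPic:
    def test_monomorphic_zero(self):
        assert pic(AlleleFrequencySet("rs1", {"A": 1.0})) == pytest.approx(0.0)

    def test_symmetric_biallelic(self):
        assert pic(AlleleFrequencySet("rs1", {"A": 0.5, "C": 0.5})) == pytest.approx(
            0.375
        )

    def test_bounded_by_expected_heterozygosity(self, panel_freqs):
        for fs in panel_freqs.values():
            het = 1.0 - sum(p * p for p in fs.freqs.values())
            assert pic(fs) < het


class TestTypicalPi:
    def test_closed_form(self):
        c = GenotypeCounts("rs1", {"A/A": 5, "A/C": 5})
        assert typical_pi(c) == pytest.approx(1.0)

    def test_all_heterozygotes_infinite(self):
        with pytest.warns(UserWarning):
            assert typical_pi(GenotypeCounts("rs1", {"A/C": 10})) == math.inf


def hwe_oracle(counts: GenotypeCounts) -> float:
    """Independent exact HWE p-value by brute-force enumeration.

    Enumerates every genotype table with the observed allele counts via
    multinomial coefficients over genotype multisets and sums the exact
    conditional probabilities of tables no more probable than observed.
    """
    ac = counts.allele_counts
    alleles = sorted(ac)
    n = counts.n

    def log_prob(table: dict[str, int]) -> float:
        het = sum(c for g, c in table.items() if len(set(g.split("/"))) == 2)
        lp = math.lgamma(n + 1) - math.lgamma(2 * n + 1) + het * math.log(2.0)
        for c in table.values():
            lp -= math.lgamma(c + 1)
        for c in ac.values():
            lp += math.lgamma(c + 1)
        return lp

    genotype_keys = [
        "/".join(sorted(pair)) for pair in combinations_with_replacement(alleles, 2)
    ]

    tables = []

    def rec(i: int, remaining: int, current: dict[str, int]):
        if i == len(genotype_keys) - 1:
            current = {**current, genotype_keys[-1]: remaining}
            tally = {a: 0 for a in alleles}
            for g, c in current.items():
                for a in g.split("/"):
                    tally[a] += c
            if tally == ac:
                tables.append({g: c for g, c in current.items() if c})
            return
        for c in range(remaining + 1):
            rec(i + 1, remaining - c, {**current, genotype_keys[i]: c})

    rec(0, n, {})
    log_obs = log_prob(dict(counts.counts))
    total = sum(math.exp(log_prob(t)) for t in tables)
    tail = sum(
        math.exp(log_prob(t)) for t in tables if log_prob(t) <= log_obs + 1e-12
    )
    return tail / total


class TestHweExact:
    def test_tiny_table_equals_enumeration(self):
        c = GenotypeCounts("rs1", {"A/A": 1, "C/C": 1})
        r = hwe_exact(c)
        assert r.method == "exact-enumeration"
        assert r.p_value == pytest.approx(hwe_oracle(c), rel=1e-9)

    @pytest.mark.parametrize("seed", range(12))
    def test_random_biallelic_tables_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 51))
        counts = {"A/A": 0, "A/C": 0, "C/C": 0}
        for _ in range(n):
            counts[rng.choice(["A/A", "A/C", "C/C"])] += 1
        c = GenotypeCounts("rs1", {g: k for g, k in counts.items() if k})
        if len(c.allele_counts) < 2:
            return  # monomorphic draw: nothing to compare
        assert hwe_exact(c).p_value == pytest.approx(hwe_oracle(c), rel=1e-9)

    def test_mode_table_gives_p_one(self):
        c = GenotypeCounts("rs1", {"A/A": 2500, "A/C": 5000, "C/C": 2500})
        assert hwe_exact(c).p_value == pytest.approx(1.0)

    def test_monomorphic_p_one(self):
        with pytest.warns(UserWarning):
            assert hwe_exact(GenotypeCounts("rs1", {"A/A": 5})).p_value == 1.0

    def test_triallelic_monte_carlo_matches_enumeration(self):
        c = GenotypeCounts(
            "rs1", {"A/A": 3, "A/C": 4, "C/C": 2, "A/G": 3, "C/G": 2, "G/G": 1}
        )
        r = hwe_exact(c, n_steps=20_000, seed=11)
        assert r.method == "monte-carlo"
        assert r.p_value == pytest.approx(hwe_oracle(c), abs=0.02)

    def test_type_one_error_conservative(self):
        """Exact-test rejection rate at alpha=0.05 stays within [0, 0.07]
        for data simulated under the null (n=114, p=0.5)."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_sims = 1000
        for _ in range(n_sims):
            genos = rng.binomial(1, 0.5, size=(114, 2)).sum(axis=1)
            c = GenotypeCounts(
                "rs1",
                {
                    "A/A": int((genos == 0).sum()),
                    "A/C": int((genos == 1).sum()),
                    "C/C": int((genos == 2).sum()),
                },
            )
            if len(c.allele_counts) < 2:
                continue
            if hwe_exact(c).p_value < 0.05:
                rejections += 1
        assert 0 <= rejections / n_sims <= 0.07


class TestPairwiseIndependence:
    def test_bonferroni_threshold_22_loci(self):
        assert bonferroni_alpha(22) == pytest.approx(0.05 / 231)

    def test_locus_paired_with_itself_rejects(self):
        cfg = SimConfig(seed=3, n_individuals=80)
        fs = AlleleFrequencySet("rsX", {"A": 0.5, "C": 0.5})
        cfg = SimConfig(seed=3, n_individuals=80, freqs=(fs,))
        t = sim_genotypes(cfg)
        dup = GenotypeTable()
        for s in t.samples:
            g = t.get(s, "rsX")
            dup.set(s, "rsX", g)
            dup.set(s, "rsY", g)
        (res,) = pairwise_independence(dup, n_permutations=500, seed=1)
        assert res.p_value < 0.01

    def test_independent_loci_calibrated(self):
        """Rejection rate at alpha=0.05 for truly independent loci lies
        within 99% binomial bounds (100 replicates, n=200 samples)."""
        fs1 = AlleleFrequencySet("rs_a", {"A": 0.5, "C": 0.5})
        fs2 = AlleleFrequencySet("rs_b", {"G": 0.5, "T": 0.5})
        rejections = 0
        reps = 100
        for rep in range(reps):
            cfg = SimConfig(seed=1000 + rep, n_individuals=200, freqs=(fs1, fs2))
            t = sim_genotypes(cfg)
            (res,) = pairwise_independence(t, n_permutations=400, seed=rep)
            if res.p_value < 0.05:
                rejections += 1
        # Binomial(100, 0.05): 99% interval roughly [0, 11]
        assert rejections <= 11

    def test_too_few_permutations_rejected(self):
        t = GenotypeTable(
            {
                "S1": {"rs1": Genotype("A", "A"), "rs2": Genotype("C", "C")},
                "S2": {"rs1": Genotype("A", "C"), "rs2": Genotype("C", "G")},
            }
        )
        with pytest.raises(ValueError):
            pairwise_independence(t, n_permutations=50, seed=0)


class TestPanelSummary:
    def test_single_locus_identity(self, panel_params):
        s = panel_summary(panel_params[:1])
        p = panel_params[0]
        assert s.cumulative_mp == pytest.approx(p.mp)
        assert s.combined_pe == pytest.approx(p.pe)
        assert s.combined_dp_standard == pytest.approx(p.dp, abs=1.5e-3)

    def test_standard_dp_complements_cumulative_mp(self, panel_params):
        s = panel_summary(panel_params)
        assert s.combined_dp_standard == pytest.approx(
            1.0 - s.cumulative_mp, abs=1e-12
        )

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="no loci"):
            panel_summary([])


class TestSimulatedPanelMatchesClosedForms:
    def test_observed_statistics_track_hwe_expectations(self, panel_freqs):
        """Per-locus MP/DP/PE/TPI on HWE-simulated genotypes stay within
        3 standard errors of their HWE closed forms (averaged over
        replicates at the published panel frequencies)."""
        rsids = ["rs12221474", "rs6559167", "rs2249057"]
        freqs = tuple(panel_freqs[r] for r in rsids)
        reps, n = 200, 114
        acc = {r: {"mp": [], "pe": [], "tpi": []} for r in rsids}
        for rep in range(reps):
            t = sim_genotypes(SimConfig(seed=5000 + rep, n_individuals=n, freqs=freqs))
            for r in rsids:
                c = GenotypeCounts.from_genotypes(
                    r, (t.get(s, r) for s in t.samples)
                )
                mp, _ = match_probability(c)
                acc[r]["mp"].append(mp)
                acc[r]["pe"].append(power_of_exclusion(c))
                acc[r]["tpi"].append(typical_pi(c))
        for r in rsids:
            fs = panel_freqs[r]
            # HWE expected genotype frequencies
            alleles = list(fs.alleles)
            gf = {}
            for i, a in enumerate(alleles):
                for b in alleles[i:]:
                    gf[(a, b)] = fs[a] ** 2 if a == b else 2 * fs[a] * fs[b]
            exp_mp = sum(f * f for f in gf.values())
            h = sum(f for (a, b), f in gf.items() if a != b)
            H = 1 - h
            exp_pe = h * h * (1 - 2 * h * H * H)
            exp_tpi = 1 / (2 * H)
            for key, expected in (("mp", exp_mp), ("pe", exp_pe), ("tpi", exp_tpi)):
                vals = np.array(acc[r][key])
                se = vals.std(ddof=1) / math.sqrt(reps)
                # finite-sample bias of these plug-in statistics is O(1/n),
                # visible at 3 SE over many replicates; allow for it
                assert abs(vals.mean() - expected) < 3 * se + 3.0 / n, (r, key)
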