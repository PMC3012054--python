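"""Positional bias, motif interactions, domain overlap, term enrichment,
disorder scoring, and known-motif similarity."""

import numpy as np
import pytest

from motifinfo import characterize, synth
from motifinfo.io import BehaviorProfile, DisorderMask, DomainAnnotations, Proteome, TermMap
from motifinfo.motif import Motif, MotifProfile, build_profile, parse_motif


@pytest.fixture(scope="module")
def nterm_planted():
    m = parse_motif("SP.[RK]")
    prot = synth.random_proteome(300, 250, 40, seed=80)
    beh = synth.random_class_profile(prot, [80, 220], seed=81)
    prot, truth = synth.plant_motif(prot, beh, m, 0, 0.9, position_mode="nterm", seed=82)
    return prot, beh, truth, m


class TestPositionalBias:
    def test_nterm_planting_detected(self, nterm_planted):
        prot, beh, _, m = nterm_planted
        prof = build_profile(prot, m, beh.ids)
        b = characterize.positional_bias(prof, beh, prot, n_rand=999, seed=1)
        assert not b.insufficient
        assert b.empirical_p < 0.01

    def test_histograms_conserve_instances(self, nterm_planted):
        prot, beh, _, m = nterm_planted
        prof = build_profile(prot, m, beh.ids)
        b = characterize.positional_bias(prof, beh, prot, n_rand=99, seed=2)
        assert b.histogram_targets.sum() + b.histogram_others.sum() == prof.n_instances()

    def test_few_instances_abstains(self):
        prot = Proteome([("A", "SPARKLIQWE" * 3), ("B", "LIVMWC" * 5), ("C", "GAGAGA" * 5)])
        beh = BehaviorProfile(["A", "B", "C"], [0, 1, 1], ["x", "y"])
        prof = build_profile(prot, parse_motif("SP.[RK]"), beh.ids)
        b = characterize.positional_bias(prof, beh, prot, seed=3)
        assert b.insufficient
        assert b.empirical_p is None

    def test_uniform_placement_not_flagged_usually(self):
        # with uniform planting, position carries no class information
        m = parse_motif("SP.[RK]")
        small_ps = 0
        for rep in range(10):
            prot = synth.random_proteome(200, 250, 40, seed=900 + rep)
            beh = synth.random_class_profile(prot, [60, 140], seed=950 + rep)
            prot, _ = synth.plant_motif(prot, beh, m, 0, 0.9, position_mode="uniform", seed=990 + rep)
            prof = build_profile(prot, m, beh.ids)
            b = characterize.positional_bias(prof, beh, prot, n_rand=199, seed=rep)
            small_ps += b.empirical_p < 0.05
        assert small_ps <= 3


class TestCooccurrence:
    @staticmethod
    def _fake_profile(present):
        m = parse_motif("LK")
        ids = [f"p{i}" for i in range(len(present))]
        return MotifProfile(m, ids, np.asarray(present, bool), [np.zeros(0, int)] * len(present))

    def test_identical_profiles_co_occur(self):
        rng = np.random.default_rng(4)
        present = rng.random(500) < 0.3
        a, b = self._fake_profile(present), self._fake_profile(present)
        mi, p, direction = characterize.cooccurrence(a, b, n_rand=999, seed=5)
        assert direction == "co-occur"
        assert p == pytest.approx(1 / 1000)
        assert mi > 0.5

    def test_disjoint_profiles_co_avoid(self):
        present_a = np.array([True] * 200 + [False] * 300)
        present_b = np.array([False] * 300 + [True] * 200)
        mi, p, direction = characterize.cooccurrence(
            self._fake_profile(present_a), self._fake_profile(present_b), n_rand=199, seed=6
        )
        assert direction == "co-avoid"
        assert p < 0.01

    def test_independent_profiles_rarely_pass(self):
        rng = np.random.default_rng(7)
        n_pass = 0
        for rep in range(100):
            a = self._fake_profile(rng.random(300) < 0.4)
            b = self._fake_profile(rng.random(300) < 0.4)
            _, p, _ = characterize.cooccurrence(a, b, n_rand=99, seed=rep)
            n_pass += p <= 1 / 100
        assert n_pass <= 5


class TestColocalization:
    def test_planted_spacing_detected(self):
        ma, mb = parse_motif("QW[AC]"), parse_motif("WQ[LM]")
        prot = synth.random_proteome(600, 300, 40, seed=100)
        beh = synth.random_class_profile(prot, [150, 450], seed=101)
        prot, _ = synth.plant_pair(prot, beh, ma, mb, 0, spacing=20, jitter=1, penetrance=0.9, seed=102)
        # random-spacing pairs in the other class so co-carriers span both classes
        prot, _ = synth.plant_motif(prot, beh, ma, 1, 0.5, seed=103)
        prot, _ = synth.plant_motif(prot, beh, mb, 1, 0.5, seed=104)
        pa = build_profile(prot, ma, beh.ids)
        pb = build_profile(prot, mb, beh.ids)
        mi, p = characterize.colocalization(pa, pb, beh, n_rand=999, seed=105)
        assert p is not None and p < 0.01

    def test_too_few_co_carriers_abstains(self):
        prot = synth.random_proteome(30, 100, 10, seed=110)
        beh = synth.random_class_profile(prot, [10, 20], seed=111)
        pa = build_profile(prot, parse_motif("WWC"), beh.ids)
        pb = build_profile(prot, parse_motif("CWW"), beh.ids)
        mi, p = characterize.colocalization(pa, pb, beh, seed=112)
        assert mi is None and p is None


class TestDomainReport:
    def _planted_domain_case(self, inside: bool, seed: int):
        m = parse_motif("QWER")
        prot = synth.random_proteome(150, 200, 20, seed=seed)
        carrier_ids = set(prot.ids[:60])
        domains = synth.plant_domains(prot, carrier_ids, coverage=0.4, seed=seed + 1)
        rng = np.random.default_rng(seed + 2)
        entries = []
        for pid in prot.ids:
            seq = list(prot.sequence(pid))
            if pid in carrier_ids:
                _, a, b = domains.intervals[pid][0]
                w = m.width
                if inside:
                    s = int(rng.integers(a, b - w + 1))
                else:
                    # pick a start whose window misses [a, b)
                    choices = [x for x in range(len(seq) - w + 1) if x + w <= a or x >= b]
                    s = int(choices[rng.integers(len(choices))])
                seq[s : s + w] = "QWER"
            entries.append((pid, "".join(seq)))
        prot = Proteome(entries)
        prof = build_profile(prot, m)
        return prof, domains, prot

    def test_inside_positive_outside_negative(self):
        prof_in, dom_in, prot_in = self._planted_domain_case(True, 120)
        rep_in = characterize.domain_report(prof_in, dom_in, prot_in)[0]
        assert rep_in.overlap_z > 0
        prof_out, dom_out, prot_out = self._planted_domain_case(False, 130)
        rep_out = characterize.domain_report(prof_out, dom_out, prot_out)[0]
        assert rep_out.overlap_z < 0

    def test_cooccurrence_p_small_when_carriers_match_domains(self):
        prof, dom, prot = self._planted_domain_case(True, 140)
        rep = characterize.domain_report(prof, dom, prot)[0]
        assert rep.cooccurrence_p < 1e-6


class TestTermEnrichment:
    def test_exact_term_ranks_first(self):
        universe = {f"p{i}" for i in range(1000)}
        target = frozenset(f"p{i}" for i in range(20))
        terms = TermMap(
            {"T1": target, "T2": frozenset(f"p{i}" for i in range(500, 560))}
        )
        ranked = characterize.term_enrichment(set(target), terms, universe)
        assert ranked[0][0] == "T1"
        assert ranked[0][1] < 1e-30

    def test_zero_overlap_p_one(self):
        universe = {f"p{i}" for i in range(100)}
        terms = TermMap({"T": frozenset(f"p{i}" for i in range(50, 60))})
        ranked = characterize.term_enrichment({f"p{i}" for i in range(10)}, terms, universe)
        assert ranked[0][1] == 1.0  # upper tail at k=0

    def test_random_carriers_rarely_corrected_significant(self):
        rng = np.random.default_rng(8)
        universe = {f"p{i}" for i in range(500)}
        ulist = sorted(universe)
        terms = TermMap(
            {f"T{j}": frozenset(rng.choice(ulist, 30, replace=False)) for j in range(20)}
        )
        clean = 0
        for rep in range(100):
            carriers = set(rng.choice(ulist, 50, replace=False))
            ranked = characterize.term_enrichment(carriers, terms, universe)
            clean += not any(cp < 0.05 for _, _, cp in ranked)
        assert clean >= 95


class TestDisorder:
    def _setup(self):
        prot = Proteome([("A", "SPARKLIQWESPAR" + "L" * 26), ("B", "SPAK" + "G" * 36)])
        m = parse_motif("SP.[RK]")
        prof = build_profile(prot, m)
        return prot, m, prof

    def test_all_inside(self):
        prot, m, prof = self._setup()
        mask = DisorderMask({"A": [(0, 40)], "B": [(0, 40)]})
        assert characterize.disorder_score(prof, mask, prot) == 1.0

    def test_none_inside(self):
        prot, m, prof = self._setup()
        mask = DisorderMask({})
        assert characterize.disorder_score(prof, mask, prot) == 0.0

    def test_partial_fraction(self):
        prot, m, prof = self._setup()
        # instances: A@0, A@10, B@0 -> cover A's first two, not B's
        mask = DisorderMask({"A": [(0, 14)]})
        assert characterize.disorder_score(prof, mask, prot) == pytest.approx(2 / 3)

    def test_majority_rule(self):
        prot = Proteome([("A", "SPARKLIQWE")])
        prof = build_profile(prot, parse_motif("SP.[RK]"))
        # covers 2 of 4 residues: not >50%
        assert characterize.disorder_score(prof, DisorderMask({"A": [(0, 2)]}), prot) == 0.0
        # covers 3 of 4 residues
        assert characterize.disorder_score(prof, DisorderMask({"A": [(0, 3)]}), prot) == 1.0

    def test_kmer_percentile_extremes(self):
        prot = synth.random_proteome(50, 120, 10, seed=150)
        mask = DisorderMask({pid: [(0, 60)] for pid in prot.ids})
        # a motif fully disordered everywhere would beat most k-mers
        pct_hi = characterize.kmer_disorder_percentile(1.0, 3, mask, prot)
        pct_lo = characterize.kmer_disorder_percentile(0.0, 3, mask, prot)
        assert 0.0 <= pct_lo < pct_hi <= 100.0


class TestSimilarity:
    def test_identical_non_wildcard_is_one(self):
        m = parse_motif("SPAR")
        assert characterize.motif_similarity(m, m) == pytest.approx(1.0)

    def test_symmetry(self):
        a, b = parse_motif("SP.[RK]"), parse_motif("[ST]P.[RK]")
        assert characterize.motif_similarity(a, b) == pytest.approx(
            characterize.motif_similarity(b, a)
        )

    def test_disjoint_sets_near_zero(self):
        a, b = parse_motif("AAAA"), parse_motif("WWWW")
        assert characterize.motif_similarity(a, b) == 0.0

    def test_wildcards_cannot_match_everything(self):
        a = parse_motif("A..A")
        b = parse_motif("W..W")
        assert characterize.motif_similarity(a, b) <= 0.05 + 1e-9

    def test_catalog_best_match_recovers_kinase_substrate(self):
        # the CDK substrate site should be the best match for SP.[RK]
        catalog = [
            ("NLS", parse_motif("K[KR].[KR]"), "nuclear localization"),
            ("CDK", parse_motif("[ST]P.[RK]"), "kinase substrate"),
            ("SH3", parse_motif("P..P"), "ligand"),
        ]
        hit = characterize.best_match(parse_motif("SP.[RK]"), catalog)
        assert hit is not None
        assert hit[0] == "CDK"
        assert hit[2] > 0.5

    def test_identity_only_for_set_identical(self):
        a, b = parse_motif("SPAR"), parse_motif("SPAK")
        assert characterize.motif_similarity(a, b) < 1.0
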