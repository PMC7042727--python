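import itertools

import numpy as np
import pytest

from famvar.funnel import (
    CONS_SCORES,
    EXONIC_DAMAGE_CLASSES,
    FUNC_CLASSES,
    LOF_CLASSES,
    PATHO_PREDICTORS,
    AnnotationRecord,
    FunnelConfig,
    SharedRegion,
    VariantRecord,
    candidate_prioritize,
    carrier_allele_freq,
    dominant_filter,
    functional_filter,
    gene_list_filters,
    pathogenicity_vote,
    quality_filter,
    rarity_filter,
    round_sig,
    run_funnel,
    shared_regions,
    union_variants,
)
from famvar.pedigree import GenotypeCall, HET, HOM_ALT, HOM_REF, NOCALL

LOW_HET = GenotypeCall(0, 1, "low")


def var(chrom, pos, calls=None, ref="A", alt="G"):
    return VariantRecord(chrom, pos, ref, alt, calls or {})


def ann(key, gene="G1", func_class="nonsynonymous", freqs=None, n_del=0, n_cons=0):
    return AnnotationRecord(
        key=key,
        gene=gene,
        func_class=func_class,
        pop_freqs=freqs or {},
        patho_calls={
            p: ("deleterious" if i < n_del else "tolerated")
            for i, p in enumerate(PATHO_PREDICTORS)
        },
        cons_calls={
            c: ("conserved" if i < n_cons else "not_conserved")
            for i, c in enumerate(CONS_SCORES)
        },
    )


class TestUnionVariants:
    def test_shared_and_private_sites(self):
        a = [var("1", 10, {"a": HET}), var("1", 20, {"a": HET})]
        b = [var("1", 10, {"b": HET}), var("1", 30, {"b": HET})]
        merged = union_variants({"a": a, "b": b})
        assert len(merged) == 3
        shared = next(v for v in merged if v.pos == 10)
        assert shared.call("a").is_het and shared.call("b").is_het
        private = next(v for v in merged if v.pos == 20)
        assert private.call("b").is_nocall

    def test_different_alts_two_records(self):
        a = [var("1", 10, {"a": HET}, alt="G")]
        b = [var("1", 10, {"b": HET}, alt="T")]
        assert len(union_variants({"a": a, "b": b})) == 2

    def test_empty(self):
        assert union_variants({}) == []

    def test_conflicting_ref_rejected(self):
        a = [var("1", 10, {"a": HET}, ref="A")]
        b = [var("1", 10, {"b": HET}, ref="C")]
        with pytest.raises(ValueError):
            union_variants({"a": a, "b": b})


class TestQualityFilter:
    def test_one_vqhigh_kept(self):
        calls = {f"s{i}": LOW_HET for i in range(5)}
        calls["s5"] = HET
        assert quality_filter([var("1", 1, calls)]) != []

    def test_all_low_removed(self):
        assert quality_filter([var("1", 1, {"a": LOW_HET, "b": LOW_HET})]) == []

    def test_recount_on_synthetic_mix(self):
        rng = np.random.default_rng(0)
        variants = []
        expected = 0
        for i in range(1000):
            quals = rng.random(4) < 0.4
            calls = {
                f"s{j}": (HET if q else LOW_HET) for j, q in enumerate(quals)
            }
            variants.append(var("1", i + 1, calls))
            expected += int(quals.any())
        assert len(quality_filter(variants)) == expected


class TestDominantFilter:
    def test_study_configuration_kept(self):
        v = var("2", 100, {"200": HET, "102": HET, "122": HOM_REF, "123": HOM_REF})
        out = dominant_filter([v], {"200", "102"}, {"122", "123"})
        assert out == [v]

    def test_all_hom_ref_removed(self):
        v = var("2", 100, {c: HOM_REF for c in ("200", "102", "122", "123")})
        assert dominant_filter([v], {"200", "102"}, {"122", "123"}) == []

    def test_exhaustive_rule_enumeration(self):
        # oracle: direct application of the verbal rule over all 4^4 states
        states = {"het": HET, "homref": HOM_REF, "homalt": HOM_ALT, "nocall": NOCALL}
        names = list(states)
        for combo in itertools.product(names, repeat=4):
            calls = {
                "c1": states[combo[0]],
                "c2": states[combo[1]],
                "u1": states[combo[2]],
                "u2": states[combo[3]],
            }
            case_states, ctrl_states = combo[:2], combo[2:]
            expected = (
                all(s in ("het", "nocall") for s in case_states)
                and any(s == "het" for s in case_states)
                and all(s == "homref" for s in ctrl_states)
            )
            got = dominant_filter(
                [var("1", 5, calls)], {"c1", "c2"}, {"u1", "u2"}
            )
            assert bool(got) == expected, combo

    def test_lax_reading_tolerates_control_nocall(self):
        v = var("2", 100, {"a": HET, "b": HET, "x": NOCALL, "y": HOM_REF})
        assert dominant_filter([v], {"a", "b"}, {"x", "y"}) == []
        assert dominant_filter(
            [v], {"a", "b"}, {"x", "y"}, require_hom_ref_controls=False
        ) == [v]

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            dominant_filter([], {"a"}, {"a", "b"})


class TestRarityFilter:
    config = FunnelConfig(case_ids=frozenset("a"), control_ids=frozenset("b"))

    def _run(self, freqs):
        v = var("1", 1)
        anns = {v.key: ann(v.key, freqs=freqs)}
        return rarity_filter([v], anns, self.config)

    def test_reported_frequencies_kept(self):
        assert self._run({"ESP6500_ea": 0.000077, "ExAC_NFE": 0.0001049}) != []

    def test_common_removed(self):
        assert self._run({"G1000": 0.05}) == []

    def test_boundary_one_percent_kept(self):
        assert self._run({"G1000": 0.01}) != []

    def test_missing_frequencies_survive(self):
        assert self._run({}) != []
        v = var("1", 1)
        assert rarity_filter([v], {}, self.config) == [v]


class TestFunctionalFilter:
    def test_class_table(self):
        # rule table over all 8 classes
        for fc in sorted(FUNC_CLASSES):
            v = var("1", 1)
            out = functional_filter([v], {v.key: ann(v.key, func_class=fc)})
            assert bool(out) == (fc in EXONIC_DAMAGE_CLASSES), fc

    def test_synonymous_removed(self):
        v = var("1", 1)
        assert functional_filter([v], {v.key: ann(v.key, func_class="synonymous")}) == []

    def test_missing_annotation_removed(self):
        assert functional_filter([var("1", 1)], {}) == []


class TestGeneListFilters:
    def test_cmd_gene_removed(self):
        v = var("1", 1)
        anns = {v.key: ann(v.key, gene="MUC16")}
        after_cmd, after_brain = gene_list_filters([v], anns, {"MUC16"}, {"MUC16"})
        assert after_cmd == [] and after_brain == []

    def test_brain_gene_kept(self):
        v = var("1", 1)
        anns = {v.key: ann(v.key, gene="APP")}
        after_cmd, after_brain = gene_list_filters([v], anns, {"MUC16"}, {"APP"})
        assert after_brain == [v]

    def test_no_gene_removed_at_brain_stage(self):
        v = var("1", 1)
        anns = {v.key: ann(v.key, gene=None)}
        after_cmd, after_brain = gene_list_filters([v], anns, set(), {"APP"})
        assert after_cmd == [v] and after_brain == []

    def test_random_membership_matches_set_arithmetic(self):
        rng = np.random.default_rng(7)
        variants, anns = [], {}
        genes = [f"G{i}" for i in range(500)]
        cmd = {g for g in genes if rng.random() < 0.2}
        brain = {g for g in genes if rng.random() < 0.5}
        for i, g in enumerate(genes):
            v = var("1", i + 1)
            variants.append(v)
            anns[v.key] = ann(v.key, gene=g)
        after_cmd, after_brain = gene_list_filters(variants, anns, cmd, brain)
        assert len(after_cmd) == sum(1 for g in genes if g not in cmd)
        assert len(after_brain) == sum(
            1 for g in genes if g not in cmd and g in brain
        )


class TestPathogenicityVote:
    config = FunnelConfig(case_ids=frozenset("a"), control_ids=frozenset("b"))

    def test_seven_of_eight_three_of_four_passes(self):
        a = ann(("1", 1, "A", "G"), n_del=7, n_cons=3)
        assert pathogenicity_vote(a, self.config)

    def test_no_votes_fails(self):
        a = ann(("1", 1, "A", "G"), n_del=0, n_cons=0)
        assert not pathogenicity_vote(a, self.config)

    def test_threshold_boundary_enumeration(self):
        for n_del in range(9):
            for n_cons in range(5):
                a = ann(("1", 1, "A", "G"), n_del=n_del, n_cons=n_cons)
                assert pathogenicity_vote(a, self.config) == (
                    n_del >= 5 and n_cons >= 2
                ), (n_del, n_cons)

    def test_lof_bypasses_vote(self):
        for fc in sorted(LOF_CLASSES):
            a = ann(("1", 1, "A", "G"), func_class=fc, n_del=0, n_cons=0)
            assert pathogenicity_vote(a, self.config), fc

    def test_missing_calls_count_against(self):
        a = AnnotationRecord(
            key=("1", 1, "A", "G"),
            gene="G",
            func_class="nonsynonymous",
            patho_calls={p: "deleterious" for p in PATHO_PREDICTORS[:4]},
            cons_calls={"CADD": "conserved"},
        )
        assert not pathogenicity_vote(a, self.config)


class TestCandidatePrioritize:
    def test_flags(self):
        v1, v2, v3 = var("1", 1), var("1", 2), var("1", 3)
        anns = {
            v1.key: ann(v1.key, gene="ADAM17"),
            v2.key: ann(v2.key, gene="LINKED"),
            v3.key: ann(v3.key, gene="LONER"),
        }
        flags = candidate_prioritize(
            [v1, v2, v3], anns, {"ADAM17"}, [("LINKED", "ADAM17")]
        )
        assert flags[v1.key] == "known_candidate"
        assert flags[v2.key] == "network_linked"
        assert flags[v3.key] == "neither"

    def test_random_graph_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(40)]
        nd = set(rng.choice(genes, size=5, replace=False))
        edges = []
        for _ in range(60):
            a, b = rng.choice(genes, size=2, replace=False)
            edges.append((a, b))
        variants, anns = [], {}
        for i, g in enumerate(genes):
            v = var("1", i + 1)
            variants.append(v)
            anns[v.key] = ann(v.key, gene=g)
        flags = candidate_prioritize(variants, anns, nd, edges)
        adjacency = {g: set() for g in genes}
        for a, b in edges:
            adjacency[a].add(b)
            adjacency[b].add(a)
        for v in variants:
            g = anns[v.key].gene
            if g in nd:
                expected = "known_candidate"
            elif adjacency[g] & nd:
                expected = "network_linked"
            else:
                expected = "neither"
            assert flags[v.key] == expected, g


class TestSharedRegions:
    def _config(self, **kw):
        base = dict(
            case_ids=frozenset({"a", "b"}),
            control_ids=frozenset({"x"}),
            window_size=100,
            max_mismatch_frac=0.02,
        )
        base.update(kw)
        return FunnelConfig(**base)

    def test_identical_vectors_single_region(self):
        rng = np.random.default_rng(0)
        variants = []
        for i in range(500):
            g = GenotypeCall(*sorted(rng.integers(0, 2, 2)), "VQHIGH")
            variants.append(var("1", (i + 1) * 10, {"a": g, "b": g}))
        regions = shared_regions(variants, ["a", "b"], self._config())
        assert len(regions) == 1
        assert regions[0].start == 10 and regions[0].end == 5000
        assert regions[0].n_sites == 500

    def test_too_few_sites_empty(self):
        variants = [var("1", i + 1, {"a": HET, "b": HET}) for i in range(50)]
        assert shared_regions(variants, ["a", "b"], self._config()) == []

    def test_requires_two_cases(self):
        with pytest.raises(ValueError):
            shared_regions([], ["a"], self._config())

    def test_sibling_ibd_coverage(self):
        # gene-dropping oracle: the truth record knows the real IBD segments
        from famvar.simulate import SimulationConfig, gene_drop
        from famvar.pedigree import Individual, Pedigree

        ped = Pedigree(
            [
                Individual("F", sex="male"),
                Individual("M", sex="female"),
                Individual("S1", "F", "M", "male"),
                Individual("S2", "F", "M", "female"),
            ]
        )
        config = SimulationConfig(
            seed=5, n_background_variants=2000, chrom_sites={"chr1": 2000}
        )
        per_genome, truth = gene_drop(ped, config)
        merged = union_variants(per_genome)
        regions = shared_regions(merged, ["S1", "S2"], self._config())
        ibd = [seg for seg in truth.ibd_segments("S1", "S2")]
        ibd_len = sum(e - s for _, s, e in ibd)
        covered = 0
        for chrom, s, e in ibd:
            for r in regions:
                if r.chrom == chrom:
                    lo, hi = max(s, r.start), min(e, r.end)
                    covered += max(0, hi - lo)
        assert ibd_len > 0
        assert covered >= 0.95 * ibd_len

    def test_unrelated_low_sharing(self):
        from famvar.simulate import SimulationConfig, gene_drop
        from famvar.pedigree import Individual, Pedigree

        ped = Pedigree([Individual("A", sex="male"), Individual("B", sex="female")])
        config = SimulationConfig(
            seed=9,
            n_background_variants=2000,
            chrom_sites={"chr1": 2000},
            freq_range=(0.3, 0.5),
        )
        per_genome, truth = gene_drop(ped, config)
        merged = union_variants(per_genome)
        regions = shared_regions(merged, ["A", "B"], self._config())
        chrom_len = 2000 * config.site_spacing
        total = sum(r.end - r.start for r in regions)
        assert total < 0.05 * chrom_len


class TestCarrierFreq:
    def test_gnomad_arithmetic(self):
        freq = carrier_allele_freq(9, 138_390)
        assert round_sig(freq, 3) == pytest.approx(0.0000325)

    def test_invalid(self):
        with pytest.raises(ValueError):
            carrier_allele_freq(1, 0)


def _mini_inputs(order_seed=None):
    """A small hand-built funnel input with one fully qualifying variant."""
    cases, controls = {"c1", "c2"}, {"u1", "u2"}
    seg = {"c1": HET, "c2": HET, "u1": HOM_REF, "u2": HOM_REF}
    variants = {
        "good": var("1", 10, dict(seg)),
        "lowq": var(
            "1", 20, {k: (LOW_HET if v.is_het else GenotypeCall(0, 0, "low")) for k, v in seg.items()}
        ),
        "nonseg": var("1", 30, {"c1": HET, "c2": HOM_REF, "u1": HOM_REF, "u2": HOM_REF}),
        "common": var("1", 40, dict(seg)),
        "synon": var("1", 50, dict(seg)),
        "cmd": var("1", 60, dict(seg)),
        "nonbrain": var("1", 70, dict(seg)),
        "benign": var("1", 80, dict(seg)),
    }
    anns = {
        variants["good"].key: ann(variants["good"].key, gene="GOOD", freqs={"x": 0.001}, n_del=6, n_cons=3),
        variants["common"].key: ann(variants["common"].key, gene="C0", freqs={"x": 0.2}, n_del=6, n_cons=3),
        variants["synon"].key: ann(variants["synon"].key, gene="S0", func_class="synonymous"),
        variants["cmd"].key: ann(variants["cmd"].key, gene="MUC1", n_del=6, n_cons=3),
        variants["nonbrain"].key: ann(variants["nonbrain"].key, gene="NB", n_del=6, n_cons=3),
        variants["benign"].key: ann(variants["benign"].key, gene="BEN", n_del=2, n_cons=1),
        variants["nonseg"].key: ann(variants["nonseg"].key, gene="NS", n_del=6, n_cons=3),
        variants["lowq"].key: ann(variants["lowq"].key, gene="LQ", n_del=6, n_cons=3),
    }
    per_genome = {
        iid: [
            VariantRecord(v.chrom, v.pos, v.ref, v.alt, {iid: v.calls[iid]})
            for v in variants.values()
        ]
        for iid in ("c1", "c2", "u1", "u2")
    }
    if order_seed is not None:
        rng = np.random.default_rng(order_seed)
        for iid in per_genome:
            rng.shuffle(per_genome[iid])
    config = FunnelConfig(
        case_ids=frozenset(cases),
        control_ids=frozenset(controls),
        apply_shared_regions=False,
    )
    gene_lists = dict(
        cmd_genes={"MUC1"},
        brain_genes={"GOOD", "C0", "S0", "BEN", "NS", "LQ"},
        nd_genes={"GOOD"},
        network_edges=[],
    )
    return per_genome, anns, gene_lists, config, variants


class TestRunFunnel:
    def test_stagewise_counts_match_construction(self):
        per_genome, anns, lists, config, variants = _mini_inputs()
        report = run_funnel(
            per_genome, anns, lists["cmd_genes"], lists["brain_genes"],
            lists["nd_genes"], lists["network_edges"], config,
        )
        assert report.counts() == {
            "union": 8,
            "quality": 7,
            "shared_region": 7,
            "dominant": 6,
            "rare": 5,
            "functional": 4,
            "cmd_excluded": 3,
            "brain_expressed": 2,
            "pathogenic": 1,
            "candidates": 1,
        }
        assert report.final == [variants["good"].key]
        assert report.candidate_flags[variants["good"].key] == "known_candidate"

    def test_monotone_and_conserving(self):
        per_genome, anns, lists, config, _ = _mini_inputs()
        report = run_funnel(
            per_genome, anns, lists["cmd_genes"], lists["brain_genes"],
            lists["nd_genes"], lists["network_edges"], config,
        )
        counts = [s.n for s in report.stages]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        total_removed = sum(s.n_removed for s in report.stages[1:])
        assert counts[0] - total_removed == counts[-1]

    def test_input_order_invariance(self):
        results = []
        for seed in (None, 1, 2):
            per_genome, anns, lists, config, _ = _mini_inputs(order_seed=seed)
            report = run_funnel(
                per_genome, anns, lists["cmd_genes"], lists["brain_genes"],
                lists["nd_genes"], lists["network_edges"], config,
            )
            results.append((report.counts(), report.final))
        assert results[0] == results[1] == results[2]

    def test_empty_input_all_zero(self):
        config = FunnelConfig(
            case_ids=frozenset({"a", "b"}),
            control_ids=frozenset({"x"}),
            apply_shared_regions=False,
        )
        report = run_funnel({}, {}, set(), set(), set(), [], config)
        assert all(s.n == 0 for s in report.stages)
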