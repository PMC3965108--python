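"""Boundary assignment, the high-confidence gate, and hierarchy placement."""

import random

import pytest

from scope_autoclass.classifier import (
    AUTOMATED_MATCHES,
    GATE_RULES,
    DomainPrediction,
    EntryMeta,
    assign_domains,
    classify_chain,
    gate_confidence,
    place_in_hierarchy,
)
from scope_autoclass.core_model import ChainRecord, Parameters, ResidueRange, ranges_to_set
from scope_autoclass.seq_search import AlignmentHit, DomainDatabase, HitGroup
from scope_autoclass.fixtures import FixtureSpec, derive_query, generate_release


def chain(n=600, observed=None, resolution=2.0, description="test chain"):
    return ChainRecord("1qry", "A", "A" * n,
                       [ResidueRange(a, b) for a, b in (observed or ((1, n),))],
                       resolution, description)


def hit(qs, qe, sid="dtgtaa1", ts=1, te=None, e=1e-9, pct=95.0):
    return AlignmentHit(ResidueRange(qs, qe), sid,
                        ResidueRange(ts, te or (qe - qs + 1)), e, pct)


def group(*hits, key=("tgta", "A")):
    from scope_autoclass.core_model import range_union_size
    return HitGroup(key, list(hits),
                    range_union_size([h.query_range for h in hits]))


class TestAssignDomains:
    def test_worked_example_boundaries(self, worked_example):
        """554-residue chain, observed 2-547, hits 2-224 and 226-544 must
        yield predicted domains 2-225 and 226-547."""
        preds = assign_domains(worked_example.hit_group, worked_example.chain)
        assert [[str(r) for r in p.ranges] for p in preds] == [["2-225"], ["226-547"]]

    def test_clip_then_extend_to_terminus(self):
        c = chain(200, observed=((10, 130),))
        (pred,) = assign_domains(group(hit(1, 120)), c)
        assert [str(r) for r in pred.ranges] == ["10-130"]

    def test_no_extension_past_the_limit(self):
        c = chain(200, observed=((1, 105),))
        (pred,) = assign_domains(group(hit(1, 90)), c)
        assert pred.ranges[-1].end == 90

    def test_extension_reaches_an_interior_gap_edge(self):
        c = chain(300, observed=((1, 95), (120, 300)))
        (pred,) = assign_domains(group(hit(1, 90)), c)
        assert pred.ranges == [ResidueRange(1, 95)]

    def test_interior_linker_appends_to_preceding_domain(self):
        c = chain(300)
        preds = assign_domains(group(hit(1, 140, "dtgtaa1"),
                                     hit(148, 300, "dtgtaa2", te=153)), c)
        assert [p.ranges for p in preds] == [[ResidueRange(1, 147)],
                                             [ResidueRange(148, 300)]]

    def test_long_interior_gap_is_left_unassigned(self):
        c = chain(300)
        preds = assign_domains(group(hit(1, 140, "dtgtaa1"),
                                     hit(160, 300, "dtgtaa2", te=141)), c)
        assert [p.ranges for p in preds] == [[ResidueRange(1, 140)],
                                             [ResidueRange(160, 300)]]

    def test_predictions_never_contain_unobserved_residues(self, flat_release):
        for i, key in enumerate(sorted(flat_release.chains)):
            q = derive_query(flat_release, key, 0.05,
                             gap_spec=((40, 12), (90, 5)), seed=50 + i,
                             pdb_id=f"g{i:03d}")
            from scope_autoclass.seq_search import filter_hits, group_and_rank, search
            db = DomainDatabase.from_bundle(flat_release)
            params = Parameters()
            hits = filter_hits(search(q.chain.seqres, db, params), db, params)
            groups = group_and_rank(hits, db)
            preds = assign_domains(groups[0], q.chain, params)
            obs = ranges_to_set(q.chain.observed_ranges)
            for p in preds:
                assert ranges_to_set(p.ranges) <= obs

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            assign_domains(HitGroup(("tgta", "A"), [], 0), chain())

    def test_hit_past_seqres_is_integrity_error(self):
        from scope_autoclass.errors import IntegrityError
        with pytest.raises(IntegrityError):
            assign_domains(group(hit(1, 700)), chain(600))


class TestGate:
    """Each rule exercised on the worked example, perturbed one axis at a time."""

    def _verdict(self, fx, chain=None, preds=None, meta=None, hits=None):
        preds = preds if preds is not None else assign_domains(fx.hit_group, fx.chain)
        return gate_confidence(
            preds, chain or fx.chain, fx.hit_group, fx.database, Parameters(),
            entry_meta=meta,
            all_filtered_hits=hits if hits is not None else fx.all_filtered_hits)

    def test_worked_example_is_accepted(self, worked_example):
        v = self._verdict(worked_example)
        assert v.accepted and not v.reason_codes

    def test_resolution_cutoff_is_inclusive(self, worked_example):
        v = self._verdict(worked_example, meta=EntryMeta(3.0, ""))
        assert v.reason_codes == {"LOW_RESOLUTION"}
        assert not self._verdict(worked_example, meta=EntryMeta(2.99, "")).reason_codes

    def test_non_crystallographic_entries_are_not_resolution_gated(self, worked_example):
        assert self._verdict(worked_example, meta=EntryMeta(None, "")).accepted

    def test_ribosomal_keyword_blocks_acceptance(self, worked_example):
        v = self._verdict(worked_example, meta=EntryMeta(2.0, "30S ribosomal protein"))
        assert v.reason_codes == {"RIBOSOMAL_OR_SYNTHETIC"}

    def test_duplicate_target_domain_blocks_acceptance(self, worked_example):
        fx = worked_example
        preds = assign_domains(fx.hit_group, fx.chain)
        dup = [preds[0],
               DomainPrediction(preds[1].query_chain_key, preds[1].ranges,
                                preds[0].source_hit)]
        assert "DUPLICATE_TARGET_DOMAIN" in self._verdict(fx, preds=dup).reason_codes

    def test_unassigned_observed_region_blocks_acceptance(self, worked_example):
        fx = worked_example
        preds = assign_domains(fx.hit_group, fx.chain)
        # shrink the second domain so >10 observed residues go unassigned
        short = DomainPrediction(preds[1].query_chain_key,
                                 [ResidueRange(226, 536)], preds[1].source_hit)
        v = self._verdict(fx, preds=[preds[0], short])
        assert "UNASSIGNED_REGION" in v.reason_codes
        # exactly 10 leftover residues are tolerated
        edge = DomainPrediction(preds[1].query_chain_key,
                                [ResidueRange(226, 537)], preds[1].source_hit)
        assert "UNASSIGNED_REGION" not in self._verdict(fx, preds=[preds[0], edge]).reason_codes

    def test_no_predictions_yields_no_hits_code(self, worked_example):
        v = self._verdict(worked_example, preds=[])
        assert not v.accepted and v.reason_codes == {"NO_HITS"}

    def test_single_domain_requires_whole_chain_target(self, worked_example):
        fx = worked_example
        preds = assign_domains(fx.hit_group, fx.chain)
        v = self._verdict(fx, preds=preds[:1])
        assert "TARGET_NOT_WHOLE_CHAIN" in v.reason_codes

    def test_three_domain_chain_fails_shape_rule(self, worked_example):
        fx = worked_example
        preds = assign_domains(fx.hit_group, fx.chain)
        extra = DomainPrediction(preds[0].query_chain_key,
                                 [ResidueRange(548, 548)], preds[1].source_hit)
        split = [DomainPrediction(preds[0].query_chain_key,
                                  [ResidueRange(2, 100)], preds[0].source_hit),
                 DomainPrediction(preds[0].query_chain_key,
                                  [ResidueRange(101, 225)], preds[1].source_hit),
                 DomainPrediction(preds[0].query_chain_key,
                                  [ResidueRange(226, 547)], preds[0].source_hit)]
        assert "MULTIDOMAIN_SHAPE" in self._verdict(fx, preds=split).reason_codes

    def test_genetic_homolog_in_any_group_blocks_acceptance(self, worked_example):
        fx = worked_example
        from scope_autoclass.seq_search import DomainInfo
        fx2_entries = dict(fx.database.entries)
        fx2_entries["dgenea1"] = DomainInfo("dgenea1", 999, 100, ("gene", "A"),
                                            "c.9.1.1", True, False)
        db = DomainDatabase(fx2_entries, dict(fx.database.sequences),
                            dict(fx.database.chain_seqres))
        genetic_hit = hit(2, 101, "dgenea1", 1, 100)
        preds = assign_domains(fx.hit_group, fx.chain)
        v = gate_confidence(preds, fx.chain, fx.hit_group, db, Parameters(),
                            all_filtered_hits=fx.all_filtered_hits + [genetic_hit])
        assert "GENETIC_DOMAIN_HOMOLOG" in v.reason_codes

    def test_reason_codes_are_independent_of_rule_order(self, worked_example):
        fx = worked_example
        preds = assign_domains(fx.hit_group, fx.chain)
        dup = [preds[0],
               DomainPrediction(preds[1].query_chain_key,
                                [ResidueRange(226, 530)], preds[0].source_hit)]
        rng = random.Random(0)
        baseline = None
        for _ in range(6):
            order = list(GATE_RULES)
            rng.shuffle(order)
            v = gate_confidence(dup, fx.chain, fx.hit_group, fx.database,
                                Parameters(), entry_meta=EntryMeta(3.5, ""),
                                all_filtered_hits=fx.all_filtered_hits,
                                rule_order=order)
            baseline = baseline or v.reason_codes
            assert v.reason_codes == baseline
        assert baseline >= {"LOW_RESOLUTION", "DUPLICATE_TARGET_DOMAIN",
                            "UNASSIGNED_REGION"}


class TestPlacement:
    def test_exact_full_match_inherits_down_to_species(self, worked_example):
        fx = worked_example
        preds = assign_domains(fx.hit_group, fx.chain)
        placed = place_in_hierarchy(preds[0], fx.release.hierarchy, fx.database)
        h = fx.release.hierarchy
        info = fx.database.info(preds[0].source_hit.target_sid)
        assert placed.placement_mode == "matched"
        assert placed.superfamily_sunid == h.get_ancestor(info.sunid, "superfamily")
        assert placed.species_sunid == h.get_ancestor(info.sunid, "species")

    def test_moderate_identity_falls_back_at_family(self, worked_example):
        fx = worked_example
        preds = assign_domains(fx.hit_group, fx.chain)
        weak = DomainPrediction(
            preds[0].query_chain_key, preds[0].ranges,
            AlignmentHit(preds[0].source_hit.query_range, preds[0].source_hit.target_sid,
                         preds[0].source_hit.target_range, 1e-20, 55.0))
        import copy
        h = copy.deepcopy(fx.release.hierarchy)
        placed = place_in_hierarchy(weak, h, fx.database)
        assert placed.placement_mode == "automated_matches"
        assert h.node(placed.family_sunid).description == AUTOMATED_MATCHES
        assert h.node(placed.species_sunid).description == AUTOMATED_MATCHES
        # superfamily still inherited
        info = fx.database.info(weak.source_hit.target_sid)
        assert placed.superfamily_sunid == h.get_ancestor(info.sunid, "superfamily")

    def test_high_identity_partial_coverage_falls_back_below_family(self, worked_example):
        fx = worked_example
        preds = assign_domains(fx.hit_group, fx.chain)
        src = preds[0].source_hit
        partial = DomainPrediction(
            preds[0].query_chain_key, preds[0].ranges,
            AlignmentHit(src.query_range, src.target_sid,
                         ResidueRange(src.target_range.start, src.target_range.end - 5),
                         1e-20, 95.0))
        import copy
        h = copy.deepcopy(fx.release.hierarchy)
        placed = place_in_hierarchy(partial, h, fx.database)
        assert placed.placement_mode == "automated_matches"
        assert h.node(placed.family_sunid).description != AUTOMATED_MATCHES
        assert h.node(placed.protein_sunid).description == AUTOMATED_MATCHES

    def test_fallback_nodes_are_reused_not_duplicated(self, worked_example):
        fx = worked_example
        preds = assign_domains(fx.hit_group, fx.chain)
        weak = DomainPrediction(
            preds[0].query_chain_key, preds[0].ranges,
            AlignmentHit(preds[0].source_hit.query_range, preds[0].source_hit.target_sid,
                         preds[0].source_hit.target_range, 1e-20, 55.0))
        import copy
        h = copy.deepcopy(fx.release.hierarchy)
        before = len(h)
        a = place_in_hierarchy(weak, h, fx.database)
        created = len(h) - before
        b = place_in_hierarchy(weak, h, fx.database)
        assert created == 3  # family + protein + species, created once
        assert len(h) == before + created
        assert (a.family_sunid, a.protein_sunid, a.species_sunid) == (
            b.family_sunid, b.protein_sunid, b.species_sunid)


class TestClassifyChain:
    def test_worked_example_end_to_end(self, worked_example):
        fx = worked_example
        preds, verdict = classify_chain(fx.chain, fx.database,
                                        fx.release.hierarchy)
        assert verdict.accepted
        assert [[str(r) for r in p.ranges] for p in preds] == [["2-225"], ["226-547"]]
        assert all(p.superfamily_sunid is not None for p in preds)

    def test_unrelated_chain_gets_no_hits(self, worked_example):
        fx = worked_example
        import numpy as np
        from scope_autoclass.fixtures import AMINO_ACIDS
        rng = np.random.default_rng(99)
        alien = ChainRecord("9zzz", "A",
                            "".join(rng.choice(list(AMINO_ACIDS), size=120)),
                            [ResidueRange(1, 120)], 2.0, "unrelated")
        preds, verdict = classify_chain(alien, fx.database, fx.release.hierarchy)
        assert preds == [] and verdict.reason_codes == {"NO_HITS"}

    def test_self_classification_recovers_whole_chain_domains(self, flat_release):
        """Classifying a release's own single-domain chains against its own
        database must reproduce every whole-chain assignment exactly."""
        db = DomainDatabase.from_bundle(flat_release)
        import copy
        h = copy.deepcopy(flat_release.hierarchy)
        for key in sorted(flat_release.chains):
            c = flat_release.chains[key]
            preds, verdict = classify_chain(c, db, h)
            assert verdict.accepted, verdict.reason_codes
            (pred,) = preds
            assert pred.ranges == [ResidueRange(1, len(c.seqres))]
            (dom,) = flat_release.domains_on_chain(key)
            assert pred.superfamily_sunid == h.get_ancestor(dom.sunid, "superfamily")
            assert pred.placement_mode == "matched"

    def test_deterministic_prediction_dump(self, worked_example):
        from scope_autoclass.classifier import dump_predictions_tsv
        fx = worked_example
        outs = set()
        for _ in range(2):
            preds, verdict = classify_chain(fx.chain, fx.database,
                                            fx.release.hierarchy)
            outs.add(dump_predictions_tsv(preds, {fx.chain.key: verdict}))
        assert len(outs) == 1
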