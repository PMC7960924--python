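"""Filter cascade, inheritance pairing and cohort-level behavior."""

import pytest

from intronseek.prioritization import (
    CandidateStatus,
    GenePanelEntry,
    deep_intronic_filter,
    frequency_filter,
    inheritance_pairing,
    max_delta,
    panel_restrict,
    prioritize_cohort,
    splice_score_filter,
)
from intronseek.synthetic_data import (
    CohortSpec,
    annotated_cohort,
    plant_cohort,
    simulate_genome_and_models,
)
from intronseek.variant_io import AnnotatedVariant, SpliceAIRecord


def _v(af=None, scores=(0, 0, 0, 0), gene="G1", pos=1000, zygosity="het",
       coding="none", proband="P1", contig="c1", ref="A", alt="G"):
    rec = None
    if scores is not None:
        rec = SpliceAIRecord(alt, gene, *scores, 0, 0, 0, 0)
    return AnnotatedVariant(
        contig=contig, pos=pos, ref=ref, alt=alt, proband=proband, gene=gene,
        zygosity=zygosity, allele_frequency=af, coding_class=coding,
        spliceai=rec,
    )


# ---------------------------------------------------------------------------
# individual filters


@pytest.mark.parametrize(
    "af, kept",
    [(0.004, True), (0.006, False), (1.43e-5, True), (None, True),
     (0.005, False)],
)
def test_frequency_filter_boundaries(af, kept):
    survivors, removed = frequency_filter([_v(af=af)])
    assert bool(survivors) is kept
    assert bool(removed) is not kept


@pytest.mark.parametrize(
    "scores, expected",
    [((0.8, 0, 0.7, 0), 0.8), ((0, 0, 0, 0), 0.0), ((0.5, 0.49, 0.2, 0.1), 0.5)],
)
def test_max_delta(scores, expected):
    assert max_delta(_v(scores=scores).spliceai) == pytest.approx(expected)


@pytest.mark.parametrize(
    "scores, kept",
    [((0.49, 0, 0, 0), False), ((0.5, 0, 0, 0), True), (None, False)],
)
def test_splice_score_filter_cutoff_inclusive(scores, kept):
    survivors, _ = splice_score_filter([_v(scores=scores)])
    assert bool(survivors) is kept


def test_panel_restrict_case_sensitive():
    panel = {"G1": GenePanelEntry("G1", "AR", "t1")}
    kept, removed = panel_restrict([_v(gene="G1"), _v(gene="g1")], panel)
    assert [v.gene for v in kept] == ["G1"]
    assert [v.gene for v in removed] == ["g1"]


def test_deep_intronic_filter(tx_by_gene, bundle):
    tx = tx_by_gene["RPGRIP1"]
    intron = tx.introns[1]
    def at(pos):
        return _v(gene="RPGRIP1", contig=tx.contig, pos=pos,
                  scores=(0.9, 0, 0, 0))

    deep = at(intron[0] + 81)       # offset +82
    near = at(intron[0] + 9)        # offset +10: strictly > 10 required
    exonic = at(tx.exons[0][0] + 5)
    kept, removed = deep_intronic_filter([deep, near, exonic], tx_by_gene)
    assert kept == [deep]
    assert set(v.pos for v in removed) == {near.pos, exonic.pos}


def test_deep_intronic_filter_missing_transcript():
    with pytest.raises(ValueError, match="NOGENE"):
        deep_intronic_filter([_v(gene="NOGENE")], {})


# ---------------------------------------------------------------------------
# inheritance pairing


def test_ad_single_hit_solves():
    status = inheritance_pairing([_v()], [], "AD")
    assert status.status == "solved_candidate"
    assert len(status.paired) == 1


def test_ar_splice_plus_coding_solves_with_two_alleles():
    splice = _v(pos=500)
    coding = _v(pos=100, scores=None, coding="frameshift")
    status = inheritance_pairing([splice], [coding], "AR")
    assert status.status == "solved_candidate"
    assert len(status.paired) == 2
    assert status.phase == "unconfirmed"


def test_ar_lone_het_needs_second_allele():
    status = inheritance_pairing([_v()], [], "AR")
    assert status.status == "needs_second_allele"
    assert "unpaired" in status.reasons


def test_ar_homozygous_splice_solves():
    status = inheritance_pairing([_v(zygosity="hom")], [], "AR")
    assert status.status == "solved_candidate"


def test_ar_two_het_splice_variants_solve():
    status = inheritance_pairing([_v(pos=500), _v(pos=900)], [], "AR")
    assert status.status == "solved_candidate"
    assert len(status.paired) == 2


def test_xl_hemi_solves_het_does_not():
    assert inheritance_pairing([_v(zygosity="hemi")], [], "XL").status == \
        "solved_candidate"
    assert inheritance_pairing([_v(zygosity="het")], [], "XL").status == \
        "needs_second_allele"


def test_unknown_mode_rejected():
    with pytest.raises(ValueError, match="mode"):
        inheritance_pairing([_v()], [], "mitochondrial")


def test_de_novo_phase_from_parents():
    splice = _v(pos=500)
    coding = _v(pos=100, scores=None, coding="nonsense")
    parents = {
        splice.key: {"father": 0, "mother": 0},
        coding.key: {"father": 0, "mother": 1},
    }
    status = inheritance_pairing([splice], [coding], "AR",
                                 parental_genotypes=parents)
    assert status.phase == "de_novo"


def test_trans_phase_from_parents():
    splice = _v(pos=500)
    coding = _v(pos=100, scores=None, coding="nonsense")
    parents = {
        splice.key: {"father": 1, "mother": 0},
        coding.key: {"father": 0, "mother": 1},
    }
    status = inheritance_pairing([splice], [coding], "AR",
                                 parental_genotypes=parents)
    assert status.phase == "trans_confirmed"


def test_candidate_status_invariants():
    with pytest.raises(ValueError):
        CandidateStatus(status="rejected", reasons=[])


# ---------------------------------------------------------------------------
# cohort-level properties


def _cohort_world(seed, **kwargs):
    spec = CohortSpec(seed=seed, **kwargs)
    genome, models, panel = simulate_genome_and_models(spec)
    cohort, truth = plant_cohort(spec, genome, models, panel)
    manifest = annotated_cohort(cohort)
    tx = {t.gene: t for t in models}
    return spec, genome, models, panel, tx, manifest, truth


def _candidate_keys(reports):
    return {
        e["variant"].key
        for r in reports
        for e in r.splice_variants
        if e["status"] == "solved_candidate"
    }


@pytest.mark.parametrize("seed", [2, 3])
def test_threshold_relaxation_is_monotone(seed):
    """Lowering the score cutoff / raising af_max never shrinks the set."""
    _, _, _, panel, tx, manifest, _ = _cohort_world(seed)
    strict, _ = prioritize_cohort(manifest, panel, tx,
                                  af_max=0.005, score_cutoff=0.5)
    lax_score, _ = prioritize_cohort(manifest, panel, tx,
                                     af_max=0.005, score_cutoff=0.3)
    lax_af, _ = prioritize_cohort(manifest, panel, tx,
                                  af_max=0.05, score_cutoff=0.5)
    base = _candidate_keys(strict)
    assert base <= _candidate_keys(lax_score)
    assert base <= _candidate_keys(lax_af)


def test_filters_commute_on_final_set():
    """The pure filters give the same survivor set in any order."""
    from itertools import permutations

    _, _, _, panel, tx, manifest, _ = _cohort_world(5)
    variants = [v for vs in manifest.values() for v in vs]
    filters = {
        "freq": lambda vs: frequency_filter(vs)[0],
        "score": lambda vs: splice_score_filter(vs)[0],
        "panel": lambda vs: panel_restrict(vs, panel)[0],
        "deep": lambda vs: deep_intronic_filter(vs, tx)[0],
    }
    results = set()
    for order in permutations(filters):
        vs = variants
        for name in order:
            vs = filters[name](vs)
        results.add(frozenset((v.proband, v.key) for v in vs))
    assert len(results) == 1


def test_planted_recovery_and_zero_decoy_leakage():
    """Every planted configuration solves; no decoy ever becomes a candidate."""
    for seed in range(6, 10):
        _, _, _, panel, tx, manifest, truth = _cohort_world(seed)
        reports, summary = prioritize_cohort(manifest, panel, tx)
        by_proband = {r.proband: r for r in reports}
        causal_keys = {k for t in truth for k in t.variant_keys}
        for t in truth:
            report = by_proband[t.proband]
            if t.intended_status == "solved_candidate":
                assert report.statuses[t.gene].status == "solved_candidate", t
            else:
                assert not report.solved, t
        assert _candidate_keys(reports) <= causal_keys


def test_zeroed_scores_give_no_candidates(bundle, tx_by_gene):
    import dataclasses

    manifest = {}
    for proband, variants in annotated_cohort(bundle.cohort).items():
        muted = []
        for v in variants:
            if v.spliceai is not None:
                v = dataclasses.replace(
                    v,
                    spliceai=dataclasses.replace(
                        v.spliceai, ds_ag=0.0, ds_al=0.0, ds_dg=0.0, ds_dl=0.0
                    ),
                )
            muted.append(v)
        manifest[proband] = muted
    _, summary = prioritize_cohort(manifest, bundle.panel, tx_by_gene)
    assert summary["distinct_splice_variants"] == 0
    assert summary["solved_probands"] == 0
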