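"""ACMG/AMP engine: evaluators, combining rules, worked examples, and
exhaustive equivalence with an independently written rule-table oracle."""
from itertools import combinations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmn.acmg import (
    CriterionAssignment,
    classify_germline_variant,
    combine_criteria,
    evaluate_pm1,
    evaluate_pm2,
    evaluate_pp3,
    evaluate_pvs1,
    evaluate_reputable_source,
    parse_token,
)
from tmn.examples import COHORT_SIZE, GERMLINE_EXAMPLES
from tmn.types import AnnotatedVariant, AnnotationBundle, Origin, VariantCall


def ann(**kw):
    return AnnotationBundle(gene=kw.pop("gene", "RUNX1"), **kw)


class TestPVS1:
    def test_nonsense_with_nmd_is_very_strong(self):
        c = evaluate_pvs1(ann(consequence="nonsense", nmd_predicted="yes"))
        assert c.token == "PVS1"

    def test_frameshift_escaping_nmd_downgraded(self):
        c = evaluate_pvs1(ann(consequence="frameshift", nmd_predicted="no"))
        assert c.token == "PVS1_Strong"

    def test_canonical_splice_is_very_strong_regardless_of_nmd(self):
        c = evaluate_pvs1(ann(consequence="canonical_splice", nmd_predicted="unknown"))
        assert c.token == "PVS1"

    def test_synonymous_is_not_a_null_variant(self):
        assert evaluate_pvs1(ann(consequence="synonymous")) is None

    def test_non_lof_gene_ineligible(self):
        assert evaluate_pvs1(
            ann(consequence="nonsense", nmd_predicted="yes"), lof_mechanism=False
        ) is None


class TestPM2:
    @pytest.mark.parametrize(
        "freq,inheritance,fires",
        [
            (0.00000796, "AR", True),
            (0.0, "AD", True),
            (None, "AD", True),            # absent from gnomAD
            (0.0000757, "AD", False),      # 7.57e-5 >= 1e-5 dominant cut
            (0.0000757, "AR", True),       # same frequency passes recessive cut
            (0.0001, "AR", False),         # strict inequality at the boundary
            (0.00002, "unknown", False),   # unknown defaults to the stricter cut
        ],
    )
    def test_inheritance_specific_cutoffs(self, freq, inheritance, fires):
        c = evaluate_pm2(ann(freq_gnomad_exome_all=freq, inheritance=inheritance))
        assert (c is not None) is fires


class TestPP3:
    @pytest.mark.parametrize(
        "sift,pp2,cadd,fires",
        [
            ("D", "D", 25.0, True),
            ("D", "P", 25.0, True),
            ("D", "B", 25.0, False),
            ("T", "D", 25.0, False),
            ("D", "P", 20.0, False),       # strict > 20
            ("D", "missing", 25.0, False),
            ("D", "D", None, False),
        ],
    )
    def test_three_tool_concordance(self, sift, pp2, cadd, fires):
        c = evaluate_pp3(ann(sift=sift, polyphen2_hvar=pp2, cadd_phred=cadd))
        assert (c is not None) is fires


class TestReputableSource:
    def test_clinvar_lp_with_stars_fires(self):
        c = evaluate_reputable_source(
            ann(clinvar_significance="likely_pathogenic", clinvar_stars=2)
        )
        assert c is not None and c.code == "PP5"

    def test_vus_with_stars_and_low_confidence_dm_does_not_fire(self):
        assert evaluate_reputable_source(
            ann(clinvar_significance="uncertain significance", clinvar_stars=2,
                hgmd_class="DM_low")
        ) is None

    def test_conflicting_clinvar_but_high_confidence_dm_fires(self):
        c = evaluate_reputable_source(
            ann(clinvar_significance="conflicting interpretations of pathogenicity",
                clinvar_stars=1, hgmd_class="DM_high")
        )
        assert c is not None

    def test_clinvar_pathogenic_without_stars_does_not_fire(self):
        assert evaluate_reputable_source(
            ann(clinvar_significance="pathogenic", clinvar_stars=0)
        ) is None


def test_pm1_is_annotation_driven():
    assert evaluate_pm1(ann(hotspot_domain=True)).code == "PM1"
    assert evaluate_pm1(ann(hotspot_domain=False)) is None


# ---------------------------------------------------------------------------
# combining rules
# ---------------------------------------------------------------------------

def toks(*tokens):
    return [parse_token(t) for t in tokens]


@pytest.mark.parametrize(
    "tokens,verdict",
    [
        (("PVS1", "PM2", "PP5"), "P"),
        (("PVS1_Strong", "PM2"), "LP"),
        (("PM1", "PM2", "PP3", "PP5"), "LP"),
        (("PVS1", "PM2"), "LP"),
        ((), "VUS"),
        (("PM2",), "VUS"),
        (("BA1",), "B"),
        (("BS1", "BS2"), "B"),
        (("BS1", "BP4"), "LB"),
        (("BP4", "BP7"), "LB"),
        (("PVS1", "PS1"), "P"),
        (("PS1", "PS2"), "P"),
        (("PVS1", "PM2", "BA1"), "VUS"),  # conflicting evidence
    ],
)
def test_combine_examples(tokens, verdict):
    assert combine_criteria(toks(*tokens)) == verdict


def test_unknown_strength_token_errors():
    bad = CriterionAssignment("PM2")
    bad.strength = "mystery"
    with pytest.raises(ValueError):
        combine_criteria([bad])


def oracle_combine(tokens):
    """Brute-force rule-table evaluator, written independently of the
    engine: counts tokens by effective strength and checks each published
    combination explicitly."""
    def strength(tok):
        if "_" in tok:
            return {"VeryStrong": "vs", "Strong": "s", "Moderate": "m",
                    "Supporting": "p", "StandAlone": "sa"}[tok.split("_", 1)[1]]
        return {"PVS": "vs", "PS": "s", "PM": "m", "PP": "p",
                "BA": "sa", "BS": "bs", "BP": "bp"}[
            tok[:3] if tok[:2] in ("PV",) else tok[:2]
        ]

    vs = s = m = p = sa = bs = bp = 0
    for tok in tokens:
        benign = tok.startswith("B")
        st_ = strength(tok)
        if benign:
            if st_ in ("sa",):
                sa += 1
            elif tok.startswith("BS") and "_" not in tok:
                bs += 1
            elif st_ == "s":
                bs += 1
            else:
                bp += 1
        else:
            vs += st_ == "vs"
            s += st_ == "s"
            m += st_ == "m"
            p += st_ == "p"

    path = (
        (vs >= 1 and s >= 1) or (vs >= 1 and m >= 2) or (vs >= 1 and m == 1 and p >= 1)
        or (vs >= 1 and p >= 2) or s >= 2 or (s == 1 and m >= 3)
        or (s == 1 and m == 2 and p >= 2) or (s == 1 and m == 1 and p >= 4)
    )
    lp = (
        (vs == 1 and m == 1) or (s == 1 and m in (1, 2)) or (s == 1 and p >= 2)
        or m >= 3 or (m == 2 and p >= 2) or (m == 1 and p >= 4)
    )
    b = sa >= 1 or bs >= 2
    lb = (bs == 1 and bp >= 1) or bp >= 2
    p_side = "P" if path else ("LP" if lp else None)
    b_side = "B" if b else ("LB" if lb else None)
    if p_side and b_side:
        return "VUS"
    return p_side or b_side or "VUS"


ALPHABET = ["PVS1", "PVS1_Strong", "PS1", "PM1", "PM2", "PP3", "PP5",
            "BA1", "BS1", "BP4"]


def test_engine_matches_bruteforce_oracle_over_all_small_subsets():
    """Exhaustive equivalence over all criterion subsets of size <= 5."""
    n_checked = 0
    for k in range(6):
        for subset in combinations(ALPHABET, k):
            assert combine_criteria(toks(*subset)) == oracle_combine(subset), subset
            n_checked += 1
    assert n_checked == 638


@settings(max_examples=200, deadline=None)
@given(st.lists(st.sampled_from(ALPHABET[:7]), unique=True, max_size=7))
def test_adding_pathogenic_evidence_is_monotone(tokens):
    """Adding pathogenic-side evidence never moves the verdict toward benign."""
    order = {"B": 0, "LB": 1, "VUS": 2, "LP": 3, "P": 4}
    base = combine_criteria(toks(*tokens))
    for extra in ALPHABET[:7]:
        if extra in tokens:
            continue
        augmented = combine_criteria(toks(*tokens, extra))
        assert order[augmented] >= order[base]


# ---------------------------------------------------------------------------
# worked examples
# ---------------------------------------------------------------------------

def as_candidate(example):
    return AnnotatedVariant(
        call=VariantCall(
            sample_id=f"{example.patient_id}-A", patient_id=example.patient_id,
            sample_role="tmn_initial", chrom="1", pos=1000, ref="G", alt="A",
            vaf=example.vaf, depth=example.depth, callers=frozenset({"gatk"}),
        ),
        annotation=example.annotation,
        in_germline_panel=True,
        origin=Origin.POTENTIAL_GERMLINE,
    )


@pytest.mark.parametrize("example", GERMLINE_EXAMPLES, ids=lambda e: e.patient_id)
def test_worked_examples_reproduce_verdict_and_criteria(example):
    cls = classify_germline_variant(as_candidate(example))
    assert cls.verdict == example.expected_verdict
    assert cls.criteria_string == example.expected_criteria


def test_carrier_rate_from_worked_examples():
    carriers = {
        e.patient_id
        for e in GERMLINE_EXAMPLES
        if classify_germline_variant(as_candidate(e)).deleterious
    }
    assert len(carriers) == 7
    assert round(100 * len(carriers) / COHORT_SIZE, 1) == 13.2


def test_classification_requires_germline_candidate_origin():
    avv = as_candidate(GERMLINE_EXAMPLES[0])
    avv.origin = Origin.SOMATIC
    with pytest.raises(ValueError):
        classify_germline_variant(avv)
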