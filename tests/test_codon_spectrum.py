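import itertools

import numpy as np
import pytest

from imkt import codon_spectrum as cs
from imkt.simdata import ToyEvent, make_toy_alignment
from imkt.types import Alignment, ValidationError

from oracles import codon_enumerator


def make_aln(ingroup_codons, outgroup_codons):
    """Build an alignment from lists of codon lists."""
    return Alignment(
        ingroup=[(f"i{k}", "".join(c)) for k, c in enumerate(ingroup_codons)],
        outgroup=("out", "".join(outgroup_codons)),
    )


# --- subsampling -------------------------------------------------------------

def test_subsample_full_depth_is_deterministic():
    aln = make_aln([["AAA"], ["AAA"], ["AAA"], ["AAA"]], [["AAA"][0]])
    cols = cs.subsample_columns(aln, depth=4, seed=0)
    assert cols == [{"A": 4}] * 3


def test_subsample_excludes_insufficient_columns():
    aln = make_aln([["AAA"], ["AAA"], ["ANA"], ["TAA"]], ["AAA"])
    cols = cs.subsample_columns(aln, depth=4, seed=0)
    assert cols[1] is None  # N leaves only 3 valid lines
    assert cols[0] == {"A": 3, "T": 1}


def test_subsample_draws_valid_subsets_every_seed():
    # 5 lines (A,A,A,T,T), depth 4: any 4-subset has 2 or 3 A's
    aln = make_aln([["AAA"], ["AAA"], ["AAA"], ["TAA"], ["TAA"]], ["AAA"])
    seen = set()
    for seed in range(40):
        counts = cs.subsample_columns(aln, depth=4, seed=seed)[0]
        assert sum(counts.values()) == 4
        assert counts.get("A", 0) in (2, 3)
        seen.add(counts["A"])
    assert seen == {2, 3}  # both outcomes of the enumeration occur


def test_subsample_is_invariant_to_sequence_order():
    base = [["ATA"], ["ATA"], ["GTA"], ["GCA"], ["NCA"]]
    aln1 = make_aln(base, ["ATA"])
    aln2 = make_aln(base[::-1], ["ATA"])
    assert cs.subsample_columns(aln1, 3, seed=7) == cs.subsample_columns(aln2, 3, seed=7)


def test_subsample_rejects_bad_depth():
    aln = make_aln([["AAA"], ["AAA"]], ["AAA"])
    with pytest.raises(ValidationError):
        cs.subsample_columns(aln, depth=3, seed=0)


# --- classification ----------------------------------------------------------

@pytest.mark.parametrize(
    "anc,der,expected",
    [
        ("TTT", "TTC", cs.NEUTRAL),  # Phe -> Phe
        ("TTT", "TTA", cs.SELECTED),  # Phe -> Leu
        ("CTG", "CTA", cs.NEUTRAL),  # Leu fourfold-degenerate 3rd position
        ("ATG", "ATA", cs.SELECTED),  # Met -> Ile
        ("TAC", "TAA", cs.SELECTED),  # Tyr -> stop
    ],
)
def test_classify_single_changes(anc, der, expected):
    assert cs.classify_site(anc, der) == expected


def test_classify_rejects_multi_position_changes():
    with pytest.raises(ValidationError):
        cs.classify_site("TTT", "TAC")


def test_resolve_overlapping_classes_most_constrained_wins():
    assert cs.resolve_overlapping_classes([cs.NEUTRAL, cs.SELECTED]) == cs.SELECTED
    assert cs.resolve_overlapping_classes([cs.NEUTRAL]) == cs.NEUTRAL
    assert cs.resolve_overlapping_classes([cs.SELECTED, cs.SELECTED]) == cs.SELECTED
    with pytest.raises(ValidationError):
        cs.resolve_overlapping_classes([])


# --- polarization ------------------------------------------------------------

def test_polarize_derived_count_against_outgroup():
    p = cs.polarize({"A": 3, "T": 1}, "A")
    assert (p.kind, p.derived, p.derived_count) == ("polymorphic", "T", 1)
    p = cs.polarize({"A": 3, "T": 1}, "T")
    assert (p.kind, p.derived, p.derived_count) == ("polymorphic", "A", 3)


def test_polarize_fixed_and_conserved_and_excluded():
    assert cs.polarize({"G": 4}, "T").kind == "fixed_difference"
    assert cs.polarize({"G": 4}, "G").kind == "monomorphic_conserved"
    p = cs.polarize({"A": 2, "T": 2}, "C")
    assert (p.kind, p.reason) == ("excluded", "unpolarizable")
    p = cs.polarize({"A": 2, "T": 1, "G": 1}, "A")
    assert (p.kind, p.reason) == ("excluded", "multiallelic")
    p = cs.polarize({"A": 4}, None)
    assert (p.kind, p.reason) == ("excluded", "unpolarizable")


# --- site counting -----------------------------------------------------------

def test_nei_gojobori_examples():
    m_n, m_s = cs.codon_site_counts("TTT")
    assert m_s == pytest.approx(1 / 3)  # only TTT->TTC synonymous
    assert m_n == pytest.approx(8 / 3)
    assert cs.codon_site_counts("ATG") == (3.0, 0.0)


def test_nei_gojobori_partition_identity_over_all_codons():
    for codon in map("".join, itertools.product("ACGT", repeat=3)):
        m_n, m_s = cs.codon_site_counts(codon)
        assert m_n + m_s == pytest.approx(3.0)
        assert m_n >= 0 and m_s >= 0


# --- build_tables ------------------------------------------------------------

def test_build_tables_planted_fixture():
    toy = make_toy_alignment(
        [
            ToyEvent(0, "syn-poly", 1),
            ToyEvent(2, "syn-poly", 1),
            ToyEvent(4, "nonsyn-poly", 1),
            ToyEvent(6, "syn-fixed"),
        ],
        n_codons=10,
        n_ingroup=4,
    )
    res = cs.build_tables(toy.alignment, depth=4, seed=0)
    assert [(b.daf, b.pn, b.ps) for b in res.daf.bins] == [(0.25, 1, 2), (0.5, 0, 0), (0.75, 0, 0)]
    assert (res.div.dn, res.div.ds) == (0, 1)


def test_build_tables_null_alignment():
    aln = make_aln([["ATG", "GGC"]] * 4, ["ATG", "GGC"])
    res = cs.build_tables(aln, depth=4, seed=0)
    assert res.daf.pn_total == 0 and res.daf.ps_total == 0
    assert (res.div.dn, res.div.ds) == (0, 0)
    assert res.div.m_n + res.div.m_s == pytest.approx(aln.length)


def test_build_tables_order_symmetry_without_missing_data():
    toy = make_toy_alignment(
        [ToyEvent(1, "nonsyn-poly", 2), ToyEvent(3, "syn-poly", 1)],
        n_codons=6, n_ingroup=5,
    )
    aln = toy.alignment
    perm = Alignment(ingroup=aln.ingroup[::-1], outgroup=aln.outgroup)
    r1 = cs.build_tables(aln, depth=5, seed=3)
    r2 = cs.build_tables(perm, depth=5, seed=3)
    assert [(b.daf, b.pn, b.ps) for b in r1.daf.bins] == [
        (b.daf, b.pn, b.ps) for b in r2.daf.bins
    ]
    assert (r1.div.dn, r1.div.ds) == (r2.div.dn, r2.div.ds)


def test_build_tables_errors_when_nothing_retained():
    aln = make_aln([["NNN"]] * 4, ["AAA"])
    with pytest.raises(ValidationError, match="empty_after_filters"):
        cs.build_tables(aln, depth=4, seed=0)


def test_column_accounting_covers_whole_alignment():
    toy = make_toy_alignment(
        [ToyEvent(0, "syn-poly", 1), ToyEvent(1, "missing-N"),
         ToyEvent(2, "multiallelic"), ToyEvent(3, "multihit")],
        n_codons=8, n_ingroup=4,
    )
    res = cs.build_tables(toy.alignment, depth=4, seed=0, keep_observations=True)
    assert 3 * (res.n_codons_retained + len(res.excluded_codons)) == toy.alignment.length
    assert len(res.observations) == toy.alignment.length


def test_polymorphism_counts_bounded_by_polymorphic_columns():
    toy = make_toy_alignment(
        [ToyEvent(i, "syn-poly", 1 + i % 3) for i in range(0, 12, 2)],
        n_codons=12, n_ingroup=4,
    )
    res = cs.build_tables(toy.alignment, depth=4, seed=0)
    assert res.daf.pn_total + res.daf.ps_total <= toy.alignment.length


@pytest.mark.parametrize(
    "events",
    [
        [ToyEvent(0, "syn-poly", 1), ToyEvent(1, "nonsyn-poly", 2),
         ToyEvent(2, "syn-fixed"), ToyEvent(3, "nonsyn-fixed")],
        [ToyEvent(0, "multiallelic"), ToyEvent(1, "unpolarizable"),
         ToyEvent(2, "missing-N"), ToyEvent(3, "multihit"), ToyEvent(4, "stop")],
        [ToyEvent(i, k, 1 + (i % 3)) for i, k in enumerate(
            ["syn-poly", "nonsyn-poly", "syn-poly", "nonsyn-fixed", "multihit",
             "syn-fixed", "missing-N", "nonsyn-poly"])],
    ],
)
def test_build_tables_matches_brute_force_enumerator(events):
    """On small planted alignments the pipeline equals an independent
    per-codon enumeration, including every exclusion reason."""
    toy = make_toy_alignment(events, n_codons=max(10, len(events) + 2), n_ingroup=4)
    res = cs.build_tables(toy.alignment, depth=4, seed=0)
    ref = codon_enumerator(toy.alignment)
    assert [(b.daf, b.pn, b.ps) for b in res.daf.bins] == ref["bins"]
    assert (res.div.dn, res.div.ds) == (ref["dn"], ref["ds"])
    assert res.div.m_n == pytest.approx(ref["m_n"])
    assert res.div.m_s == pytest.approx(ref["m_s"])
    assert sorted(res.excluded_codons) == ref["excluded"]


def test_build_tables_matches_enumerator_on_random_alignments(rng):
    """Fuzz: random mutations on a random coding background, full depth."""
    for trial in range(10):
        n_codons, n_in = 20, 5
        background = [
            "".join(rng.choice(list("ACGT"), 3)) for _ in range(n_codons)
        ]
        ingroup = [list("".join(background)) for _ in range(n_in)]
        outgroup = list("".join(background))
        n_mut = int(rng.integers(5, 15))
        for _ in range(n_mut):
            pos = int(rng.integers(0, 3 * n_codons))
            base = str(rng.choice(list("ACGTN")))
            if rng.random() < 0.25:
                outgroup[pos] = base
            else:
                ingroup[int(rng.integers(0, n_in))][pos] = base
        aln = Alignment(
            ingroup=[(f"i{k}", "".join(s)) for k, s in enumerate(ingroup)],
            outgroup=("out", "".join(outgroup)),
        )
        try:
            res = cs.build_tables(aln, depth=n_in, seed=0)
        except ValidationError:
            continue  # everything excluded: nothing to compare
        ref = codon_enumerator(aln)
        assert [(b.daf, b.pn, b.ps) for b in res.daf.bins] == ref["bins"], trial
        assert (res.div.dn, res.div.ds) == (ref["dn"], ref["ds"])
        assert res.div.m_n == pytest.approx(ref["m_n"])
        assert sorted(res.excluded_codons) == ref["excluded"]


def test_default_depth_targets_ninety_percent_coverage():
    # 30 columns x 5 lines; one line is N over 4 columns, so depth 5 covers
    # only 26/30 < 90% of columns while depth 4 covers all of them
    ingroup = [["AAA"] * 10 for _ in range(5)]
    ingroup[0][0] = "NNN"
    ingroup[0][1] = "NAA"
    aln = make_aln(ingroup, ["AAA"] * 10)
    assert cs.default_depth(aln) == 4
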