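"""Protease rule engine: cut sites, digestion, intact release, yield math."""

import pytest

from pepscreen import (
    CleavageRuleSet,
    SyntheticConfig,
    cut_sites,
    digest,
    gen_proteins,
    is_released_intact,
    load_rules,
    minimal_releasable_superpeptide,
    yield_estimate,
)
from pepscreen.digest import BlockingRule, save_rules


def test_default_thermolysin_targets(thermolysin):
    assert thermolysin.p1_prime_targets >= set("AFILMV")
    assert thermolysin.enzyme == "thermolysin"
    assert thermolysin.provenance  # source note ships with the rules


def test_empty_target_set_rejected():
    with pytest.raises(ValueError):
        CleavageRuleSet(enzyme="x", p1_prime_targets=frozenset())


def test_unknown_residues_in_rules_rejected():
    with pytest.raises(ValueError):
        CleavageRuleSet(enzyme="x", p1_prime_targets=frozenset("AXB"))
    with pytest.raises(ValueError):
        BlockingRule(position="P9", residues=frozenset("A"))


def test_rules_round_trip(tmp_path, thermolysin):
    path = tmp_path / "rules.json"
    save_rules(thermolysin, path)
    back = load_rules(path)
    assert back == thermolysin


def test_no_targets_no_cuts(thermolysin):
    assert cut_sites("GGGG", thermolysin) == []


def test_single_cut_before_target():
    rules = CleavageRuleSet(enzyme="t", p1_prime_targets=frozenset("V"))
    assert cut_sites("GVGG", rules) == [1]


def test_blocking_rules_veto_cuts(thermolysin):
    # P1 acidic vetoes: E|F bond is not cut
    assert cut_sites("GEFG", thermolysin) == []
    # P2' proline vetoes: G|V-P context
    assert cut_sites("GGVP", thermolysin) == []
    # same bonds cut without the blocking context
    assert cut_sites("GSFG", thermolysin) == [2]
    assert cut_sites("GGVG", thermolysin) == [2]


def test_cut_sites_match_exhaustive_predicate_evaluation():
    """60-residue sequence under a 2-rule set vs per-bond evaluation."""
    rules = CleavageRuleSet(
        enzyme="toy",
        p1_prime_targets=frozenset("LV"),
        blocking_rules=(
            BlockingRule(position="P1", residues=frozenset("DE")),
            BlockingRule(position="P2prime", residues=frozenset("P")),
        ),
    )
    seq = gen_proteins(
        SyntheticConfig(seed=60, n_proteins=1, min_length=60, max_length=60)
    )[0].sequence

    expected = []
    for bond in range(1, len(seq)):
        p1, p1p = seq[bond - 1], seq[bond]
        p2p = seq[bond + 1] if bond + 1 < len(seq) else None
        if p1p in "LV" and p1 not in "DE" and p2p != "P":
            expected.append(bond)
    assert cut_sites(seq, rules) == expected


def test_adding_blocking_rule_never_adds_cuts():
    base = CleavageRuleSet(enzyme="t", p1_prime_targets=frozenset("AFILMV"))
    stricter = CleavageRuleSet(
        enzyme="t",
        p1_prime_targets=frozenset("AFILMV"),
        blocking_rules=(BlockingRule(position="P1", residues=frozenset("DE")),),
    )
    for seed in range(5):
        seq = gen_proteins(
            SyntheticConfig(seed=seed, n_proteins=1, min_length=40, max_length=80)
        )[0].sequence
        assert set(cut_sites(seq, stricter)) <= set(cut_sites(seq, base))


def test_digest_no_cuts_whole_sequence(thermolysin):
    result = digest("GGGGGG", thermolysin)
    assert result.fragments == ((1, 6, "GGGGGG"),)


def test_digest_partition_arithmetic():
    # targets {V}: cuts exactly at bonds 2 and 5 of the 7-mer
    rules = CleavageRuleSet(enzyme="t", p1_prime_targets=frozenset("V"))
    result = digest("GGVGGVG", rules)
    assert result.cut_bonds == (2, 5)
    assert result.fragments == ((1, 2, "GG"), (3, 5, "VGG"), (6, 7, "VG"))


def test_digest_fragments_reconcatenate(thermolysin):
    proteins = gen_proteins(
        SyntheticConfig(seed=123, n_proteins=100, min_length=30, max_length=120)
    )
    for prot in proteins:
        result = digest(prot.sequence, thermolysin)
        assert "".join(f[2] for f in result.fragments) == prot.sequence
        # boundaries coincide with cut bonds plus the termini
        ends = tuple(f[1] for f in result.fragments[:-1])
        assert ends == result.cut_bonds


def test_release_of_uncut_whole_protein(thermolysin):
    ok, reason = is_released_intact("GGGGGG", 1, 6, thermolysin)
    assert ok and reason == "released intact"


def test_release_fails_on_internal_cleavage():
    rules = CleavageRuleSet(enzyme="t", p1_prime_targets=frozenset("V"))
    ok, reason = is_released_intact("GGVGGG", 1, 6, rules)
    assert not ok and reason == "internal cleavage"


def test_release_out_of_range_span(thermolysin):
    with pytest.raises(ValueError):
        is_released_intact("GGGG", 2, 5, thermolysin)


def test_digest_fragments_are_released_and_spans_match_brute_force(thermolysin):
    seq = gen_proteins(
        SyntheticConfig(seed=9, n_proteins=1, min_length=40, max_length=40)
    )[0].sequence
    result = digest(seq, thermolysin)
    fragment_spans = {(s, e) for s, e, _ in result.fragments}
    for s, e, _ in result.fragments:
        ok, _ = is_released_intact(seq, s, e, thermolysin)
        assert ok

    # exhaustive span scan: a span is releasable iff it is a fragment
    sites = set(result.cut_bonds)
    for start in range(1, len(seq) + 1):
        for end in range(start, len(seq) + 1):
            ok, _ = is_released_intact(seq, start, end, thermolysin)
            expected = (
                (start == 1 or start - 1 in sites)
                and (end == len(seq) or end in sites)
                and not any(start <= b < end for b in sites)
            )
            assert ok == expected
            if ok:
                assert (start, end) in fragment_spans


# Fixture mirroring the candidate-rescue analysis: a 6-mer flanked by a cut
# on the N side only; its internal F is protected by an acidic P1, and one
# C-terminal serine reaches the next cut site, making the 7-mer releasable.
_PARENT = "GGVEEFYCSVGG"


def test_minimal_superpeptide_extends_one_residue(thermolysin):
    assert cut_sites(_PARENT, thermolysin) == [2, 9]
    ok, reason = is_released_intact(_PARENT, 3, 8, thermolysin)  # VEEFYC
    assert not ok and reason == "no cleavage at C-terminal flank"
    span = minimal_releasable_superpeptide(_PARENT, 3, 8, thermolysin, max_extension=2)
    assert span == (3, 9)
    assert _PARENT[span[0] - 1 : span[1]] == "VEEFYCS"

    # exhaustive enumeration confirms no shorter qualifying span exists
    qualifying = [
        (s, e)
        for s in range(1, len(_PARENT) + 1)
        for e in range(s, len(_PARENT) + 1)
        if s <= 3 and e >= 8 and (3 - s) + (e - 8) <= 2
        and is_released_intact(_PARENT, s, e, thermolysin)[0]
    ]
    assert min(qualifying, key=lambda se: (se[1] - se[0], se[0])) == (3, 9)


def test_minimal_superpeptide_identity_when_already_releasable(thermolysin):
    span = minimal_releasable_superpeptide(_PARENT, 3, 9, thermolysin, max_extension=2)
    assert span == (3, 9)


def test_minimal_superpeptide_none_without_extension(thermolysin):
    assert (
        minimal_releasable_superpeptide(_PARENT, 3, 8, thermolysin, max_extension=0)
        is None
    )


def test_yield_arithmetic():
    """Purification yield per gram of nuts: 0.216 g protein of which 15.7%
    is the 460-residue parent, carrying a 7-residue peptide."""
    protein_mg, peptide_mg = yield_estimate(0.216, 0.157, 7, 460)
    assert round(protein_mg, 1) == 33.9
    assert round(peptide_mg, 2) == 0.52


def test_yield_identity_bound():
    protein_mg, peptide_mg = yield_estimate(0.5, 1.0, 100, 100)
    assert peptide_mg == protein_mg == 500.0


def test_yield_rejects_bad_arguments():
    with pytest.raises(ValueError):
        yield_estimate(-1.0, 0.5, 7, 460)
    with pytest.raises(ValueError):
        yield_estimate(0.2, 1.5, 7, 460)
    with pytest.raises(ValueError):
        yield_estimate(0.2, 0.5, 500, 460)
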