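"""CPM normalization, Fisher exact test and the enrichment screen."""

import math

import numpy as np
import pytest

from endosirna.diffexpr import cpm, exact_enrichment_test, select_enriched
from endosirna.preprocess import SmallRNATag


def hypergeom_two_sided(a, ta, b, tb):
    """Brute-force two-sided Fisher p: sum hypergeometric probabilities
    not exceeding the observed table's, over all tables with the same
    margins. Exact integer arithmetic via math.comb."""
    k = a + b
    n = ta + tb
    denom = math.comb(n, k)

    def pmf(x):
        if x < 0 or x > ta or k - x > tb or k - x < 0:
            return 0.0
        return math.comb(ta, x) * math.comb(tb, k - x) / denom

    p_obs = pmf(a)
    return sum(p for x in range(0, k + 1) if (p := pmf(x)) <= p_obs * (1 + 1e-9))


def test_cpm_definition_and_pseudocount():
    # pseudocount of 0.5 on a count of 100 perturbs the value by ~0.5%
    assert cpm(100, 10**6) == pytest.approx(100.0, rel=6e-3)
    assert cpm(100, 10**6) == (100 + 0.5) / (10**6 + 0.5) * 1e6
    assert cpm(0, 1000) > 0  # pseudocount keeps folds finite
    # scale invariance up to the pseudocount perturbation
    assert cpm(200, 2 * 10**6) == pytest.approx(cpm(100, 10**6), rel=6e-3)
    with pytest.raises(ValueError):
        cpm(1, 0)


def test_fisher_identical_proportions_is_one():
    assert exact_enrichment_test(10, 1000, 10, 1000) == pytest.approx(1.0)


def test_fisher_row_swap_symmetry():
    p1 = exact_enrichment_test(10, 1000, 0, 1000)
    p2 = exact_enrichment_test(0, 1000, 10, 1000)
    assert p1 == pytest.approx(p2, abs=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_fisher_matches_hypergeometric_oracle(seed):
    """Two-sided Fisher p equals exhaustive hypergeometric summation to
    1e-10 for totals up to 2000."""
    rng = np.random.default_rng(seed)
    cases = [(10, 990, 0, 1000), (5, 95, 20, 80), (0, 50, 0, 50)]
    for _ in range(20):
        ta = int(rng.integers(10, 2001))
        tb = int(rng.integers(10, 2001))
        a = int(rng.integers(0, min(ta, 40)))
        b = int(rng.integers(0, min(tb, 40)))
        cases.append((a, ta - a, b, tb - b))
    for a, rest_a, b, rest_b in cases:
        ta, tb = a + rest_a, b + rest_b
        p = exact_enrichment_test(a, ta, b, tb)
        assert p == pytest.approx(hypergeom_two_sided(a, ta, b, tb), abs=1e-10)


def test_fold_antisymmetry():
    for ca, cb, ta, tb in ((10, 3, 1000, 900), (0, 7, 500, 600)):
        f_ab = cpm(ca, ta) / cpm(cb, tb)
        f_ba = cpm(cb, tb) / cpm(ca, ta)
        assert f_ab == pytest.approx(1.0 / f_ba, rel=1e-12)


def test_select_enriched_requires_all_comparators():
    tags = [
        SmallRNATag("ACGTACGTACGTACGTACGTAC", {"z": 200, "s": 2, "o": 2}),
        SmallRNATag("TTTTGGGGCCCCAAAATTTTGG", {"z": 200, "s": 2, "o": 180}),
        SmallRNATag("AACCGGTTAACCGGTTAACCGG", {"z": 0, "s": 50, "o": 50}),
    ]
    totals = {"z": 10000, "s": 10000, "o": 10000}
    selected, results = select_enriched(tags, totals, "z", ["s", "o"])
    assert selected == [tags[0].tag_id]
    # the tag high in one comparator fails the conjunction
    assert tags[1].tag_id not in selected
    # absent from the focal library: fold < 1, never selected
    assert tags[2].tag_id not in selected
    assert all(0 <= r.p_value <= 1 and r.fold > 0 for r in results)


def test_thresholds_are_strict():
    """A tag at exactly the fold or p threshold is never selected."""
    tag = SmallRNATag("ACGTACGTACGTACGTACGTAC", {"z": 60, "s": 5})
    totals = {"z": 10000, "s": 10000}
    fold = cpm(60, 10000) / cpm(5, 10000)
    p = exact_enrichment_test(60, 10000, 5, 10000)
    sel_at, _ = select_enriched([tag], totals, "z", ["s"], fold_threshold=fold)
    assert sel_at == []
    sel_below, _ = select_enriched(
        [tag], totals, "z", ["s"], fold_threshold=fold * 0.999
    )
    assert sel_below == [tag.tag_id]
    sel_p, _ = select_enriched(
        [tag], totals, "z", ["s"], p_threshold=p
    )
    assert sel_p == []
    sel_p2, _ = select_enriched(
        [tag], totals, "z", ["s"], p_threshold=min(1.0, p * 1.001)
    )
    assert sel_p2 == [tag.tag_id]


def test_null_simulation_type_one_control():
    """With no planted enrichment at depth 1e5, the fraction of tags
    passing p < 0.01 per comparison stays at or below 0.02."""
    rng = np.random.default_rng(77)
    n_tags, depth = 400, 100_000
    props = rng.dirichlet(np.ones(n_tags))
    counts_a = rng.multinomial(depth, props)
    counts_b = rng.multinomial(depth, props)
    rejected = sum(
        exact_enrichment_test(int(a), depth, int(b), depth) < 0.01
        for a, b in zip(counts_a, counts_b)
    )
    assert rejected / n_tags <= 0.02


def test_bh_flag_only_shrinks_selection():
    rng = np.random.default_rng(3)
    tags = [
        SmallRNATag("ACGTACGTACGTACGTAC" + "ACGT"[i] * 2,
                    {"z": int(rng.integers(0, 200)), "s": int(rng.integers(0, 200))})
        for i in range(4)
    ]
    totals = {"z": 5000, "s": 5000}
    raw, _ = select_enriched(tags, totals, "z", ["s"])
    adj, _ = select_enriched(tags, totals, "z", ["s"], bh_correct=True)
    assert set(adj) <= set(raw)
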