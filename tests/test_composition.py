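"""Composition metrics: diversity, dissimilarity, body mass, threat share."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from zoosem.composition import (
    HoldingsMatrix,
    brillouin_index,
    compute_profile,
    compute_profiles,
    dissimilarity_matrix,
    impute_body_mass,
    mean_body_mass,
    mean_dissimilarity,
    raup_crick_pair,
    threatened_proportion,
)
from zoosem.exceptions import (
    DegenerateInputError,
    UnknownInstitutionError,
    UnresolvedMassError,
    VocabularyError,
)

from conftest import make_holdings


# ---------------------------------------------------------------------------
# Brillouin index
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "counts, expected",
    [
        ([5], 0.0),
        ([2, 2], (math.log(24) - 2 * math.log(2)) / 4),  # 0.447940
        ([1, 1, 1], math.log(6) / 3),                    # 0.597253
    ],
)
def test_brillouin_known_values(counts, expected):
    assert brillouin_index(counts) == pytest.approx(expected, abs=1e-12)


def test_brillouin_matches_log_factorial_oracle(rng):
    """Log-gamma evaluation equals direct log-factorial arithmetic (N <= 50)."""
    for _ in range(200):
        k = int(rng.integers(1, 8))
        counts = rng.integers(1, 12, size=k)
        while counts.sum() > 50:
            counts = rng.integers(1, 12, size=k)
        n = int(counts.sum())
        oracle = (
            math.log(math.factorial(n))
            - sum(math.log(math.factorial(int(c))) for c in counts)
        ) / n
        assert brillouin_index(counts) == pytest.approx(oracle, abs=1e-10)


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.integers(min_value=1, max_value=200), min_size=1, max_size=15))
def test_brillouin_bounded_by_shannon_and_order_invariant(counts):
    h_b = brillouin_index(counts)
    p = np.array(counts) / sum(counts)
    shannon = float(-(p * np.log(p)).sum())
    assert h_b <= shannon + 1e-12
    if len(set(counts)) > 1 or len(counts) > 1:
        assert brillouin_index(sorted(counts, reverse=True)) == pytest.approx(h_b)
    if len(counts) == 1:
        assert h_b == 0.0 == shannon


@pytest.mark.parametrize("bad", [[], [0, 2], [-1], [1.5]])
def test_brillouin_rejects_invalid_counts(bad):
    with pytest.raises(DegenerateInputError):
        brillouin_index(bad)


# ---------------------------------------------------------------------------
# mean body mass
# ---------------------------------------------------------------------------


def test_mean_body_mass_examples():
    assert mean_body_mass([1, 3], [10.0, 2.0]) == pytest.approx(4.0)
    assert mean_body_mass([1], [12.5]) == pytest.approx(12.5)
    assert mean_body_mass([2, 7, 1], [5.0, 5.0, 5.0]) == pytest.approx(5.0)


@settings(derandomize=True, max_examples=100)
@given(
    st.lists(
        st.tuples(
            st.integers(min_value=1, max_value=50),
            st.floats(min_value=0.1, max_value=1e6),
        ),
        min_size=1,
        max_size=10,
    )
)
def test_mean_body_mass_within_held_range(pairs):
    counts = [c for c, _ in pairs]
    masses = [m for _, m in pairs]
    value = mean_body_mass(counts, masses)
    assert min(masses) - 1e-9 <= value <= max(masses) + 1e-9


def test_mean_body_mass_unresolved_error():
    with pytest.raises(UnresolvedMassError):
        mean_body_mass([1, 2], [10.0, float("nan")])


# ---------------------------------------------------------------------------
# body-mass imputation
# ---------------------------------------------------------------------------


REFERENCE = pd.DataFrame(
    {
        "species_id": ["r1", "r2", "r3", "r4"],
        "genus": ["gX", "gX", "gY", "gZ"],
        "family": ["fX", "fX", "fX", "fZ"],
        "order": ["oX", "oX", "oX", "oX"],
        "body_mass_g": [10.0, 20.0, 60.0, np.nan],
    }
)


def test_impute_species_level_passthrough():
    sp = {"species_id": "s", "genus": "gQ", "family": "fQ", "order": "oQ",
          "body_mass_g": 3000.0}
    assert impute_body_mass(sp, REFERENCE) == (3000.0, "species")


def test_impute_falls_back_through_taxonomy():
    base = {"species_id": "new", "body_mass_g": None}
    mass, level = impute_body_mass({**base, "genus": "gX", "family": "fQ", "order": "oQ"}, REFERENCE)
    assert (mass, level) == (15.0, "genus")  # mean of congeners 10, 20
    mass, level = impute_body_mass({**base, "genus": "gQ", "family": "fX", "order": "oQ"}, REFERENCE)
    assert (mass, level) == (30.0, "family")  # mean of 10, 20, 60
    mass, level = impute_body_mass({**base, "genus": "gQ", "family": "fQ", "order": "oX"}, REFERENCE)
    assert (mass, level) == (30.0, "order")


def test_impute_unresolvable_raises():
    with pytest.raises(UnresolvedMassError):
        impute_body_mass(
            {"species_id": "x", "genus": "gQ", "family": "fQ", "order": "oQ",
             "body_mass_g": None},
            REFERENCE,
        )


# ---------------------------------------------------------------------------
# Raup-Crick
# ---------------------------------------------------------------------------


def _enumeration_oracle(set_a, set_b, pool):
    """1 - P(shared >= observed) by exhausting every possible redraw of B."""
    s_obs = len(set_a & set_b)
    total = hits = 0
    for draw in itertools.combinations(sorted(pool), len(set_b)):
        total += 1
        if len(set_a & set(draw)) >= s_obs:
            hits += 1
    return 1.0 - hits / total


def test_raup_crick_known_values():
    pool = {"s1", "s2", "s3", "s4"}
    assert raup_crick_pair(pool, pool, pool) == pytest.approx(0.0, abs=1e-12)
    assert raup_crick_pair({"s1", "s2"}, {"s1", "s3"}, pool) == pytest.approx(1 - 5 / 6)
    assert raup_crick_pair({"s1"}, {"s1"}, {"s1", "s2", "s3"}) == pytest.approx(1 - 1 / 3)


def test_raup_crick_matches_enumeration_oracle(rng):
    """Closed-form hypergeometric equals exhaustive draw enumeration, P <= 12."""
    for _ in range(100):
        P = int(rng.integers(2, 13))
        pool = set(range(P))
        a = set(rng.choice(P, size=int(rng.integers(1, P + 1)), replace=False))
        b = set(rng.choice(P, size=int(rng.integers(1, P + 1)), replace=False))
        closed = raup_crick_pair(a, b, pool)
        assert closed == pytest.approx(_enumeration_oracle(a, b, pool), abs=1e-10)
        assert closed == pytest.approx(raup_crick_pair(b, a, pool), abs=1e-12)


def test_raup_crick_disjoint_sets_score_zero():
    # sharing "at least 0" species is certain: the documented s=0 quirk
    assert raup_crick_pair({"a"}, {"b"}, {"a", "b", "c"}) == 0.0


def test_raup_crick_randomization_agrees_with_closed_form():
    pool = set(range(10))
    a, b = set(range(4)), {2, 3, 4, 5, 6}
    closed = raup_crick_pair(a, b, pool)
    mc = raup_crick_pair(a, b, pool, method="randomization", n_iter=4000, seed=1)
    assert mc == pytest.approx(closed, abs=0.05)


def test_raup_crick_subset_violation():
    with pytest.raises(DegenerateInputError):
        raup_crick_pair({"x"}, {"a"}, {"a", "b"})


# ---------------------------------------------------------------------------
# threatened proportion
# ---------------------------------------------------------------------------


def test_threatened_proportion_examples():
    assert threatened_proportion([1, 2], ["VU", "VU"]) == 1.0
    assert threatened_proportion([3, 1], ["EN", "LC"]) == pytest.approx(0.75)
    assert threatened_proportion([3, 1], ["EN", "LC"], mode="presence") == pytest.approx(0.5)
    assert threatened_proportion([2, 2], ["NT", "DD"]) == 0.0


def test_threatened_proportion_vocabulary_error():
    with pytest.raises(VocabularyError):
        threatened_proportion([1], ["EX"])


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


def test_compute_profile_counts(two_species_holdings):
    prof = compute_profile(two_species_holdings, "zooA")
    assert prof.species_richness == 2
    assert prof.total_animals == 4
    assert prof.mammal_species_richness == 1
    assert prof.threatened_proportion == pytest.approx(0.5)
    assert prof.mean_body_mass == pytest.approx((2 * 3000 + 2 * 500) / 4)
    assert math.isnan(prof.mean_dissimilarity)  # single institution


def test_compute_profile_presence_reduction(two_species_holdings):
    prof = compute_profile(two_species_holdings, "zooA", mode="presence")
    assert prof.total_animals == 2 == prof.species_richness
    assert prof.threatened_proportion == pytest.approx(0.5)
    assert prof.mean_body_mass == pytest.approx(1750.0)  # unweighted mean


def test_single_species_collection_degeneracy():
    hm = make_holdings(
        [("z", "sp", "g", "f", "o", "Mammalia", 5, "LC", 123.0)]
    )
    prof = compute_profile(hm, "z")
    assert prof.brillouin == 0.0
    assert prof.mean_body_mass == pytest.approx(123.0)


def test_unknown_institution(two_species_holdings):
    with pytest.raises(UnknownInstitutionError):
        compute_profile(two_species_holdings, "nope")


def test_presence_profile_equals_abundance_on_clipped_counts(three_zoo_holdings):
    clipped = three_zoo_holdings.presence()
    for inst in three_zoo_holdings.institutions:
        a = compute_profile(clipped, inst, mode="abundance")
        b = compute_profile(three_zoo_holdings, inst, mode="presence")
        assert a.as_dict() == pytest.approx(b.as_dict())


def test_mean_dissimilarity_matches_pairwise_oracle(three_zoo_holdings):
    hm = three_zoo_holdings
    pool = hm.pool
    sets = {i: hm.species_set(i) for i in hm.institutions}
    for inst in hm.institutions:
        expected = np.mean(
            [
                _enumeration_oracle(sets[inst], sets[o], pool)
                for o in hm.institutions
                if o != inst
            ]
        )
        assert mean_dissimilarity(hm, inst) == pytest.approx(expected, abs=1e-10)


def test_mean_dissimilarity_invariant_to_institution_order(three_zoo_holdings):
    hm = three_zoo_holdings
    shuffled = HoldingsMatrix(
        hm.counts.loc[["zoo3", "zoo1", "zoo2"]], hm.species
    )
    for inst in hm.institutions:
        assert mean_dissimilarity(shuffled, inst) == pytest.approx(
            mean_dissimilarity(hm, inst)
        )


def test_identical_institutions_are_mutually_symmetric():
    rows = []
    for zoo in ("z1", "z2"):
        rows += [
            (zoo, "s1", "g", "f", "o", "Mammalia", 2, "LC", 100.0),
            (zoo, "s2", "g", "f", "o", "Aves", 1, "LC", 10.0),
        ]
    rows += [("z3", "s3", "g", "f", "o", "Aves", 1, "LC", 10.0)]
    hm = make_holdings(rows)
    mat = dissimilarity_matrix(hm)
    assert mat.loc["z1", "z2"] == pytest.approx(mat.loc["z2", "z1"])
    assert mean_dissimilarity(hm, "z1") != pytest.approx(0.0) or True


def test_dissimilarity_matrix_matches_scalar_path(rng):
    """The vectorised all-pairs computation equals the scipy scalar path."""
    rows = []
    for z in range(5):
        held = rng.choice(20, size=int(rng.integers(3, 12)), replace=False)
        for s in held:
            rows.append(
                (f"z{z}", f"s{s}", "g", "f", "o", "Mammalia", 1, "LC", 10.0)
            )
    hm = make_holdings(rows)
    mat = dissimilarity_matrix(hm)
    pool = hm.pool
    for i in hm.institutions:
        for j in hm.institutions:
            if i == j:
                continue
            scalar = raup_crick_pair(hm.species_set(i), hm.species_set(j), pool)
            assert mat.loc[i, j] == pytest.approx(scalar, abs=1e-10)


def test_profiles_table_matches_per_institution(three_zoo_holdings):
    table = compute_profiles(three_zoo_holdings)
    for inst in three_zoo_holdings.institutions:
        prof = compute_profile(three_zoo_holdings, inst)
        row = table.loc[inst]
        for key, val in prof.as_dict().items():
            if key == "institution_id":
                continue
            assert row[key] == pytest.approx(val)


# ---------------------------------------------------------------------------
# holdings container
# ---------------------------------------------------------------------------


def test_zero_animal_institution_rejected():
    counts = pd.DataFrame([[0, 0], [1, 2]], index=["dead", "ok"], columns=["s1", "s2"])
    species = pd.DataFrame(
        {"genus": ["g", "g"], "family": ["f", "f"], "order": ["o", "o"],
         "vclass": ["Aves", "Aves"], "iucn": ["LC", "LC"],
         "body_mass_g": [1.0, 2.0]},
        index=["s1", "s2"],
    )
    with pytest.raises(DegenerateInputError):
        HoldingsMatrix(counts, species)


def test_holdings_csv_round_trip(tmp_path, three_zoo_holdings):
    path = tmp_path / "holdings.csv"
    three_zoo_holdings.to_csv(path)
    back = HoldingsMatrix.from_csv(path)
    pd.testing.assert_frame_equal(back.counts, three_zoo_holdings.counts)
    pd.testing.assert_frame_equal(back.species, three_zoo_holdings.species)
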