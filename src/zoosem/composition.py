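"""Per-institution collection-composition metrics.

Given a table of vertebrate holdings (which institution holds how many
individuals of which species, with taxonomy, IUCN Red List category and body
mass attached), this module derives the variables used by the attendance and
in situ path models:

* species richness, total animals, mammal species richness;
* the abundance-weighted proportion of threatened (CR/EN/VU) species;
* the abundance-weighted mean species body mass
  ``M̄ = Σ x_i m_i / Σ x_i`` (x_i individuals, m_i grams);
* the Brillouin diversity index ``(ln N! − Σ ln n_i!)/N`` — the natural
  alpha-diversity measure for a fully censused collection;
* the mean Raup–Crick dissimilarity between the focal institution and every
  other institution, under the hypergeometric null model.

Every metric has an abundance mode and a presence–absence mode (all positive
counts treated as one individual).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import hypergeom

from .exceptions import (
    DegenerateInputError,
    UnknownInstitutionError,
    UnresolvedMassError,
    VocabularyError,
)

VERTEBRATE_CLASSES = frozenset({"Mammalia", "Aves", "Reptilia", "Amphibia"})
IUCN_CATEGORIES = frozenset({"CR", "EN", "VU", "NT", "LC", "DD", "NE"})
THREATENED = frozenset({"CR", "EN", "VU"})

Mode = Literal["abundance", "presence"]

#: Columns required in a long-format holdings CSV.
HOLDINGS_COLUMNS = (
    "institution_id",
    "species_id",
    "genus",
    "family",
    "order",
    "vclass",
    "count",
    "iucn",
    "body_mass_g",
)

SPECIES_COLUMNS = ("genus", "family", "order", "vclass", "iucn", "body_mass_g")


def _check_mode(mode: str) -> None:
    if mode not in ("abundance", "presence"):
        raise ValueError(f"mode must be 'abundance' or 'presence', got {mode!r}")


@dataclass(frozen=True)
class SpeciesAttributes:
    """Static attributes of one species."""

    species_id: str
    genus: str
    family: str
    order: str
    vclass: str
    iucn: str
    body_mass_g: float | None = None

    def __post_init__(self) -> None:
        if self.vclass not in VERTEBRATE_CLASSES:
            raise VocabularyError(
                f"unknown vertebrate class {self.vclass!r} for {self.species_id}"
            )
        if self.iucn not in IUCN_CATEGORIES:
            raise VocabularyError(
                f"unknown IUCN category {self.iucn!r} for {self.species_id}"
            )
        if self.body_mass_g is not None and not self.body_mass_g > 0:
            raise ValueError(f"body_mass_g must be > 0, got {self.body_mass_g}")


class HoldingsMatrix:
    """Institutions × species individual counts with species attributes.

    Parameters
    ----------
    counts
        Wide table, rows = institution ids, columns = species ids, cells =
        non-negative integer individual counts.
    species
        Species attribute table indexed by species id with columns
        ``genus, family, order, vclass, iucn, body_mass_g`` (mass may be NaN
        before imputation). Must cover every column of ``counts``.
    """

    def __init__(self, counts: pd.DataFrame, species: pd.DataFrame):
        counts = counts.astype(np.int64, copy=True)
        if (counts.to_numpy() < 0).any():
            raise ValueError("holdings counts must be non-negative")
        empty = counts.sum(axis=1) == 0
        if empty.any():
            bad = list(counts.index[empty])
            raise DegenerateInputError(
                f"institutions with zero animals are not allowed: {bad}"
            )
        missing = set(counts.columns) - set(species.index)
        if missing:
            raise ValueError(f"species without attributes: {sorted(missing)}")
        species = species.loc[list(counts.columns)]
        counts.index.name = "institution_id"
        counts.columns.name = "species_id"
        species.index.name = "species_id"
        bad_class = set(species["vclass"]) - VERTEBRATE_CLASSES
        if bad_class:
            raise VocabularyError(f"unknown vertebrate classes: {sorted(bad_class)}")
        bad_iucn = set(species["iucn"]) - IUCN_CATEGORIES
        if bad_iucn:
            raise VocabularyError(f"unknown IUCN categories: {sorted(bad_iucn)}")
        self.counts = counts
        self.species = species

    # -- construction ------------------------------------------------------

    @classmethod
    def from_long(cls, table: pd.DataFrame) -> "HoldingsMatrix":
        """Build from a long-format table with :data:`HOLDINGS_COLUMNS`."""
        missing = set(HOLDINGS_COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"holdings table missing columns: {sorted(missing)}")
        counts = (
            table.pivot_table(
                index="institution_id",
                columns="species_id",
                values="count",
                aggfunc="sum",
                fill_value=0,
            )
            .sort_index()
            .sort_index(axis=1)
        )
        species = (
            table.drop_duplicates("species_id")
            .set_index("species_id")[list(SPECIES_COLUMNS)]
            .sort_index()
        )
        species["body_mass_g"] = pd.to_numeric(species["body_mass_g"], errors="coerce")
        return cls(counts, species)

    @classmethod
    def from_csv(cls, path) -> "HoldingsMatrix":
        return cls.from_long(pd.read_csv(path))

    def to_long(self) -> pd.DataFrame:
        long = (
            self.counts.stack()
            .rename("count")
            .reset_index()
            .rename(columns={"level_0": "institution_id", "level_1": "species_id"})
        )
        long.columns = ["institution_id", "species_id", "count"]
        long = long[long["count"] > 0]
        long = long.merge(
            self.species.reset_index().rename(columns={"index": "species_id"}),
            on="species_id",
        )
        return long[list(HOLDINGS_COLUMNS)].sort_values(
            ["institution_id", "species_id"], ignore_index=True
        )

    def to_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)

    # -- views -------------------------------------------------------------

    @property
    def institutions(self) -> list[str]:
        return list(self.counts.index)

    @property
    def pool(self) -> frozenset:
        """Union of species held by at least one institution."""
        present = self.counts.sum(axis=0) > 0
        return frozenset(self.counts.columns[present])

    def row(self, institution) -> pd.Series:
        if institution not in self.counts.index:
            raise UnknownInstitutionError(institution)
        return self.counts.loc[institution]

    def species_set(self, institution) -> frozenset:
        row = self.row(institution)
        return frozenset(row.index[row > 0])

    def presence(self) -> "HoldingsMatrix":
        """Copy with every positive count reduced to one individual."""
        return HoldingsMatrix(self.counts.clip(upper=1), self.species)


@dataclass(frozen=True)
class CompositionProfile:
    """The derived composition variables for one institution."""

    institution_id: str
    species_richness: int
    total_animals: int
    mammal_species_richness: int
    threatened_proportion: float
    mean_body_mass: float
    brillouin: float
    mean_dissimilarity: float  # NaN for a single-institution dataset
    mode: str = "abundance"

    def as_dict(self) -> dict:
        return {
            "institution_id": self.institution_id,
            "species_richness": self.species_richness,
            "total_animals": self.total_animals,
            "mammal_species_richness": self.mammal_species_richness,
            "threatened_proportion": self.threatened_proportion,
            "mean_body_mass": self.mean_body_mass,
            "brillouin": self.brillouin,
            "mean_dissimilarity": self.mean_dissimilarity,
        }


# ---------------------------------------------------------------------------
# elementary metrics
# ---------------------------------------------------------------------------


def brillouin_index(counts: Iterable[int]) -> float:
    """Brillouin diversity ``H_B = (ln N! − Σ ln n_i!)/N`` via log-gamma.

    Appropriate for a fully censused community (a zoo inventory is a census,
    not a sample), and bounded above by the Shannon index of the same counts.
    """
    n = np.asarray(list(counts), dtype=float)
    if n.size == 0:
        raise DegenerateInputError("brillouin_index requires at least one count")
    if (n < 1).any() or not np.allclose(n, np.round(n)):
        raise DegenerateInputError("brillouin_index counts must be integers >= 1")
    total = n.sum()
    return float((gammaln(total + 1.0) - gammaln(n + 1.0).sum()) / total)


def mean_body_mass(counts: Iterable[float], masses: Iterable[float]) -> float:
    """Abundance-weighted mean species body mass ``Σ x_i m_i / Σ x_i`` (grams)."""
    x = np.asarray(list(counts), dtype=float)
    m = np.asarray(list(masses), dtype=float)
    if x.shape != m.shape:
        raise ValueError("counts and masses must be aligned")
    if x.size == 0 or x.sum() <= 0:
        raise DegenerateInputError("mean_body_mass requires positive total abundance")
    if np.isnan(m[x > 0]).any():
        bad = [i for i, (xi, mi) in enumerate(zip(x, m)) if xi > 0 and math.isnan(mi)]
        raise UnresolvedMassError(f"unresolved body mass at positions {bad}")
    return float(np.dot(x, np.nan_to_num(m)) / x.sum())


def impute_body_mass(
    species: SpeciesAttributes | Mapping,
    reference: pd.DataFrame,
) -> tuple[float, str]:
    """Resolve a species body mass, falling back up the taxonomy.

    The species' own mass is used when present; otherwise the arithmetic mean
    of reference masses sharing its genus, then family, then order (first
    non-empty level wins). Returns ``(mass_g, level)`` where level is one of
    ``species``, ``genus``, ``family``, ``order``.

    ``reference`` needs columns ``genus, family, order, body_mass_g`` and a
    species-id index (or a ``species_id`` column).
    """
    if isinstance(species, SpeciesAttributes):
        rec = {
            "species_id": species.species_id,
            "genus": species.genus,
            "family": species.family,
            "order": species.order,
            "body_mass_g": species.body_mass_g,
        }
    else:
        rec = dict(species)
    own = rec.get("body_mass_g")
    if own is not None and not (isinstance(own, float) and math.isnan(own)):
        return float(own), "species"

    ref = reference.reset_index() if "species_id" not in reference.columns else reference
    masses = pd.to_numeric(ref["body_mass_g"], errors="coerce")
    sid = rec.get("species_id")
    if sid is not None:
        hit = masses[(ref["species_id"] == sid) & masses.notna()]
        if len(hit):
            return float(hit.mean()), "species"
    for level in ("genus", "family", "order"):
        key = rec.get(level)
        if key is None:
            continue
        hit = masses[(ref[level] == key) & masses.notna()]
        if len(hit):
            return float(hit.mean()), level
    raise UnresolvedMassError(
        f"no body mass for {rec.get('species_id')!r} at species, genus, family or order level"
    )


def resolve_masses(holdings: HoldingsMatrix, reference: pd.DataFrame | None = None) -> pd.Series:
    """Species-id → grams for every species, imputing from ``reference`` where
    the holdings table itself has no mass. Raises when any species stays
    unresolved. When no reference is given the holdings' own attribute table
    doubles as the reference (congeners inside the dataset fill the gaps)."""
    ref = reference if reference is not None else holdings.species.reset_index()
    out = {}
    for sid, row in holdings.species.iterrows():
        rec = {"species_id": sid, **row.to_dict()}
        mass, _level = impute_body_mass(rec, ref)
        out[sid] = mass
    return pd.Series(out, name="body_mass_g")


def threatened_proportion(
    counts: Iterable[float],
    iucn: Iterable[str],
    mode: Mode = "abundance",
) -> float:
    """Share of the collection in IUCN threatened categories (CR/EN/VU).

    Abundance mode weights by individuals; presence mode is the fraction of
    species. NT/LC/DD/NE all count as non-threatened.
    """
    _check_mode(mode)
    x = np.asarray(list(counts), dtype=float)
    cats = list(iucn)
    if len(cats) != x.size:
        raise ValueError("counts and iucn must be aligned")
    bad = set(cats) - IUCN_CATEGORIES
    if bad:
        raise VocabularyError(f"unknown IUCN categories: {sorted(bad)}")
    if mode == "presence":
        x = (x > 0).astype(float)
    if x.sum() <= 0:
        raise DegenerateInputError("threatened_proportion requires positive abundance")
    flag = np.array([c in THREATENED for c in cats], dtype=float)
    return float(np.dot(x, flag) / x.sum())


# ---------------------------------------------------------------------------
# Raup–Crick dissimilarity
# ---------------------------------------------------------------------------


def raup_crick_pair(
    set_a: Iterable,
    set_b: Iterable,
    pool: Iterable,
    *,
    method: Literal["hypergeometric", "randomization"] = "hypergeometric",
    n_iter: int = 9999,
    seed: int | None = None,
) -> float:
    """Raup–Crick dissimilarity between two presence sets.

    With ``a = |A|``, ``b = |B|``, ``s = |A ∩ B|`` and pool size ``P``, the
    index is one minus the probability of sharing *at least* ``s`` species when
    both sets are drawn at random from the pool holding their richness fixed —
    i.e. ``P(X < s)`` for ``X ~ Hypergeometric(P, a, b)``. Symmetric in the two
    sets and zero for disjoint sets (``s = 0`` makes sharing at least 0 species
    certain; this quirk is a property of the index, kept as defined).

    ``method="randomization"`` estimates the same probability by Monte Carlo
    reshuffling of species identities (``n_iter`` draws, seeded).
    """
    A, B, P = frozenset(set_a), frozenset(set_b), frozenset(pool)
    if not A <= P or not B <= P:
        raise DegenerateInputError("both sets must be subsets of the pool")
    if not A or not B:
        raise DegenerateInputError("both sets must be non-empty")
    s = len(A & B)
    if method == "hypergeometric":
        # P(X <= s-1) with M=pool, n=|A| marked, N=|B| drawn
        return float(hypergeom.cdf(s - 1, len(P), len(A), len(B)))
    if method == "randomization":
        rng = np.random.default_rng(seed)
        pool_arr = np.array(sorted(P))
        hits = 0
        for _ in range(n_iter):
            ra = rng.choice(pool_arr, size=len(A), replace=False)
            rb = rng.choice(pool_arr, size=len(B), replace=False)
            if len(np.intersect1d(ra, rb)) < s:
                hits += 1
        return hits / n_iter
    raise ValueError(f"unknown method {method!r}")


def _rc_matrix(presence: np.ndarray, pool_size: int) -> np.ndarray:
    """All-pairs hypergeometric Raup–Crick for a boolean institutions × species
    matrix. Log-space evaluation through a gammaln lookup keeps large pools
    exact; verified against the scalar scipy path in the test suite."""
    n_inst = presence.shape[0]
    presence = presence.astype(np.int64)
    a = presence.sum(axis=1)
    shared = presence @ presence.T
    gl = gammaln(np.arange(pool_size + 2, dtype=np.float64))

    def log_comb(n, k):
        return gl[n + 1] - gl[k + 1] - gl[n - k + 1]

    out = np.zeros((n_inst, n_inst))
    for i in range(n_inst):
        for j in range(i + 1, n_inst):
            s = shared[i, j]
            if s == 0:
                continue
            k = np.arange(0, s)  # shared-count values below the observed s
            valid = (k <= a[i]) & (a[j] - k <= pool_size - a[i]) & (k <= a[j])
            k = k[valid]
            if k.size == 0:
                continue
            logs = (
                log_comb(a[i], k)
                + log_comb(pool_size - a[i], a[j] - k)
                - log_comb(pool_size, a[j])
            )
            m = logs.max()
            out[i, j] = out[j, i] = float(np.exp(m) * np.exp(logs - m).sum())
    return np.clip(out, 0.0, 1.0)


def dissimilarity_matrix(holdings: HoldingsMatrix) -> pd.DataFrame:
    """Pairwise Raup–Crick dissimilarity between every pair of institutions,
    pool = union of species across all institutions."""
    pool = holdings.pool
    presence = (holdings.counts.loc[:, sorted(pool)] > 0).to_numpy()
    mat = _rc_matrix(presence, len(pool))
    return pd.DataFrame(mat, index=holdings.institutions, columns=holdings.institutions)


def mean_dissimilarity(holdings: HoldingsMatrix, institution) -> float:
    """Mean Raup–Crick dissimilarity between the focal institution and every
    other institution."""
    if institution not in holdings.counts.index:
        raise UnknownInstitutionError(institution)
    if len(holdings.institutions) < 2:
        raise DegenerateInputError("mean dissimilarity needs at least two institutions")
    mat = dissimilarity_matrix(holdings)
    others = [i for i in holdings.institutions if i != institution]
    return float(mat.loc[institution, others].mean())


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


def _profile_from_row(
    institution,
    counts: pd.Series,
    species: pd.DataFrame,
    mode: Mode,
    mean_diss: float,
) -> CompositionProfile:
    held = counts[counts > 0]
    if held.empty:
        raise DegenerateInputError(f"institution {institution!r} holds no animals")
    x = held.to_numpy(dtype=float)
    if mode == "presence":
        x = np.ones_like(x)
    attrs = species.loc[held.index]
    masses = pd.to_numeric(attrs["body_mass_g"], errors="coerce").to_numpy(dtype=float)
    if np.isnan(masses).any():
        bad = sorted(held.index[np.isnan(masses)])
        raise UnresolvedMassError(
            f"unresolved body mass for {bad}; run resolve_masses first"
        )
    return CompositionProfile(
        institution_id=institution,
        species_richness=int(len(held)),
        total_animals=int(x.sum()),
        mammal_species_richness=int((attrs["vclass"] == "Mammalia").sum()),
        threatened_proportion=threatened_proportion(x, attrs["iucn"], mode="abundance"),
        mean_body_mass=mean_body_mass(x, masses),
        brillouin=brillouin_index(x.astype(int)),
        mean_dissimilarity=mean_diss,
        mode=mode,
    )


def compute_profile(
    holdings: HoldingsMatrix, institution, mode: Mode = "abundance"
) -> CompositionProfile:
    """All composition variables for one institution.

    In presence mode every positive count is treated as a single individual,
    so total animals equals species richness, the mean body mass is the
    unweighted species mean and the threatened proportion is a species
    fraction. ``mean_dissimilarity`` is NaN for a single-institution dataset
    (the index needs a comparison set).
    """
    _check_mode(mode)
    counts = holdings.row(institution)
    if len(holdings.institutions) >= 2:
        mdiss = mean_dissimilarity(holdings, institution)
    else:
        mdiss = float("nan")
    return _profile_from_row(institution, counts, holdings.species, mode, mdiss)


def compute_profiles(holdings: HoldingsMatrix, mode: Mode = "abundance") -> pd.DataFrame:
    """Composition profiles for every institution as one table (computes the
    pairwise dissimilarity matrix once)."""
    _check_mode(mode)
    if len(holdings.institutions) >= 2:
        mat = dissimilarity_matrix(holdings)
        n = len(holdings.institutions)
        mdiss = (mat.sum(axis=1)) / (n - 1)
    else:
        mdiss = pd.Series(float("nan"), index=holdings.institutions)
    rows = [
        _profile_from_row(
            inst, holdings.counts.loc[inst], holdings.species, mode, float(mdiss[inst])
        ).as_dict()
        for inst in holdings.institutions
    ]
    return pd.DataFrame(rows).set_index("institution_id")
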