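"""Antibody Fc N-glycoform nomenclature, abundance tables, and quality indices.

An intact IgG carries two N-glycans, one per heavy chain. Species are written
as arm pairs, e.g. ``"G1F ⋅ G0F"``: G0/G1/G2 give the number of terminal
galactoses on a bi-antennary glycan, a trailing F marks core fucosylation, and
``none`` marks an unoccupied site. Fractional abundances of these pairs
(percent, summing to 100 per sample) are the module's central table, from
which two product-quality indices are computed:

* the **galactosylation index**, the abundance-weighted percentage of
  available galactosylation sites that carry a galactose; and
* the **glycation index**, the abundance-weighted occupancy of a fixed
  maximum of three non-enzymatic hexose (glycation) sites, measured on the
  deglycosylated antibody.

Because a glycation hexose and a galactose are isobaric at the intact level
(+162 Da each), intact-mass glycoform assignments are biased whenever
glycation is present; :func:`correct_hexosylation_bias` deconvolves that bias
using the independently measured glycation distribution.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

logger = logging.getLogger(__name__)

SEPARATOR = " ⋅ "

#: Recognised single-arm tokens.
ARM_TOKENS = ("none", "G0", "G1", "G2", "G0F", "G1F", "G2F")

#: Fixed number of glycation (hexose) sites per antibody.
GLYCATION_SITES = 3

#: Valid feeding-strategy codes for sample metadata.
STRATEGIES = ("STD", "STD+", "LoG", "LoG+", "HiF", "HIP", "HIP+")

#: Culture phases at which glycoform samples are taken.
PHASES = ("exp", "sta")

_ARM_RE = re.compile(r"^(?:none|G([0-2])(F?))$")


class GlycoformParseError(ValueError):
    """Raised when a glycoform label cannot be parsed."""


@dataclass(frozen=True, order=True)
class GlycanArm:
    """One of the two N-glycans of an intact antibody.

    ``gal_sites`` is 2 for any present bi-antennary glycan and 0 for an
    unoccupied site: sites cannot exist without a glycan.
    """

    token: str

    def __post_init__(self) -> None:
        if self.token != "none" and not _ARM_RE.match(self.token):
            raise GlycoformParseError(f"unknown glycan arm token: {self.token!r}")

    @property
    def present(self) -> bool:
        return self.token != "none"

    @property
    def gal_count(self) -> int:
        return int(self.token[1]) if self.present else 0

    @property
    def fucosylated(self) -> bool:
        return self.token.endswith("F")

    @property
    def gal_sites(self) -> int:
        return 2 if self.present else 0


def _arm_sort_key(arm: GlycanArm) -> tuple:
    # present arms first, then by galactose count, fucosylation, token text
    return (not arm.present, arm.gal_count, arm.fucosylated, arm.token)


@dataclass(frozen=True)
class GlycoformSpecies:
    """A parsed glycoform pair in canonical arm order.

    ``g`` is the total number of galactose residues, ``d`` the total number
    of possible galactosylation sites (2 per present arm). ``hexose_adducts``
    counts additional glycation hexoses when the species represents an
    intact-level (glycation-resolved) observation.
    """

    arm_a: GlycanArm
    arm_b: GlycanArm
    hexose_adducts: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.hexose_adducts <= GLYCATION_SITES:
            raise ValueError(
                f"hexose_adducts must be in [0, {GLYCATION_SITES}], "
                f"got {self.hexose_adducts}"
            )
        a, b = sorted((self.arm_a, self.arm_b), key=_arm_sort_key)
        object.__setattr__(self, "arm_a", a)
        object.__setattr__(self, "arm_b", b)

    @property
    def g(self) -> int:
        """Total galactose residues on the pair."""
        return self.arm_a.gal_count + self.arm_b.gal_count

    @property
    def d(self) -> int:
        """Total possible galactosylation sites on the pair."""
        return self.arm_a.gal_sites + self.arm_b.gal_sites

    @property
    def label(self) -> str:
        base = f"{self.arm_a.token}{SEPARATOR}{self.arm_b.token}"
        if self.hexose_adducts:
            base += f" + {self.hexose_adducts}Hex"
        return base

    @property
    def backbone(self) -> str:
        """Fucosylation/occupancy backbone, i.e. the label with galactose
        counts and hexose adducts stripped (used to group isobaric ladders)."""
        def strip(arm: GlycanArm) -> str:
            if not arm.present:
                return "none"
            return "G.F" if arm.fucosylated else "G."

        return SEPARATOR.join(sorted(strip(a) for a in (self.arm_a, self.arm_b)))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_glycoform(label: str) -> GlycoformSpecies:
    """Parse a glycoform-pair label such as ``"G1F ⋅ G0F"``.

    The two arm tokens are separated by "⋅" (ASCII "." accepted as an alias);
    surrounding whitespace is tolerated. An optional trailing ``+ nHex``
    records glycation hexose adducts of an intact-level observation.
    Parsing is idempotent through :attr:`GlycoformSpecies.label`.
    """
    text = label.strip()
    hexoses = 0
    m = re.search(r"\+\s*(\d+)\s*Hex\s*$", text)
    if m:
        hexoses = int(m.group(1))
        text = text[: m.start()].strip()
    parts = [p for p in re.split(r"\s*[⋅.]\s*", text) if p]
    if len(parts) != 2:
        raise GlycoformParseError(
            f"expected exactly two arm tokens separated by '⋅' in {label!r}, "
            f"found {len(parts)}"
        )
    return GlycoformSpecies(GlycanArm(parts[0]), GlycanArm(parts[1]), hexoses)


def vocabulary() -> list[GlycoformSpecies]:
    """All canonical arm-pair species over the seven-token vocabulary."""
    seen: dict[str, GlycoformSpecies] = {}
    for a in ARM_TOKENS:
        for b in ARM_TOKENS:
            sp = GlycoformSpecies(GlycanArm(a), GlycanArm(b))
            seen.setdefault(sp.label, sp)
    return list(seen.values())


@dataclass
class GlycoformTable:
    """Samples x glycoforms fractional abundances (percent) with metadata.

    ``abundances`` is a DataFrame indexed by sample id with one column per
    canonical glycoform label; every row sums to 100. ``metadata`` carries
    ``strategy``, ``phase`` and ``replicate`` per sample.
    """

    abundances: pd.DataFrame
    metadata: pd.DataFrame
    species: dict[str, GlycoformSpecies] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.species:
            self.species = {c: parse_glycoform(c) for c in self.abundances.columns}
        if not self.abundances.index.equals(self.metadata.index):
            raise ValueError("abundance and metadata sample ids differ")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundances.index)

    def values(self) -> np.ndarray:
        return self.abundances.to_numpy(dtype=float)


def normalize_abundances(
    raw: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    *,
    tolerance_pct: float = 0.5,
) -> GlycoformTable:
    """Scale raw per-sample abundances to fractional abundances summing to 100.

    Relative ratios within a sample are preserved. Input rows already within
    ``tolerance_pct`` percentage points of 100 are silently consistent;
    larger deviations are renormalized with a warning only when they exceed
    the tolerance, and an all-zero sample is an error.

    Parameters
    ----------
    raw:
        samples x glycoform-label DataFrame of nonnegative abundances
        (arbitrary units or percent).
    metadata:
        optional per-sample DataFrame (strategy, phase, replicate); defaults
        to empty columns.
    """
    values = raw.to_numpy(dtype=float)
    if (values < 0).any():
        bad = raw.index[(values < 0).any(axis=1)][0]
        raise ValueError(f"negative abundance in sample {bad!r}")
    sums = values.sum(axis=1)
    zero = sums <= 0
    if zero.any():
        raise ValueError(
            f"sample {raw.index[zero][0]!r} has all-zero abundances; "
            "cannot form fractional abundances"
        )
    off = np.abs(sums - 100.0) > tolerance_pct
    # warn only for rows that look like percent data but deviate; raw-unit
    # inputs (sums far from 100) are normalized silently by design
    if off.any() and np.all(np.abs(sums - 100.0) <= 5.0):
        logger.warning(
            "%d sample(s) deviated from a 100%% sum by more than %.2f "
            "percentage points and were renormalized",
            int(off.sum()),
            tolerance_pct,
        )
    norm = 100.0 * values / sums[:, None]
    species = {c: parse_glycoform(c) for c in raw.columns}
    abundances = pd.DataFrame(norm, index=raw.index, columns=[species[c].label for c in raw.columns])
    if metadata is None:
        metadata = pd.DataFrame(
            {"strategy": pd.NA, "phase": pd.NA, "replicate": pd.NA}, index=raw.index
        )
    return GlycoformTable(abundances, metadata.loc[raw.index].copy())


def galactosylation_index(table: GlycoformTable) -> pd.Series:
    """Abundance-weighted galactose site occupancy, percent per sample.

    For glycoform *j* with fractional abundance ``A_j``, galactose count
    ``g_j`` and possible sites ``d_j``::

        index = 100 * sum_j(A_j * g_j) / sum_j(A_j * d_j)

    Always in [0, 100]; a sample whose entire abundance lies on species
    without galactosylation sites has an undefined index and raises.
    """
    g = np.array([sp.g for sp in table.species.values()], dtype=float)
    d = np.array([sp.d for sp in table.species.values()], dtype=float)
    A = table.values()
    num = A @ g
    den = A @ d
    if np.any(den <= 0):
        bad = table.abundances.index[den <= 0][0]
        raise ValueError(
            f"sample {bad!r}: no abundance on species with galactosylation sites"
        )
    return pd.Series(100.0 * num / den, index=table.abundances.index, name="galactosylation_index")


@dataclass
class GlycationProfile:
    """Per-sample hexose-count distribution of the deglycosylated antibody.

    ``fractions`` is a samples x 4 DataFrame (columns ``hexoses_0`` ..
    ``hexoses_3``, percent, rows summing to 100) giving the abundance of
    antibody carrying 0-3 glycation hexoses.
    """

    fractions: pd.DataFrame

    def __post_init__(self) -> None:
        expected = [f"hexoses_{i}" for i in range(GLYCATION_SITES + 1)]
        if list(self.fractions.columns) != expected:
            raise ValueError(f"glycation profile columns must be {expected}")
        vals = self.fractions.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError("negative glycation fractions")
        sums = vals.sum(axis=1)
        if np.any(np.abs(sums - 100.0) > 1e-9 * 100.0):
            self.fractions = self.fractions.mul(100.0 / sums, axis=0)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fractions.index)

    def values(self) -> np.ndarray:
        return self.fractions.to_numpy(dtype=float)


def glycation_index(profile: GlycationProfile) -> pd.Series:
    """Abundance-weighted glycation-site occupancy, percent per sample.

    With hexose counts ``g_i`` in {0..3}, fractions ``f_i`` summing to 100,
    and a fixed maximum of ``s_i = 3`` sites::

        index = 100 * sum_i(g_i * f_i) / sum_i(s_i * f_i)
    """
    f = profile.values()
    g = np.arange(GLYCATION_SITES + 1, dtype=float)
    num = f @ g
    den = GLYCATION_SITES * f.sum(axis=1)
    return pd.Series(100.0 * num / den, index=profile.fractions.index, name="glycation_index")


def forward_hexosylation_bias(
    table: GlycoformTable, profile: GlycationProfile
) -> GlycoformTable:
    """Convolve true glycoform abundances with a glycation distribution.

    Models how intact-level measurement mixes glycation hexoses into the
    apparent galactosylation ladder: within each fucosylation backbone, the
    observed abundance at total hexose count ``h`` is the sum over glycation
    counts ``k`` of (true abundance at galactose count ``h - k``) x
    (glycation fraction ``k``). Observed mass at a ladder position with a
    matching galactose class is annotated as those (apparently more
    galactosylated) species, split by their within-class ratios; positions
    with no matching class — beyond the fully galactosylated species, or at
    a galactose count absent from the vocabulary — are annotated as the
    nearest lower class with explicit ``+ nHex`` adducts. No mass is lost,
    so :func:`correct_hexosylation_bias` is the exact inverse.
    """
    _check_sample_match(table, profile)
    glyc = profile.values() / 100.0
    A = table.values()
    cols = list(table.abundances.columns)
    out: dict[str, np.ndarray] = {c: np.zeros(A.shape[0]) for c in cols}
    for backbone, idx in _backbone_groups(table).items():
        gals = np.array([table.species[cols[i]].g for i in idx])
        gmax = max(int(table.species[cols[i]].d) for i in idx)
        classes = sorted({int(g) for g in gals})
        for s in range(A.shape[0]):
            true_by_g = np.zeros(gmax + 1)
            np.add.at(true_by_g, gals, A[s, idx])
            observed = np.convolve(true_by_g, glyc[s])
            for h, mass in enumerate(observed):
                if mass <= 0:
                    continue
                below = [g for g in classes if g <= h]
                carrier = max(below) if below else min(classes)
                adducts = max(0, h - carrier)
                members = [i for i, gg in zip(idx, gals) if gg == carrier]
                weights = A[s, members]
                total = weights.sum()
                w = (weights / total if total > 0
                     else np.full(len(members), 1.0 / len(members)))
                for m, wm in zip(members, w):
                    sp = table.species[cols[m]]
                    if adducts:
                        sp = GlycoformSpecies(sp.arm_a, sp.arm_b,
                                              sp.hexose_adducts + adducts)
                    col = sp.label
                    if col not in out:
                        out[col] = np.zeros(A.shape[0])
                    out[col][s] += mass * wm
    abundances = pd.DataFrame(out, index=table.abundances.index)
    abundances = abundances.mul(100.0 / abundances.sum(axis=1), axis=0)
    return GlycoformTable(abundances, table.metadata.copy())


def correct_hexosylation_bias(
    table: GlycoformTable, profile: GlycationProfile
) -> GlycoformTable:
    """Remove the glycation contribution from intact-level glycoform abundances.

    Galactose and glycation hexose are isobaric (+162 Da), so intact-level
    galactosylation ladders are biased towards higher apparent galactose
    counts whenever glycation is present. Under the independence model
    (observed hexose ladder = true galactosylation ladder convolved with the
    glycation distribution measured on deglycosylated antibody), the truth is
    recovered per sample and fucosylation backbone by non-negative
    least-squares deconvolution. Components driven slightly negative by
    measurement noise are clipped at zero and each row renormalized to 100.
    With zero glycation the table is returned unchanged (up to normalization).
    """
    _check_sample_match(table, profile)
    glyc = profile.values() / 100.0
    A = table.values()
    out = np.zeros_like(A)
    cols = list(table.abundances.columns)
    for backbone, idx in _backbone_groups(table).items():
        # total observed hexoses per species: apparent galactoses plus any
        # explicitly annotated glycation adducts
        hexes = np.array(
            [table.species[cols[i]].g + table.species[cols[i]].hexose_adducts for i in idx]
        )
        gals = np.array([table.species[cols[i]].g for i in idx])
        plain = [i for i, sp in zip(idx, gals) if table.species[cols[i]].hexose_adducts == 0]
        gmax = max(int(table.species[cols[i]].d) for i in idx)
        n_obs = max(gmax, int(hexes.max())) + 1
        for s in range(A.shape[0]):
            observed = np.zeros(n_obs)
            np.add.at(observed, hexes, A[s, idx])
            kernel = glyc[s]
            if kernel[0] >= 1.0 - 1e-12:
                truth = observed[: gmax + 1]
            else:
                # column k of C maps truth mass at galactose count k onto
                # observed hexose counts k..k+3, truncated at the ladder end
                C = np.zeros((n_obs, gmax + 1))
                for k in range(gmax + 1):
                    seg = kernel[: n_obs - k]
                    C[k : k + len(seg), k] = seg
                truth, _ = nnls(C, observed)
            for gi in range(gmax + 1):
                members = [i for i in plain if table.species[cols[i]].g == gi]
                if not members:
                    continue
                weights = A[s, members]
                total = weights.sum()
                w = weights / total if total > 0 else np.full(len(members), 1 / len(members))
                for m, wm in zip(members, w):
                    out[s, m] += truth[gi] * wm
    out = np.clip(out, 0.0, None)
    abundances = pd.DataFrame(out, index=table.abundances.index, columns=cols)
    abundances = abundances.mul(100.0 / abundances.sum(axis=1), axis=0)
    return GlycoformTable(abundances, table.metadata.copy(), dict(table.species))


def _backbone_groups(table: GlycoformTable) -> dict[str, list[int]]:
    groups: dict[str, list[int]] = {}
    for i, col in enumerate(table.abundances.columns):
        groups.setdefault(table.species[col].backbone, []).append(i)
    return groups


def _check_sample_match(table: GlycoformTable, profile: GlycationProfile) -> None:
    if list(table.abundances.index) != list(profile.fractions.index):
        missing = set(table.abundances.index) ^ set(profile.fractions.index)
        raise ValueError(
            f"glycoform table and glycation profile sample ids differ: {sorted(missing)}"
        )
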