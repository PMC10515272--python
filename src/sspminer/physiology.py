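"""Drought-damage physiology metrics and group statistics.

Implements the standard leaf-level stress formulas:

* relative water content          RWC = (FW - DW) / (SW - DW) x 100%
* relative electrolyte conductivity  REC = K1 / K2 x 100%
* malondialdehyde concentration   MDA (nM/g) = [(A532 - A600) x Vr / eps x 1e9]
                                               / (Wt x Vt / V)

with the thiobarbituric-acid extinction coefficient eps = 1.55e5 L/mol/cm.
The MDA expression is evaluated with the literal operator order printed
above ((d x Vr) / eps, then x 1e9); the unit label nM/g follows the source
convention (dimensional bookkeeping strictly gives nmol/g for these inputs —
documented, not altered).

Group comparison is classical one-way ANOVA with a compact letter display
built from Tukey HSD pairwise tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "EXTINCTION_COEFFICIENT",
    "PhysiologySample",
    "rwc",
    "rec",
    "mda",
    "GroupComparison",
    "group_compare",
]

#: MDA-TBA adduct extinction coefficient, L/mol/cm.
EXTINCTION_COEFFICIENT = 1.55e5


@dataclass(frozen=True)
class PhysiologySample:
    """Raw measurements for one sample (fields default NaN = not measured).

    FW/SW/DW: fresh, water-saturated and dry weight (g) for RWC.
    K1/K2: initial and post-boiling conductivity for REC.
    A532/A600: absorbances; Vr, V, Vt (mL) and Wt (g) for MDA.
    """

    sample_id: str
    treatment: str = ""
    FW: float = float("nan")
    SW: float = float("nan")
    DW: float = float("nan")
    K1: float = float("nan")
    K2: float = float("nan")
    A532: float = float("nan")
    A600: float = float("nan")
    Vr: float = float("nan")
    V: float = float("nan")
    Vt: float = float("nan")
    Wt: float = float("nan")

    def rwc(self) -> float:
        return rwc(self.FW, self.SW, self.DW)

    def rec(self) -> float:
        return rec(self.K1, self.K2)

    def mda(self) -> float:
        return mda(self.A532, self.A600, self.Vr, self.Wt, self.Vt, self.V)


def rwc(fw: float, sw: float, dw: float) -> float:
    """Relative water content, percent of saturated minus dry weight."""
    if sw == dw:
        raise ZeroDivisionError("RWC undefined: saturated weight equals dry weight")
    if not (dw <= fw <= sw):
        warnings.warn(
            f"RWC inputs violate DW <= FW <= SW (FW={fw}, SW={sw}, DW={dw}); "
            "value returned anyway"
        )
    return (fw - dw) / (sw - dw) * 100.0


def rec(k1: float, k2: float) -> float:
    """Relative electrolyte conductivity, percent."""
    if k2 <= 0:
        raise ZeroDivisionError("REC undefined: K2 must be positive")
    value = k1 / k2 * 100.0
    if value > 100.0:
        warnings.warn(f"REC {value:.1f}% exceeds 100% (K1 > K2)")
    return value


def mda(
    a532: float,
    a600: float,
    vr: float,
    wt: float,
    vt: float,
    v: float,
    epsilon: float = EXTINCTION_COEFFICIENT,
) -> float:
    """MDA concentration (nM/g fresh weight), literal printed operator order."""
    for name, val in {"Vr": vr, "Wt": wt, "Vt": vt, "V": v}.items():
        if val <= 0:
            raise ValueError(f"MDA: {name} must be positive, got {val}")
    diff = a532 - a600
    if diff < 0:
        warnings.warn("MDA: A600 exceeds A532 (blank over signal); negative value")
    return (diff * vr / epsilon * 1e9) / (wt * vt / v)


@dataclass
class GroupComparison:
    groups: list[str]
    means: dict[str, float]
    sds: dict[str, float]
    f_statistic: float
    p_value: float
    letters: dict[str, str]

    def summary(self) -> str:
        lines = [f"one-way ANOVA: F = {self.f_statistic:.3f}, p = {self.p_value:.3g}"]
        for g in self.groups:
            lines.append(
                f"  {g}: {self.means[g]:.3f} +/- {self.sds[g]:.3f}  {self.letters[g]}"
            )
        return "\n".join(lines)


def _letter_display(groups: list[str], nonsig: set[frozenset]) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Each letter denotes a maximal clique-like set of groups none of whose
    pairs differ significantly; groups sharing a letter are statistically
    indistinguishable at the chosen alpha.
    """
    sets: list[set[str]] = []
    for g in groups:
        placed = False
        for s in sets:
            if all(frozenset((g, h)) in nonsig for h in s):
                s.add(g)
                placed = True
        if not placed:
            sets.append({g})
    # absorb subsets
    sets = [s for i, s in enumerate(sets) if not any(s < t for j, t in enumerate(sets) if i != j)]
    letters = {g: "" for g in groups}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", sets):
        for g in groups:
            if g in s:
                letters[g] += letter
    return letters


def group_compare(
    values_by_group: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> GroupComparison:
    """Per-group mean +/- SD, one-way ANOVA, and Tukey-based letter display."""
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("group_compare needs at least two groups")
    arrays = {g: np.asarray(values_by_group[g], dtype=float) for g in groups}
    for g, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {g!r} has fewer than two values")

    f_stat, p_val = stats.f_oneway(*arrays.values())
    if not np.isfinite(f_stat):  # all groups identical and constant
        f_stat, p_val = 0.0, 1.0

    nonsig: set[frozenset] = set()
    pooled_var = np.mean([a.var(ddof=1) for a in arrays.values()])
    if pooled_var == 0.0:
        # degenerate: no within-group variance; equal means are indistinct
        for i, g in enumerate(groups):
            for h in groups[i + 1 :]:
                if arrays[g].mean() == arrays[h].mean():
                    nonsig.add(frozenset((g, h)))
    else:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        data = np.concatenate([arrays[g] for g in groups])
        labels = np.concatenate([[g] * arrays[g].size for g in groups])
        tk = pairwise_tukeyhsd(data, labels, alpha=alpha)
        pairs = list(combinations([str(g) for g in tk.groupsunique], 2))
        for (g, h), reject in zip(pairs, tk.reject):
            if not reject:
                nonsig.add(frozenset((g, h)))

    return GroupComparison(
        groups=groups,
        means={g: float(a.mean()) for g, a in arrays.items()},
        sds={g: float(a.std(ddof=1)) for g, a in arrays.items()},
        f_statistic=float(f_stat),
        p_value=float(p_val),
        letters=_letter_display(groups, nonsig),
    )
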