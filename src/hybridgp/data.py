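"""Core containers: pure-line genotypes, hybrid pedigree, phenotypes.

Lines are fully homozygous, so a single 0/1 indicator per marker (1 =
homozygous for the counted allele B, 0 = homozygous b) describes the whole
genotype; hybrids are always derived from their two parents, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LineGenotypes", "HybridPedigree", "PhenotypeTable"]


@dataclass
class LineGenotypes:
    """Homozygote-indicator matrix for the inbred lines of one heterotic group.

    Parameters
    ----------
    group_label
        Name of the heterotic group (e.g. ``"dent"``).
    line_ids
        Ordered unique line identifiers (rows of ``calls``).
    marker_ids
        Ordered unique marker identifiers (columns of ``calls``).
    calls
        ``(n_lines, n_markers)`` matrix with entries in {0, 1}; 1 means
        homozygous for the counted allele B at that marker.
    """

    group_label: str
    line_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D matrix (lines x markers)")
        if self.calls.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError(f"duplicate line ids in group {self.group_label!r}")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError(f"duplicate marker ids in group {self.group_label!r}")
        bad = ~np.isin(self.calls, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-0/1 genotype call {self.calls[i, j]!r} for line "
                f"{self.line_ids[i]!r} at marker {self.marker_ids[j]!r}"
            )
        self.calls = self.calls.astype(np.float64)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def line_index(self) -> dict[str, int]:
        return {lid: i for i, lid in enumerate(self.line_ids)}


def check_shared_panel(g1: LineGenotypes, g2: LineGenotypes) -> None:
    """Fail loudly unless both groups carry an identical, identically ordered
    marker panel (a prerequisite for every hybrid-level coding)."""
    if g1.marker_ids != g2.marker_ids:
        n_common = len(set(g1.marker_ids) & set(g2.marker_ids))
        raise ValueError(
            f"marker panels differ between groups {g1.group_label!r} "
            f"({g1.n_markers} markers) and {g2.group_label!r} ({g2.n_markers} "
            f"markers); {n_common} shared. Reconcile panels explicitly "
            "(intersect_panels) before building codings."
        )


def intersect_panels(g1: LineGenotypes, g2: LineGenotypes) -> tuple[LineGenotypes, LineGenotypes]:
    """Restrict both groups to the shared markers, in group-1 file order."""
    shared = [m for m in g1.marker_ids if m in set(g2.marker_ids)]
    if not shared:
        raise ValueError("marker panels have no markers in common")
    idx1 = [g1.marker_ids.index(m) for m in shared]
    pos2 = {m: j for j, m in enumerate(g2.marker_ids)}
    idx2 = [pos2[m] for m in shared]
    return (
        LineGenotypes(g1.group_label, list(g1.line_ids), shared, g1.calls[:, idx1]),
        LineGenotypes(g2.group_label, list(g2.line_ids), shared, g2.calls[:, idx2]),
    )


@dataclass
class HybridPedigree:
    """Maps each single-cross hybrid to one parent line per heterotic group."""

    hybrid_ids: list[str]
    parent1: dict[str, str]
    parent2: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.hybrid_ids)) != len(self.hybrid_ids):
            dup = pd.Series(self.hybrid_ids)
            dup = dup[dup.duplicated()].iloc[0]
            raise ValueError(f"duplicate hybrid id {dup!r} in pedigree")
        for h in self.hybrid_ids:
            if h not in self.parent1 or h not in self.parent2:
                raise ValueError(f"hybrid {h!r} lacks a parent in one group")

    @property
    def n_hybrids(self) -> int:
        return len(self.hybrid_ids)

    def parents(self, hybrid_id: str) -> tuple[str, str]:
        return self.parent1[hybrid_id], self.parent2[hybrid_id]

    def validate_against(self, g1: LineGenotypes, g2: LineGenotypes) -> None:
        """Referential integrity: every parent must be a genotyped line."""
        l1, l2 = set(g1.line_ids), set(g2.line_ids)
        for h in self.hybrid_ids:
            if self.parent1[h] not in l1:
                raise ValueError(
                    f"hybrid {h!r}: parent {self.parent1[h]!r} not found in "
                    f"group {g1.group_label!r}"
                )
            if self.parent2[h] not in l2:
                raise ValueError(
                    f"hybrid {h!r}: parent {self.parent2[h]!r} not found in "
                    f"group {g2.group_label!r}"
                )

    def subset(self, hybrid_ids: list[str]) -> "HybridPedigree":
        missing = [h for h in hybrid_ids if h not in self.parent1]
        if missing:
            raise KeyError(f"hybrids not in pedigree: {missing[:5]}")
        return HybridPedigree(
            list(hybrid_ids),
            {h: self.parent1[h] for h in hybrid_ids},
            {h: self.parent2[h] for h in hybrid_ids},
        )


@dataclass
class PhenotypeTable:
    """Entry means of hybrids: one record per hybrid plus optional covariates."""

    hybrid_ids: list[str]
    values: np.ndarray
    trait: str = "trait"
    covariates: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.hybrid_ids),):
            raise ValueError("one phenotype value per hybrid required")
        if len(set(self.hybrid_ids)) != len(self.hybrid_ids):
            raise ValueError("duplicate hybrid id in phenotype table (entry means expected)")

    @property
    def n(self) -> int:
        return len(self.hybrid_ids)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.hybrid_ids, name=self.trait)

    def subset(self, hybrid_ids: list[str]) -> "PhenotypeTable":
        pos = {h: i for i, h in enumerate(self.hybrid_ids)}
        idx = [pos[h] for h in hybrid_ids]
        cov = self.covariates.iloc[idx] if self.covariates is not None else None
        return PhenotypeTable(list(hybrid_ids), self.values[idx], self.trait, cov)
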