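"""Incidence codings for hybrid genomic models.

Origin-specific (GCA-model) codings
-----------------------------------
Within each heterotic group the homozygote indicator ``M`` (0/1) is centered
by the within-group B-allele frequency ``p``::

    z = M - p            so z in {q, -p} per marker (q = 1 - p)

and the dominance coding of a hybrid is the product of its two parental
centered codes::

    w = -2 z1 z2         i.e. {-2 q1 q2, 2 q1 p2, 2 p1 q2, -2 p1 p2}
                         for genotypes B1B2, B1b2, b1B2, b1b2.

Over the ideal hybrid population (class frequencies p1p2, p1q2, q1p2, q1q2)
the codes z1, z2 and w have zero mean and zero pairwise cross-products: the
additive and dominance design columns are orthogonal by construction.

Hybrid-level (G-model) codings
------------------------------
The NOIA parameterization builds additive (``Ha``) and dominance (``Hd``)
codes from the genotype-class frequencies observed in the hybrid set itself,
so orthogonality holds without assuming Hardy-Weinberg equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import LineGenotypes, HybridPedigree, check_shared_panel

__all__ = [
    "AlleleFrequencies",
    "AdditiveCoding",
    "DominanceCoding",
    "HybridGenotypes",
    "NoiaCodings",
    "compute_allele_freqs",
    "center_line_genotypes",
    "build_parent_incidence",
    "build_dominance_incidence",
    "derive_hybrid_genotypes",
    "noia_codings",
]


@dataclass
class AlleleFrequencies:
    """Frequency of the counted allele B per marker, within one group."""

    group_label: str
    p: np.ndarray
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if ((self.p < 0) | (self.p > 1)).any():
            raise ValueError("allele frequencies must lie in [0, 1]")
        if self.p.shape != (len(self.marker_ids),):
            raise ValueError("one frequency per marker required")

    @property
    def q(self) -> np.ndarray:
        return 1.0 - self.p


@dataclass
class AdditiveCoding:
    """Centered line coding Z = M - 1 p' for one group (lines x markers)."""

    group_label: str
    Z: np.ndarray
    line_ids: list[str]
    marker_ids: list[str]


@dataclass
class DominanceCoding:
    """Hybrid dominance coding W with W[h, k] = -2 z1[parent1(h), k] z2[parent2(h), k]."""

    W: np.ndarray
    hybrid_ids: list[str]
    marker_ids: list[str]


@dataclass
class HybridGenotypes:
    """Derived hybrid genotypes (B-allele counts) and their class frequencies.

    ``counts`` is hybrids x markers in {0, 1, 2}; ``p_bb``, ``p_het``,
    ``p_BB`` are the per-marker genotype-class frequencies observed in the
    hybrid set (no HWE assumption), and ``pk`` the hybrid B frequency.
    """

    counts: np.ndarray
    hybrid_ids: list[str]
    marker_ids: list[str]
    p_BB: np.ndarray
    p_het: np.ndarray
    p_bb: np.ndarray

    @property
    def pk(self) -> np.ndarray:
        return self.p_BB + 0.5 * self.p_het


@dataclass
class NoiaCodings:
    """NOIA additive (Ha) and dominance (Hd) codings at the hybrid level."""

    Ha: np.ndarray
    Hd: np.ndarray
    hybrid_ids: list[str]
    marker_ids: list[str]


def compute_allele_freqs(G: LineGenotypes) -> AlleleFrequencies:
    """Observed B frequency per marker: the column mean of the 0/1 calls."""
    if G.n_lines == 0:
        raise ValueError(f"group {G.group_label!r} has no lines")
    return AlleleFrequencies(G.group_label, G.calls.mean(axis=0), list(G.marker_ids))


def center_line_genotypes(G: LineGenotypes, f: AlleleFrequencies) -> AdditiveCoding:
    """Z = M - 1 p'.  With observed frequencies every column sums to zero."""
    if G.n_markers != len(f.marker_ids):
        raise ValueError("genotypes and frequencies cover different marker panels")
    return AdditiveCoding(G.group_label, G.calls - f.p[None, :], list(G.line_ids), list(G.marker_ids))


def build_parent_incidence(ped: HybridPedigree, G: LineGenotypes, group: int) -> np.ndarray:
    """0/1 incidence T (hybrids x lines) linking each hybrid to its parent
    in ``G``'s group; exactly one 1 per row.  ``group`` selects which parent
    map of the pedigree is used (1 or 2)."""
    if group not in (1, 2):
        raise ValueError("group must be 1 or 2")
    parent = ped.parent1 if group == 1 else ped.parent2
    pos = G.line_index()
    T = np.zeros((ped.n_hybrids, G.n_lines))
    for i, h in enumerate(ped.hybrid_ids):
        p = parent[h]
        if p not in pos:
            raise ValueError(
                f"hybrid {h!r}: parent {p!r} not among the {G.n_lines} lines "
                f"of group {G.group_label!r}"
            )
        T[i, pos[p]] = 1.0
    return T


def build_dominance_incidence(
    Z1: AdditiveCoding, Z2: AdditiveCoding, ped: HybridPedigree
) -> DominanceCoding:
    """W[h, k] = -2 z1 z2 with the parental rows given by the pedigree."""
    if Z1.marker_ids != Z2.marker_ids:
        raise ValueError("additive codings cover different marker panels")
    pos1 = {l: i for i, l in enumerate(Z1.line_ids)}
    pos2 = {l: i for i, l in enumerate(Z2.line_ids)}
    i1 = np.array([pos1[ped.parent1[h]] for h in ped.hybrid_ids])
    i2 = np.array([pos2[ped.parent2[h]] for h in ped.hybrid_ids])
    W = -2.0 * Z1.Z[i1, :] * Z2.Z[i2, :]
    return DominanceCoding(W, list(ped.hybrid_ids), list(Z1.marker_ids))


def derive_hybrid_genotypes(
    G1: LineGenotypes, G2: LineGenotypes, ped: HybridPedigree
) -> HybridGenotypes:
    """Hybrid B-allele counts = sum of parental indicators; class frequencies
    are computed over the hybrid set itself (no HWE assumption)."""
    check_shared_panel(G1, G2)
    ped.validate_against(G1, G2)
    pos1, pos2 = G1.line_index(), G2.line_index()
    i1 = np.array([pos1[ped.parent1[h]] for h in ped.hybrid_ids])
    i2 = np.array([pos2[ped.parent2[h]] for h in ped.hybrid_ids])
    counts = G1.calls[i1, :] + G2.calls[i2, :]
    n = len(ped.hybrid_ids)
    p_BB = (counts == 2).sum(axis=0) / n
    p_het = (counts == 1).sum(axis=0) / n
    p_bb = (counts == 0).sum(axis=0) / n
    return HybridGenotypes(counts, list(ped.hybrid_ids), list(G1.marker_ids), p_BB, p_het, p_bb)


def noia_codings(H: HybridGenotypes) -> NoiaCodings:
    """NOIA additive and dominance codings from hybrid genotype-class frequencies.

    Additive: ``Ha = 2 - 2 pk, 1 - 2 pk, -2 pk`` for genotypes BB, Bb, bb,
    with ``pk`` the hybrid B frequency.  Dominance, with class frequencies
    ``pBB``, ``pBb``, ``pbb`` and denominator
    ``den = pBB + pbb - (pBB - pbb)^2``::

        hd(BB) = -2 pBb pbb / den
        hd(Bb) =  4 pBB pbb / den
        hd(bb) = -2 pBB pBb / den

    Markers whose hybrid set lacks the class structure (``den == 0``, e.g.
    all hybrids heterozygous, or a monomorphic class pattern) get a zero Hd
    column: a zero coding contributes no (co)variance, and panel alignment
    is preserved.
    """
    counts = H.counts
    pk = H.pk
    Ha = counts - 2.0 * pk[None, :]

    pBB, pBb, pbb = H.p_BB, H.p_het, H.p_bb
    den = pBB + pbb - (pBB - pbb) ** 2
    degenerate = np.abs(den) < 1e-12
    safe = np.where(degenerate, 1.0, den)
    hd_BB = -2.0 * pBb * pbb / safe
    hd_Bb = 4.0 * pBB * pbb / safe
    hd_bb = -2.0 * pBB * pBb / safe
    Hd = np.select(
        [counts == 2, counts == 1],
        [np.broadcast_to(hd_BB, counts.shape), np.broadcast_to(hd_Bb, counts.shape)],
        default=0.0,
    )
    Hd = np.where(counts == 0, np.broadcast_to(hd_bb, counts.shape), Hd)
    Hd[:, degenerate] = 0.0
    return NoiaCodings(Ha, Hd, list(H.hybrid_ids), list(H.marker_ids))
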