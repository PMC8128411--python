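"""Genomic relationship matrices for the GCA- and G-models.

Scalings follow the variance definitions of the underlying statistical
effects:

* additive, per group:      ``G_A = Z Z' / sum(p q)``
* dominance, across hybrids: ``D = W W' / sum(4 p1 q1 p2 q2)``
* every epistatic and G-model (NOIA) matrix: Gram or Hadamard product
  divided by ``trace/n`` so the mean diagonal is exactly 1.

With observed within-group frequencies, ``G_A`` has mean diagonal exactly 1
and mean entry exactly 0 (columns of Z sum to zero), so variance components
multiplying these matrices read directly as genetic variances.  VanRaden's
method-1 matrix from 0/2-coded lines equals ``2 G_A`` — the factor 2 is the
outbred- vs fully-inbred reference population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import LineGenotypes
from .encoding import AlleleFrequencies, AdditiveCoding, DominanceCoding, NoiaCodings

__all__ = [
    "KinshipMatrix",
    "additive_kinship",
    "vanraden1_kinship",
    "dominance_kinship",
    "epistatic_within",
    "epistatic_across",
    "epistatic_with_dominance",
    "gmodel_kinships",
    "kinship_summary",
]

KINSHIP_NAMES = (
    "GA1", "GA2", "D", "GAA11", "GAA22", "GAA12",
    "GA1D", "GA2D", "GDD", "GAH", "DH", "GAAH", "GVR1",
)


@dataclass
class KinshipMatrix:
    """A named symmetric relationship matrix with its scaling constant.

    ``level`` records what the rows index: lines of group 1 or 2, or
    hybrids.  ``scale_constant`` is the denominator that was applied, kept
    for reproducibility.
    """

    name: str
    level: str  # {"lines1", "lines2", "hybrids"}
    values: np.ndarray
    scale_constant: float
    ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"kinship {self.name!r}: matrix shape {self.values.shape} vs {n} ids")

    @property
    def n(self) -> int:
        return len(self.ids)


def _gram(X: np.ndarray, denom: float, name: str, level: str, ids: list[str]) -> KinshipMatrix:
    if denom <= 0:
        raise ValueError(f"kinship {name!r}: non-positive denominator {denom!r}")
    K = (X @ X.T) / denom
    return KinshipMatrix(name, level, K, denom, ids)


def additive_kinship(Z: AdditiveCoding, f: AlleleFrequencies, group: int | None = None) -> KinshipMatrix:
    """G_A = Z Z' / sum_i p_i q_i over the lines of one group."""
    denom = float(np.sum(f.p * f.q))
    if denom <= 0:
        raise ValueError("all markers fixed in this group: sum(pq) = 0")
    level = "lines1" if group in (None, 1) else "lines2"
    name = "GA1" if level == "lines1" else "GA2"
    return _gram(Z.Z, denom, name, level, list(Z.line_ids))


def vanraden1_kinship(G: LineGenotypes, f: AlleleFrequencies) -> KinshipMatrix:
    """VanRaden method 1 on 0/2-coded lines: (M* - 2p)(M* - 2p)' / (2 sum pq).

    Equals ``2 G_A`` elementwise: the additive variance it multiplies refers
    to an outbred population at the same frequencies rather than to the fully
    inbred one.
    """
    denom = 2.0 * float(np.sum(f.p * f.q))
    if denom <= 0:
        raise ValueError("all markers fixed in this group: sum(pq) = 0")
    Zstar = 2.0 * G.calls - 2.0 * f.p[None, :]
    return _gram(Zstar, denom, "GVR1", "lines1", list(G.line_ids))


def dominance_kinship(
    W: DominanceCoding, f1: AlleleFrequencies, f2: AlleleFrequencies
) -> KinshipMatrix:
    """D = W W' / sum_i 4 p1 q1 p2 q2 across hybrids."""
    denom = float(np.sum(4.0 * f1.p * f1.q * f2.p * f2.q))
    if denom <= 0:
        raise ValueError(
            "no marker segregates in both groups: sum(4 p1 q1 p2 q2) = 0"
        )
    return _gram(W.W, denom, "D", "hybrids", list(W.hybrid_ids))


def _trace_scaled(values: np.ndarray, name: str, level: str, ids: list[str]) -> KinshipMatrix:
    n = values.shape[0]
    scale = float(np.trace(values)) / n
    if scale <= 0:
        raise ValueError(f"kinship {name!r}: zero trace, cannot scale")
    return KinshipMatrix(name, level, values / scale, scale, ids)


def epistatic_within(GA: KinshipMatrix) -> KinshipMatrix:
    """Within-group additive-by-additive matrix (G_A . G_A) / (tr/n).

    The Hadamard square of the additive Gram matrix equals the Gram matrix
    of the (never materialized) Kronecker pairwise coding Z (x) Z.
    """
    name = {"lines1": "GAA11", "lines2": "GAA22"}.get(GA.level)
    if name is None:
        raise ValueError("epistatic_within expects a line-level additive kinship")
    return _trace_scaled(GA.values * GA.values, name, GA.level, list(GA.ids))


def epistatic_across(
    GA1: KinshipMatrix, GA2: KinshipMatrix, T1: np.ndarray, T2: np.ndarray,
    hybrid_ids: list[str],
) -> KinshipMatrix:
    """Across-group additive-by-additive matrix at the hybrid level:
    (T1 G_A1 T1') . (T2 G_A2 T2'), scaled to mean diagonal 1.

    Entry (i, j) before scaling is the product of the two parental additive
    relationships: GA1[parent1(i), parent1(j)] * GA2[parent2(i), parent2(j)].
    """
    H1 = T1 @ GA1.values @ T1.T
    H2 = T2 @ GA2.values @ T2.T
    return _trace_scaled(H1 * H2, "GAA12", "hybrids", list(hybrid_ids))


def epistatic_with_dominance(
    D: KinshipMatrix,
    GA: KinshipMatrix | None = None,
    T: np.ndarray | None = None,
    kind: str = "DD",
) -> KinshipMatrix:
    """Dominance-involving pairwise epistatic matrices at the hybrid level.

    ``kind``: ``"A1D"`` -> (T1 G_A1 T1') . D; ``"A2D"`` -> (T2 G_A2 T2') . D;
    ``"DD"`` -> D . D.  Each is scaled by its own tr/n.  These terms are
    constructible but excluded from the stock model menu — their variance
    estimates are too inaccurate to be useful in practice.
    """
    if kind == "DD":
        values = D.values * D.values
        name = "GDD"
    elif kind in ("A1D", "A2D"):
        if GA is None or T is None:
            raise ValueError(f"kind {kind!r} needs the additive kinship and its incidence T")
        values = (T @ GA.values @ T.T) * D.values
        name = "GA1D" if kind == "A1D" else "GA2D"
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return _trace_scaled(values, name, "hybrids", list(D.ids))


def gmodel_kinships(N: NoiaCodings) -> dict[str, KinshipMatrix]:
    """G-model (NOIA) matrices: GAH = Ha Ha'/(tr/n), DH = Hd Hd'/(tr/n),
    GAAH = (GAH . GAH)/(tr/n)."""
    ids = list(N.hybrid_ids)
    GAH = _trace_scaled(N.Ha @ N.Ha.T, "GAH", "hybrids", ids)
    DH = _trace_scaled(N.Hd @ N.Hd.T, "DH", "hybrids", ids)
    GAAH = _trace_scaled(GAH.values * GAH.values, "GAAH", "hybrids", ids)
    return {"GAH": GAH, "DH": DH, "GAAH": GAAH}


def kinship_summary(K: KinshipMatrix) -> dict[str, float]:
    """Diagnostics: mean diagonal, mean entry, extreme eigenvalues, off-diagonal range."""
    if not np.isfinite(K.values).all():
        raise ValueError(f"kinship {K.name!r} contains non-finite entries")
    eig = np.linalg.eigvalsh((K.values + K.values.T) / 2.0)
    off = K.values[~np.eye(K.n, dtype=bool)] if K.n > 1 else np.array([np.nan])
    return {
        "mean_diag": float(np.mean(np.diag(K.values))),
        "mean_all": float(np.mean(K.values)),
        "min_eigenvalue": float(eig[0]),
        "max_eigenvalue": float(eig[-1]),
        "offdiag_min": float(np.min(off)),
        "offdiag_max": float(np.max(off)),
    }
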