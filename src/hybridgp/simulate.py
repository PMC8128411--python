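"""Synthetic two-group hybrid studies with analytically known variance components.

The generator emulates the structure of a maize Dent x Flint hybrid trial:
two diverged panels of fully inbred lines, an (incomplete) factorial of
single crosses in which each line parents several hybrids, and entry-mean
phenotypes.  Founder allele frequencies are drawn per group from a Beta law
(truncated away from fixation), line genotypes are independent Bernoulli
draws per marker — linkage equilibrium by construction, matching the
standing assumption of the variance theory.

In the default *statistical* effect mode, substitution effects, dominance
effects and epistatic pair effects are drawn i.i.d. normal and then rescaled
once per effect class so that the realized analytic variance (computed from
the drawn effects and the observed line frequencies, e.g.
``sum_k p1 q1 alpha1^2`` for group-1 additive) equals its target exactly.
This makes parameter-recovery tests sharp.  The *functional* mode draws
functional (a1, a2, d) effects per locus and derives the statistical effects
through the single-locus theory before the same rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import LineGenotypes, HybridPedigree, PhenotypeTable
from .encoding import (
    compute_allele_freqs,
    center_line_genotypes,
    build_dominance_incidence,
    AlleleFrequencies,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_lines",
    "simulate_pedigree",
    "simulate_effects_and_phenotypes",
    "simulate_study",
]


@dataclass
class SimConfig:
    """Study-generator settings.

    Defaults mirror the structure of the public Dent x Flint grain-yield
    data set this package is modeled around: 123 x 86 lines, 1,254 hybrids
    in an incomplete factorial, 35,478 SNPs, and the variance components
    estimated there by the full GCA-model (trait units q/ha; mean set to a
    typical grain-yield level of 100 q/ha).
    """

    n1: int = 123
    n2: int = 86
    nsnp: int = 35_478
    design: str = "incomplete"  # {"complete", "incomplete"}
    n_hybrids: int = 1254  # ignored for design="complete"
    beta1: tuple[float, float] = (2.0, 2.0)
    beta2: tuple[float, float] = (2.0, 2.0)
    freq_bounds: tuple[float, float] = (0.05, 0.95)
    effect_mode: str = "statistical"  # {"statistical", "functional"}
    var_A1: float = 19.06
    var_A2: float = 10.61
    var_D: float = 2.3
    var_AA11: float = 5.41
    var_AA22: float = 5.57
    var_AA12: float = 3.24
    var_r1: float = 3.8
    var_r2: float = 4.56
    var_e: float = 13.67
    n_epistatic_pairs: int = 500
    mu: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("var_A1", "var_A2", "var_D", "var_AA11", "var_AA22",
                     "var_AA12", "var_r1", "var_r2", "var_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.design not in ("complete", "incomplete"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.effect_mode not in ("statistical", "functional"):
            raise ValueError(f"unknown effect mode {self.effect_mode!r}")


@dataclass
class SimTruth:
    """Realized (analytic) variance components and the drawn effects.

    Marker-based components are exact by the rescaling construction; the
    r and residual entries report the target variances the draws used.
    """

    realized: dict[str, float]
    alpha1: np.ndarray = field(repr=False, default=None)
    alpha2: np.ndarray = field(repr=False, default=None)
    d: np.ndarray = field(repr=False, default=None)
    pairs_11: np.ndarray = field(repr=False, default=None)
    pairs_22: np.ndarray = field(repr=False, default=None)
    pairs_12: np.ndarray = field(repr=False, default=None)
    aa_11: np.ndarray = field(repr=False, default=None)
    aa_22: np.ndarray = field(repr=False, default=None)
    aa_12: np.ndarray = field(repr=False, default=None)
    r1: np.ndarray = field(repr=False, default=None)
    r2: np.ndarray = field(repr=False, default=None)


def simulate_lines(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[LineGenotypes, LineGenotypes, AlleleFrequencies, AlleleFrequencies]:
    """Draw the two inbred-line panels and their observed frequencies."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    lo, hi = cfg.freq_bounds
    markers = [f"M{j}" for j in range(cfg.nsnp)]
    panels = []
    for label, n, (a, b) in (("group1", cfg.n1, cfg.beta1), ("group2", cfg.n2, cfg.beta2)):
        p = np.clip(rng.beta(a, b, size=cfg.nsnp), lo, hi)
        calls = (rng.random((n, cfg.nsnp)) < p[None, :]).astype(float)
        ids = [f"{'D' if label == 'group1' else 'F'}{i}" for i in range(n)]
        panels.append(LineGenotypes(label, ids, markers, calls))
    g1, g2 = panels
    return g1, g2, compute_allele_freqs(g1), compute_allele_freqs(g2)


def simulate_pedigree(
    cfg: SimConfig,
    g1: LineGenotypes,
    g2: LineGenotypes,
    rng: np.random.Generator | None = None,
    max_retries: int = 50,
) -> HybridPedigree:
    """Complete factorial, or a uniform sample of crosses in which every
    line is guaranteed to parent at least one hybrid."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    n_cells = g1.n_lines * g2.n_lines
    if cfg.design == "complete" or cfg.n_hybrids == n_cells:
        cells = np.arange(n_cells)
    else:
        if cfg.n_hybrids > n_cells:
            raise ValueError(f"n_hybrids={cfg.n_hybrids} exceeds the {n_cells} possible crosses")
        if cfg.n_hybrids < max(g1.n_lines, g2.n_lines):
            raise ValueError("too few hybrids to cover every line at least once")
        for _ in range(max_retries):
            cells = rng.choice(n_cells, size=cfg.n_hybrids, replace=False)
            i1 = cells // g2.n_lines
            i2 = cells % g2.n_lines
            if np.unique(i1).size == g1.n_lines and np.unique(i2).size == g2.n_lines:
                break
        else:
            raise RuntimeError(
                f"could not cover every line in {max_retries} draws of "
                f"{cfg.n_hybrids} crosses; increase n_hybrids"
            )
        cells = np.sort(cells)
    i1 = cells // g2.n_lines
    i2 = cells % g2.n_lines
    hybrids = [f"H{k}" for k in range(cells.size)]
    return HybridPedigree(
        hybrids,
        {h: g1.line_ids[a] for h, a in zip(hybrids, i1)},
        {h: g2.line_ids[b] for h, b in zip(hybrids, i2)},
    )


def _rescale(effects: np.ndarray, weights: np.ndarray, target: float) -> tuple[np.ndarray, float]:
    """Scale an effect vector so that sum(weights * effects^2) == target."""
    realized = float(weights @ effects**2)
    if target == 0.0 or realized == 0.0:
        return np.zeros_like(effects), 0.0
    return effects * np.sqrt(target / realized), target


def _draw_pairs(rng: np.random.Generator, nsnp: int, n_pairs: int) -> np.ndarray:
    n_pairs = min(n_pairs, nsnp * (nsnp - 1) // 2)
    pairs = set()
    while len(pairs) < n_pairs:
        k, m = rng.integers(0, nsnp, size=2)
        if k != m:
            pairs.add((min(k, m), max(k, m)))
    return np.array(sorted(pairs))


def simulate_effects_and_phenotypes(
    cfg: SimConfig,
    g1: LineGenotypes,
    g2: LineGenotypes,
    ped: HybridPedigree,
    rng: np.random.Generator | None = None,
) -> tuple[PhenotypeTable, SimTruth]:
    """Draw effects, rescale per class to the target variances, and emit
    phenotypes ``y = mu + genetic value + e`` with their SimTruth sidecar."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    f1, f2 = compute_allele_freqs(g1), compute_allele_freqs(g2)
    Z1 = center_line_genotypes(g1, f1)
    Z2 = center_line_genotypes(g2, f2)
    pq1, pq2 = f1.p * f1.q, f2.p * f2.q

    if cfg.effect_mode == "statistical":
        alpha1 = rng.standard_normal(cfg.nsnp)
        alpha2 = rng.standard_normal(cfg.nsnp)
        d = rng.standard_normal(cfg.nsnp)
    else:
        a1 = rng.standard_normal(cfg.nsnp)
        a2 = rng.standard_normal(cfg.nsnp)
        d = rng.standard_normal(cfg.nsnp)
        # statistical substitution effects from the single-locus theory,
        # using each group's observed frequencies
        alpha1 = a1 + (f2.q - f2.p) * d
        alpha2 = a2 + (f1.q - f1.p) * d

    alpha1, vA1 = _rescale(alpha1, pq1, cfg.var_A1)
    alpha2, vA2 = _rescale(alpha2, pq2, cfg.var_A2)
    d, vD = _rescale(d, 4.0 * pq1 * pq2, cfg.var_D)

    pairs_11 = pairs_22 = pairs_12 = np.empty((0, 2), dtype=int)
    aa_11 = aa_22 = aa_12 = np.empty(0)
    vAA11 = vAA22 = vAA12 = 0.0
    if cfg.var_AA11 > 0:
        pairs_11 = _draw_pairs(rng, cfg.nsnp, cfg.n_epistatic_pairs)
        w = pq1[pairs_11[:, 0]] * pq1[pairs_11[:, 1]]
        aa_11, vAA11 = _rescale(rng.standard_normal(len(pairs_11)), w, cfg.var_AA11)
    if cfg.var_AA22 > 0:
        pairs_22 = _draw_pairs(rng, cfg.nsnp, cfg.n_epistatic_pairs)
        w = pq2[pairs_22[:, 0]] * pq2[pairs_22[:, 1]]
        aa_22, vAA22 = _rescale(rng.standard_normal(len(pairs_22)), w, cfg.var_AA22)
    if cfg.var_AA12 > 0:
        pairs_12 = _draw_pairs(rng, cfg.nsnp, cfg.n_epistatic_pairs)
        w = pq1[pairs_12[:, 0]] * pq2[pairs_12[:, 1]]
        aa_12, vAA12 = _rescale(rng.standard_normal(len(pairs_12)), w, cfg.var_AA12)

    pos1, pos2 = g1.line_index(), g2.line_index()
    i1 = np.array([pos1[ped.parent1[h]] for h in ped.hybrid_ids])
    i2 = np.array([pos2[ped.parent2[h]] for h in ped.hybrid_ids])

    u1 = Z1.Z @ alpha1  # line-level additive values, group 1
    u2 = Z2.Z @ alpha2
    W = build_dominance_incidence(Z1, Z2, ped)
    g_dom = W.W @ d

    e11 = np.zeros(g1.n_lines)
    if aa_11.size:
        e11 = (Z1.Z[:, pairs_11[:, 0]] * Z1.Z[:, pairs_11[:, 1]]) @ aa_11
    e22 = np.zeros(g2.n_lines)
    if aa_22.size:
        e22 = (Z2.Z[:, pairs_22[:, 0]] * Z2.Z[:, pairs_22[:, 1]]) @ aa_22
    e12 = np.zeros(ped.n_hybrids)
    if aa_12.size:
        e12 = (Z1.Z[i1][:, pairs_12[:, 0]] * Z2.Z[i2][:, pairs_12[:, 1]]) @ aa_12

    r1 = rng.normal(0.0, np.sqrt(cfg.var_r1), g1.n_lines) if cfg.var_r1 > 0 else np.zeros(g1.n_lines)
    r2 = rng.normal(0.0, np.sqrt(cfg.var_r2), g2.n_lines) if cfg.var_r2 > 0 else np.zeros(g2.n_lines)
    e = rng.normal(0.0, np.sqrt(cfg.var_e), ped.n_hybrids) if cfg.var_e > 0 else np.zeros(ped.n_hybrids)

    y = (
        cfg.mu
        + u1[i1] + u2[i2] + g_dom
        + e11[i1] + e22[i2] + e12
        + r1[i1] + r2[i2] + e
    )
    truth = SimTruth(
        realized={
            "A1": vA1, "A2": vA2, "D": vD,
            "AA11": vAA11, "AA22": vAA22, "AA12": vAA12,
            "r1": cfg.var_r1, "r2": cfg.var_r2, "e": cfg.var_e,
        },
        alpha1=alpha1, alpha2=alpha2, d=d,
        pairs_11=pairs_11, pairs_22=pairs_22, pairs_12=pairs_12,
        aa_11=aa_11, aa_22=aa_22, aa_12=aa_12, r1=r1, r2=r2,
    )
    return PhenotypeTable(list(ped.hybrid_ids), y, "sim_trait"), truth


def simulate_study(cfg: SimConfig) -> dict:
    """One call for the whole study: panels, pedigree, phenotypes, truth."""
    rng = np.random.default_rng(cfg.seed)
    g1, g2, f1, f2 = simulate_lines(cfg, rng)
    ped = simulate_pedigree(cfg, g1, g2, rng)
    phenotypes, truth = simulate_effects_and_phenotypes(cfg, g1, g2, ped, rng)
    return {
        "g1": g1, "g2": g2, "freq1": f1, "freq2": f2,
        "pedigree": ped, "phenotypes": phenotypes, "truth": truth,
    }
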